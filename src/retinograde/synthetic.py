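"""Synthetic retinal fundus images with grade-consistent pathology.

Each sample is a circular fundus field on a dark surround containing a bright
optic disc, a branching dark vessel tree rooted at the disc, a dark fovea at
the field centre, and — depending on grade — microaneurysms, haemorrhages,
soft exudates, hard exudates and neovascular tufts.  Intensities are loosely
modeled on fundus photography: red-dominant background with the strongest
vessel/lesion contrast in the green channel.

Grading rules encoded by the generator (and invertible from the masks):

* DR grade follows lesion load: mild NPDR has a few microaneurysms only;
  moderate adds haemorrhages and soft exudates; severe carries >= 10 lesions
  spread over >= 2 quadrants; proliferative adds dense neovascular tufts.
* DME grade follows the minimum distance from any hard-exudate pixel to the
  fovea centre: severe closer than R/6, moderate closer than R/3, mild
  beyond; no hard exudates means no DME.

Hard exudates are placed only when a DME grade is requested, so the two
grades stay mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import (
    DR_GRADES,
    GradeLabel,
    JOINT_CLASSES,
    LESION_CLASSES,
    MASK_CLASSES,
)

__all__ = [
    "GeneratorConfig",
    "FundusSample",
    "generate_sample",
    "generate_dataset",
    "measure_grade",
    "write_dataset",
]

# Per-grade lesion count ranges (inclusive); totals are disjoint across
# grades so the grade is recoverable from the masks.
DEFAULT_LESION_RANGES = {
    "healthy": {},
    "mild_NPDR": {"microaneurysm": (1, 5)},
    "moderate_NPDR": {
        "microaneurysm": (2, 4),
        "haemorrhage": (1, 3),
        "soft_exudate": (1, 2),
    },
    "severe_NPDR": {
        "microaneurysm": (6, 10),
        "haemorrhage": (4, 7),
        "soft_exudate": (2, 4),
    },
    "proliferative_DR": {
        "microaneurysm": (6, 10),
        "haemorrhage": (4, 7),
        "soft_exudate": (2, 4),
    },
}

#: Lesion total at or above which (absent tufts) the load reads as severe.
SEVERE_TOTAL = 10


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-fundus generator.

    ``dme_thresholds`` are fractions of the fundus radius R: a hard exudate
    closer to the fovea than ``severe_frac * R`` marks severe DME, closer
    than ``moderate_frac * R`` moderate, anything farther mild.
    """

    image_size: int = 128
    class_mix: dict = field(
        default_factory=lambda: {lab.name: 1.0 / len(JOINT_CLASSES) for lab in JOINT_CLASSES}
    )
    lesion_ranges: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LESION_RANGES.items()})
    dme_thresholds: tuple = (1.0 / 6.0, 1.0 / 3.0)  # (severe_frac, moderate_frac)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"class_mix proportions sum to {total}, expected 1")
        sev, mod = self.dme_thresholds
        if not (0 < sev < mod < 1):
            raise ValueError("dme_thresholds must satisfy 0 < severe < moderate < 1")

    @property
    def fundus_radius(self) -> float:
        return 0.48 * self.image_size


@dataclass
class FundusSample:
    """One synthetic fundus image with ground-truth masks and grade label."""

    image: np.ndarray  # H x W x 3 uint8
    masks: dict  # class name -> H x W bool
    label: GradeLabel
    provenance: dict

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for name, m in self.masks.items():
            if m.shape != (h, w):
                raise ValueError(f"mask {name!r} shape {m.shape} != image {h, w}")


# ---------------------------------------------------------------------------
# drawing primitives

def _disk_indices(shape, cy, cx, r):
    y0 = max(0, int(np.floor(cy - r)))
    y1 = min(shape[0], int(np.ceil(cy + r)) + 1)
    x0 = max(0, int(np.floor(cx - r)))
    x1 = min(shape[1], int(np.ceil(cx + r)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return yy[inside], xx[inside]


def _stamp(mask, cy, cx, r):
    ys, xs = _disk_indices(mask.shape, cy, cx, r)
    mask[ys, xs] = True


def _tint(image, mask_sel, factors=None, color=None, alpha=1.0):
    """Multiply (factors) or blend toward (color) the selected pixels."""
    sel = image[mask_sel]
    if factors is not None:
        sel = sel * np.asarray(factors)
    if color is not None:
        sel = (1 - alpha) * sel + alpha * np.asarray(color, dtype=float)
    image[mask_sel] = sel


class _Placer:
    """Rejection-samples non-overlapping lesion sites inside the field."""

    def __init__(self, rng, size, field_r, avoid):
        self.rng = rng
        self.size = size
        self.field_r = field_r
        self.avoid = list(avoid)  # (cy, cx, radius) exclusion disks
        self.placed = []

    def place(self, r, quadrant=None, max_tries=200):
        c = self.size / 2.0
        for _ in range(max_tries):
            rho = self.field_r * (0.15 + 0.8 * np.sqrt(self.rng.uniform()))
            if quadrant is None:
                ang = self.rng.uniform(0, 2 * np.pi)
            else:
                ang = self.rng.uniform(quadrant * np.pi / 2, (quadrant + 1) * np.pi / 2)
            cy, cx = c + rho * np.sin(ang), c + rho * np.cos(ang)
            if rho + r > self.field_r - 2:
                continue
            if any(np.hypot(cy - ay, cx - ax) < ar + r + 2 for ay, ax, ar in self.avoid):
                continue
            if any(np.hypot(cy - py, cx - px) < pr + r + 2 for py, px, pr in self.placed):
                continue
            self.placed.append((cy, cx, r))
            return cy, cx
        # dense grades on small canvases may exhaust tries; relax separation
        self.placed.append((cy, cx, r))
        return cy, cx


def _draw_vessels(rng, size, field_r, disc_cy, disc_cx, disc_r):
    """Branching vessel tree rooted at the optic disc centre.

    Every stroke starts at the disc centre or on a parent path, so the mask
    is 8-connected to the disc region by construction.  Returns the mask and
    the list of on-path points (used to seed neovascular tufts).
    """
    mask = np.zeros((size, size), dtype=bool)
    c = size / 2.0
    path_points = []

    def walk(y, x, ang, width, length, depth):
        step = 1.2
        ang0 = ang  # bounded curvature: arcades meander but never loop back
        for i in range(length):
            r = max(1.0, width)
            _stamp(mask, y, x, r)
            if depth <= 1 and i % 4 == 0:
                path_points.append((y, x))
            ang = np.clip(ang + rng.normal(0, 0.18), ang0 - 1.0, ang0 + 1.0)
            y += step * np.sin(ang)
            x += step * np.cos(ang)
            if np.hypot(y - c, x - c) > field_r - 3:
                return
            if depth < 2 and i > 8 and rng.uniform() < 0.035:
                walk(y, x, ang + rng.choice([-1, 1]) * rng.uniform(0.4, 0.9),
                     width * 0.7, int(length * 0.6), depth + 1)
            width *= 0.995

    # main arcades leave the disc fanning toward and around the fovea side
    base = np.arctan2(c - disc_cy, c - disc_cx)
    n_main = rng.integers(5, 8)
    for k in range(n_main):
        # spread the arcades over a wide fan so they separate quickly
        ang = base + (k - (n_main - 1) / 2.0) * (3.4 / n_main) + rng.normal(0, 0.12)
        walk(disc_cy, disc_cx, ang, width=rng.uniform(1.0, 1.4),
             length=int(field_r * rng.uniform(0.9, 1.4)), depth=0)
    return mask, path_points


def _draw_tufts(rng, vessel_mask, path_points, n_tufts, field_r, size,
                disc_cy, disc_cx, disc_r):
    """Dense neovascular tufts sprouting from existing vessel points.

    Tufts are kept clear of the optic-disc neighbourhood (excluded from the
    thickness-based re-measurement) and are thicker than any normal stroke
    crossing, so the grading rules stay invertible.
    """
    c = size / 2.0
    candidates = [
        i for i, (y, x) in enumerate(path_points)
        if np.hypot(y - disc_cy, x - disc_cx) > disc_r + 14
    ] or list(range(len(path_points)))
    idx = rng.choice(candidates, size=min(n_tufts, len(candidates)), replace=False)
    for i in idx:
        y, x = path_points[i]
        if np.hypot(y - c, x - c) > field_r - 9:
            y, x = c + (y - c) * 0.7, c + (x - c) * 0.7
        _stamp(vessel_mask, y, x, rng.uniform(4.5, 5.5))


def _hard_exudate_band(config, dme_grade):
    """(low, high) distance band (pixels from fovea centre) for a DME grade."""
    R = config.fundus_radius
    sev, mod = config.dme_thresholds
    if dme_grade == "severe":
        return 0.0, sev * R
    if dme_grade == "moderate":
        return sev * R, mod * R
    if dme_grade == "mild":
        return mod * R, 0.8 * R
    raise ValueError(f"no hard-exudate band for dme_grade {dme_grade!r}")


def _place_hard_exudates(rng, masks, config, dme_grade, fovea_cy, fovea_cx,
                         disc_cy, disc_cx, disc_r):
    """Hard-exudate dots whose minimum fovea distance falls in the grade band."""
    lo, hi = _hard_exudate_band(config, dme_grade)
    size = config.image_size
    c = size / 2.0
    anchor_d = 0.5 * (lo + hi)
    mask = masks["hard_exudate"]
    n_dots = int(rng.integers(4, 9))
    placed_any = False
    for i in range(n_dots):
        r = rng.uniform(1.0, 2.0)
        for _ in range(100):
            # anchor dot pins the minimum distance near the band midpoint;
            # later dots may only sit farther out (still inside the field)
            if i == 0:
                d = anchor_d + r
            else:
                d = rng.uniform(anchor_d + r + 1.0, 0.85 * config.fundus_radius)
            ang = rng.uniform(0, 2 * np.pi)
            cy, cx = fovea_cy + d * np.sin(ang), fovea_cx + d * np.cos(ang)
            if np.hypot(cy - c, cx - c) > config.fundus_radius - 3:
                continue
            if np.hypot(cy - disc_cy, cx - disc_cx) < disc_r + r + 2:
                continue
            _stamp(mask, cy, cx, r)
            placed_any = True
            break
    if not placed_any:  # pathological config; guarantee at least the anchor
        _stamp(mask, fovea_cy + anchor_d, fovea_cx, 1.5)


# ---------------------------------------------------------------------------

def generate_sample(config: GeneratorConfig, label: GradeLabel, seed: int) -> FundusSample:
    """Render one labeled fundus image; bit-reproducible from ``seed``."""
    if not isinstance(label, GradeLabel):
        label = GradeLabel(*label)
    if label.dr_grade == "healthy" and label.dme_grade != "none":
        raise ValueError("healthy retina cannot carry DME")  # unreachable: GradeLabel validates

    rng = np.random.default_rng(seed)
    size = config.image_size
    c = size / 2.0
    R = config.fundus_radius

    yy, xx = np.mgrid[0:size, 0:size]
    rr2 = (yy - c) ** 2 + (xx - c) ** 2
    field = rr2 <= R**2

    img = np.zeros((size, size, 3), dtype=float)
    # red-dominant background with gentle radial falloff
    base = np.array([168.0, 96.0, 42.0])
    falloff = 1.0 - 0.25 * rr2 / R**2
    img[:] = base[None, None, :] * falloff[:, :, None]

    masks = {name: np.zeros((size, size), dtype=bool) for name in MASK_CLASSES}

    # optic disc, nasal side (left/right chosen per-sample)
    side = rng.choice([-1.0, 1.0])
    disc_cy = c + rng.uniform(-0.08, 0.08) * R
    disc_cx = c + side * 0.55 * R
    disc_r = 0.14 * R
    _stamp(masks["optic_disc"], disc_cy, disc_cx, disc_r)
    _tint(img, masks["optic_disc"], color=(238.0, 208.0, 162.0), alpha=0.9)

    # fovea: small dark pit at the field centre
    fovea_cy = c + rng.uniform(-1.5, 1.5)
    fovea_cx = c + rng.uniform(-1.5, 1.5)
    fovea_r = max(2.0, 0.05 * R)
    _stamp(masks["fovea"], fovea_cy, fovea_cx, fovea_r)
    _tint(img, masks["fovea"], factors=(0.62, 0.52, 0.62))

    # vessel tree (drawn after disc so vessels darken the disc surface too)
    vessels, path_points = _draw_vessels(rng, size, R, disc_cy, disc_cx, disc_r)
    if label.dr_grade == "proliferative_DR":
        _draw_tufts(rng, vessels, path_points, int(rng.integers(2, 5)), R, size,
                    disc_cy, disc_cx, disc_r)
    masks["vessel"] = vessels
    _tint(img, vessels, factors=(0.72, 0.42, 0.62))

    # lesions driven by the DR grade
    ranges = config.lesion_ranges[label.dr_grade]
    placer = _Placer(
        rng, size, R,
        avoid=[(disc_cy, disc_cx, disc_r), (fovea_cy, fovea_cx, fovea_r)],
    )
    quadrant_cycle = 0
    heavy = label.dr_grade in ("severe_NPDR", "proliferative_DR")
    for lesion, (lo, hi) in ranges.items():
        n = int(rng.integers(lo, hi + 1))
        for _ in range(n):
            q = quadrant_cycle % 4 if heavy else None
            quadrant_cycle += 1
            if lesion == "microaneurysm":
                cy, cx = placer.place(r=1.5)
                _stamp(masks[lesion], cy, cx, rng.uniform(1.0, 1.8))
            elif lesion == "haemorrhage":
                cy, cx = placer.place(r=5.0, quadrant=q)
                blob = np.zeros((size, size), dtype=bool)
                for _ in range(3):
                    _stamp(blob, cy + rng.normal(0, 1.5), cx + rng.normal(0, 1.5),
                           rng.uniform(2.5, 4.5))
                masks[lesion] |= blob
            elif lesion == "soft_exudate":
                cy, cx = placer.place(r=5.0, quadrant=q)
                _stamp(masks[lesion], cy, cx, rng.uniform(3.5, 5.5))
    _tint(img, masks["microaneurysm"], factors=(0.55, 0.38, 0.55))
    _tint(img, masks["haemorrhage"], factors=(0.48, 0.30, 0.45))
    _tint(img, masks["soft_exudate"], color=(216.0, 206.0, 178.0), alpha=0.75)

    # hard exudates pinned to the DME distance band
    if label.dme_grade != "none":
        _place_hard_exudates(rng, masks, config, label.dme_grade,
                             fovea_cy, fovea_cx, disc_cy, disc_cx, disc_r)
        _tint(img, masks["hard_exudate"], color=(246.0, 226.0, 86.0), alpha=0.92)

    img += rng.normal(0.0, config.noise_sd, img.shape)
    img[~field] = 0.0
    for m in masks.values():
        m &= field

    image = np.clip(img, 0, 255).astype(np.uint8)
    provenance = {
        "seed": int(seed),
        "image_size": size,
        "noise_sd": config.noise_sd,
        "dme_thresholds": tuple(config.dme_thresholds),
        "label": label.name,
    }
    return FundusSample(image=image, masks=masks, label=label, provenance=provenance)


# ---------------------------------------------------------------------------
# grade re-measurement (the generator's own rules, run in reverse)

def _fovea_centre(masks):
    ys, xs = np.nonzero(masks["fovea"])
    return float(ys.mean()), float(xs.mean())


def measure_grade(masks: dict, config: GeneratorConfig) -> GradeLabel:
    """Recover the grade label from the structure masks alone."""
    counts = {
        lesion: int(ndimage.label(masks[lesion])[1])
        for lesion in ("microaneurysm", "haemorrhage", "soft_exudate")
    }
    total = sum(counts.values())

    # neovascular tufts: locally *thick* vessel regions away from the optic
    # disc.  Normal strokes stay under ~3.7 px half-width even where several
    # cross or run merged; tufts are filled disks of radius >= 4.5 px, so
    # the distance transform separates them cleanly.
    disc_dilated = ndimage.binary_dilation(masks["optic_disc"], iterations=6)
    thickness = ndimage.distance_transform_edt(masks["vessel"] & ~disc_dilated)
    has_tufts = bool(thickness.max() >= 4.2)

    if has_tufts:
        dr = "proliferative_DR"
    elif total == 0:
        dr = "healthy"
    elif total >= SEVERE_TOTAL:
        dr = "severe_NPDR"
    elif counts["haemorrhage"] > 0 or counts["soft_exudate"] > 0:
        dr = "moderate_NPDR"
    else:
        dr = "mild_NPDR"

    hard_ys, hard_xs = np.nonzero(masks["hard_exudate"])
    if hard_ys.size == 0:
        dme = "none"
    else:
        fy, fx = _fovea_centre(masks)
        dmin = float(np.min(np.hypot(hard_ys - fy, hard_xs - fx)))
        sev, mod = config.dme_thresholds
        R = config.fundus_radius
        if dmin < sev * R:
            dme = "severe"
        elif dmin < mod * R:
            dme = "moderate"
        else:
            dme = "mild"
    if dr == "healthy" and dme != "none":  # inconsistent masks
        dr = "mild_NPDR"
    return GradeLabel(dr, dme)


# ---------------------------------------------------------------------------

def _allocate_counts(mix: dict, n: int) -> dict:
    """Largest-remainder apportionment of n samples over the class mix."""
    names = sorted(mix)
    quotas = {k: mix[k] * n for k in names}
    counts = {k: int(math.floor(quotas[k])) for k in names}
    short = n - sum(counts.values())
    by_rem = sorted(names, key=lambda k: (quotas[k] - counts[k], k), reverse=True)
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def generate_dataset(config: GeneratorConfig, n: int):
    """Generate ``n`` samples honoring the class mix; returns (samples, manifest)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    nonzero = [k for k, p in config.class_mix.items() if p > 0]
    if n < len(nonzero):
        raise ValueError(
            f"n={n} is smaller than the {len(nonzero)} classes with nonzero mix"
        )
    counts = _allocate_counts(config.class_mix, n)
    seeds = (np.random.SeedSequence(config.seed).generate_state(n, dtype=np.uint32) >> 1)
    labels = []
    for name in sorted(counts):
        labels.extend([GradeLabel.from_name(name)] * counts[name])
    # shuffle so any prefix of the dataset is a class mixture, not one grade
    order = np.random.default_rng(config.seed).permutation(n)
    labels = [labels[i] for i in order]
    samples = [
        generate_sample(config, lab, int(s)) for lab, s in zip(labels, seeds)
    ]
    manifest = pd.DataFrame(
        {
            "path": [f"sample_{i:04d}.png" for i in range(n)],
            "dr_grade": [s.label.dr_grade for s in samples],
            "dme_grade": [s.label.dme_grade for s in samples],
            "seed": [s.provenance["seed"] for s in samples],
        }
    )
    return samples, manifest


def write_dataset(samples, manifest: pd.DataFrame, outdir, write_masks: bool = False):
    """Write images as PNG and the manifest as CSV under ``outdir``."""
    import imageio.v3 as iio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, path in zip(samples, manifest["path"]):
        iio.imwrite(outdir / path, sample.image)
        if write_masks:
            mdir = outdir / "masks" / Path(path).stem
            mdir.mkdir(parents=True, exist_ok=True)
            for name, m in sample.masks.items():
                iio.imwrite(mdir / f"{name}.png", (m * 255).astype(np.uint8))
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir / "manifest.csv"
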