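"""Chicken Swarm Algorithm: a role-structured, derivative-free minimizer.

The population splits by fitness rank into roosters (best), hens and chicks
(worst); some hens are mothers.  Per step:

* a rooster perturbs its position multiplicatively, ``A * (1 + N(0, s2))``,
  where ``s2 = 1`` if it is at least as fit as a randomly chosen other
  rooster, else ``exp((fv_l - fv_m) / (|fv_m| + eps))`` (< 1, shrinking the
  search when outclassed);
* a hen steps toward its group rooster (scale ``S1``) and a random other
  member (scale ``S2``) with fresh uniform draws — for a hen worse than both,
  ``S2 < 1 < S1``;
* a chick follows its mother with factor ``FL`` drawn from [0, 2].

Roles are refreshed from the fitness ranking every ``G`` steps; the best
position ever evaluated is archived (elitism), so the reported optimum is
monotone non-increasing.  Fitness is minimized throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SwarmParams", "Swarm", "csa_init", "csa_step", "csa_optimize"]

_EXP_CLIP = 50.0  # keeps exp() finite for pathological fitness spreads


@dataclass(frozen=True)
class SwarmParams:
    """Role fractions and update constants."""

    rooster_frac: float = 0.2
    hen_frac: float = 0.6  # chicks take the rest
    mother_frac: float = 0.5  # fraction of hens that are mothers
    refresh_every: int = 10  # G: steps between role reassignments
    fl_range: tuple = (0.0, 2.0)
    eps: float = 1e-12
    bounds: tuple = (-1.0, 1.0)

    def counts(self, n: int):
        if n < 4:
            raise ValueError("swarm needs N >= 4 so every role is populated")
        nr = max(1, int(round(self.rooster_frac * n)))
        nc = max(1, int(round((1.0 - self.rooster_frac - self.hen_frac) * n)))
        nh = n - nr - nc
        if nh < 1:
            raise ValueError("role fractions leave no hens")
        return nr, nh, nc


@dataclass
class Swarm:
    positions: np.ndarray  # (N, DS)
    fitness: np.ndarray  # (N,)
    roosters: np.ndarray  # member indices, best-ranked
    hens: np.ndarray
    chicks: np.ndarray
    mothers: np.ndarray  # subset of hens
    hen_rooster: dict  # hen index -> its rooster index
    chick_mother: dict  # chick index -> its mother hen index
    params: SwarmParams
    rng: np.random.Generator
    ts: int = 0
    best_position: np.ndarray | None = None
    best_fitness: float = np.inf
    history: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.fitness)


def _assign_roles(swarm: Swarm) -> None:
    """Rank by fitness: roosters best, chicks worst; pair hens and chicks."""
    p = swarm.params
    nr, nh, nc = p.counts(swarm.n)
    order = np.argsort(swarm.fitness, kind="stable")
    swarm.roosters = order[:nr]
    swarm.hens = order[nr : nr + nh]
    swarm.chicks = order[nr + nh :]
    nm = max(1, int(round(p.mother_frac * nh)))
    swarm.mothers = swarm.rng.choice(swarm.hens, size=nm, replace=False)
    swarm.hen_rooster = {
        int(h): int(swarm.rng.choice(swarm.roosters)) for h in swarm.hens
    }
    swarm.chick_mother = {
        int(c): int(swarm.rng.choice(swarm.mothers)) for c in swarm.chicks
    }


def csa_init(
    objective,
    ds: int,
    n: int,
    params: SwarmParams = SwarmParams(),
    seed: int = 0,
) -> Swarm:
    """Uniform random swarm inside the bounds, evaluated and role-assigned."""
    rng = np.random.default_rng(seed)
    lo, hi = params.bounds
    pos = rng.uniform(lo, hi, size=(n, ds))
    fit = np.array([float(objective(x)) for x in pos])
    swarm = Swarm(
        positions=pos,
        fitness=fit,
        roosters=np.empty(0, dtype=int),
        hens=np.empty(0, dtype=int),
        chicks=np.empty(0, dtype=int),
        mothers=np.empty(0, dtype=int),
        hen_rooster={},
        chick_mother={},
        params=params,
        rng=rng,
    )
    _assign_roles(swarm)
    best = int(np.argmin(fit))
    swarm.best_position = pos[best].copy()
    swarm.best_fitness = float(fit[best])
    swarm.history.append(swarm.best_fitness)
    return swarm


def rooster_sigma2(fv_m: float, fv_l: float, eps: float = 1e-12) -> float:
    """Variance of the rooster's multiplicative Gaussian perturbation."""
    if fv_m <= fv_l:
        return 1.0
    return float(np.exp(np.clip((fv_l - fv_m) / (abs(fv_m) + eps), -_EXP_CLIP, 0.0)))


def hen_scales(fv_m: float, fv_ro1: float, fv_ro2: float, eps: float = 1e-12):
    """(S1, S2): pull toward own rooster and toward a random other member."""
    s1 = float(np.exp(np.clip((fv_m - fv_ro1) / (abs(fv_m) + eps), -_EXP_CLIP, _EXP_CLIP)))
    s2 = float(np.exp(np.clip(fv_ro2 - fv_m, -_EXP_CLIP, _EXP_CLIP)))
    return s1, s2


def csa_step(swarm: Swarm, objective) -> Swarm:
    """Advance the swarm one time step in place (and return it).

    Moves follow the role update rules; each member then keeps its new
    position only if the fitness improved (greedy per-individual
    acceptance).  This extends the best-ever archive's elitism down to
    individuals and prevents the swarm from abandoning good regions when a
    rooster's multiplicative kick lands badly.
    """
    p = swarm.params
    rng = swarm.rng
    lo, hi = p.bounds
    pos = swarm.positions
    fit = swarm.fitness
    ds = pos.shape[1]
    new = pos.copy()

    for m in swarm.roosters:
        others = swarm.roosters[swarm.roosters != m]
        l = int(rng.choice(others)) if others.size else int(m)
        s2 = rooster_sigma2(fit[m], fit[l], p.eps)
        new[m] = pos[m] * (1.0 + rng.normal(0.0, np.sqrt(s2), size=ds))

    for m in swarm.hens:
        ro1 = swarm.hen_rooster[int(m)]
        choices = np.setdiff1d(np.arange(swarm.n), [m, ro1])
        ro2 = int(rng.choice(choices))
        s1, s2 = hen_scales(fit[m], fit[ro1], fit[ro2], p.eps)
        new[m] = (
            pos[m]
            + s1 * rng.uniform(size=ds) * (pos[ro1] - pos[m])
            + s2 * rng.uniform(size=ds) * (pos[ro2] - pos[m])
        )

    for m in swarm.chicks:
        mother = swarm.chick_mother[int(m)]
        fl = rng.uniform(*p.fl_range)
        new[m] = pos[m] + fl * (pos[mother] - pos[m])

    np.clip(new, lo, hi, out=new)
    new_fit = np.array([float(objective(x)) for x in new])
    improved = new_fit < fit
    pos[improved] = new[improved]
    swarm.fitness = np.where(improved, new_fit, fit)
    swarm.ts += 1

    best = int(np.argmin(swarm.fitness))
    if swarm.fitness[best] < swarm.best_fitness:
        swarm.best_fitness = float(swarm.fitness[best])
        swarm.best_position = pos[best].copy()
    swarm.history.append(swarm.best_fitness)

    if swarm.ts % p.refresh_every == 0:
        _assign_roles(swarm)
    return swarm


def csa_optimize(
    objective,
    ds: int,
    n: int = 30,
    steps: int = 200,
    params: SwarmParams = SwarmParams(),
    seed: int = 0,
):
    """Run CSA from scratch; returns (best_position, best_fitness, history)."""
    swarm = csa_init(objective, ds, n, params, seed)
    for _ in range(steps):
        csa_step(swarm, objective)
    return swarm.best_position, swarm.best_fitness, swarm.history
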