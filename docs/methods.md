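# Methods

`retinograde` implements an automatic grading pipeline for diabetic
retinopathy (DR) and diabetic macular edema (DME) on retinal fundus images,
exercised end to end on a synthetic fundus generator.  The five stages are
wavelet preprocessing, per-pixel neural segmentation with shift-add weight
quantization, adaptive Gabor feature extraction, penalized-Gini
random-forest feature selection, and a chicken-swarm-optimized classifier.
This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic study conditions do and do
not establish.

## Synthetic fundus generator

Each sample is a circular fundus field (radius R = 0.48 × image size,
default 128 px) on black surround: red-dominant background with radial
falloff, a bright optic disc (radius 0.14 R, nasal side chosen per sample),
a branching vessel tree rooted at the disc centre (5–7 arcades with bounded
curvature, recursive side branches, strongest contrast in the green
channel), a dark fovea at the field centre, and additive Gaussian sensor
noise (sd 5 intensity units).  Pathology is driven by the grade label:

* **DR grade** follows lesion load.  Mild NPDR: 1–5 microaneurysms (dark
  dots, radius 1–1.8 px).  Moderate: 2–4 microaneurysms + 1–3 haemorrhages
  (irregular dark blobs) + 1–2 soft exudates (pale fuzzy blobs).  Severe:
  6–10 / 4–7 / 2–4 of the same, placed round-robin over the four quadrants
  so the load spreads.  Proliferative adds 2–4 neovascular tufts — dense
  vessel blobs of radius 4.5–5.5 px sprouting from vessel paths away from
  the disc.  The per-grade count ranges are chosen so grade totals are
  disjoint and the grade is recoverable from the masks.
* **DME grade** follows the minimum distance from any hard-exudate pixel to
  the fovea centre, in fractions of R: severe < R/6, moderate < R/3, mild
  beyond.  Hard exudates (bright yellow dot clusters) are placed only when
  a DME grade is requested; an anchor dot is pinned to the middle of the
  requested distance band and further dots may only sit farther out, so the
  measured minimum always falls in the band.

`measure_grade` inverts these rules from the masks alone (connected-
component lesion counts; neovascular tufts read as vessel-mask regions
whose distance transform exceeds 4.2 px away from the disc — normal stroke
crossings stay below ~4 px, tufts above 4.4).  A generator/rule consistency
test holds across all grades and seeds exercised.

The default joint label space has 8 classes: healthy, the four DR grades,
and the three DME grades attached to distinct DR backgrounds
(mild DME + moderate NPDR, moderate DME + severe NPDR, severe DME +
proliferative DR), reflecting co-progression of edema and retinopathy.

**What the generator does not model:** photoreceptor texture, vessel
reflexes, illumination gradients of real cameras, camera blur, inter-eye
anatomical variation, drusen or other confounders, and realistic lesion
photometry.  Results on this generator demonstrate that the pipeline's
machinery works and that its stages compose correctly; they are not
evidence of clinical-grade accuracy on photographs.

## Preprocessing

The image is resized and reduced to its green channel (the channel with
the strongest vessel/lesion contrast), optionally histogram-equalized, and
denoised in the wavelet domain: multilevel separable 2D DWT (haar default,
db2 available; symmetric padding; default 2 levels), soft thresholding of
the detail sub-bands, inverse transform.  The universal threshold
(sigma-hat sqrt(2 log n), sigma-hat from the median absolute finest
diagonal coefficient over 0.6745) is the library default; the pipeline
passes an explicit mild threshold of 8 intensity units because the
universal rule, calibrated for white noise, removes the 2–4 px dot lesions
that carry the grading signal.

The pipeline's analysis path deliberately skips global histogram
equalization.  Exact equalization is a rank transform: when bright lesions
are separated from the background's upper tail by an empty intensity gap,
ranks on both sides are adjacent and the gap is erased — hard-exudate
pixel recall dropped from ~0.85 to ~0.4 with equalization in the loop.
The equalization op itself (monotone CDF remap onto [0, 255]) remains part
of the library, is exercised by the preprocessing CLI and tests, and can
be re-enabled with `PipelineConfig(equalize=True)`.  Nothing downstream
depends on absolute illumination: the Gabor features are DC-removed and
thus invariant to constant offsets, and the segmenter standardizes its
patches.

## Segmentation and shift-add quantization

A per-pixel MLP (default 64 tanh hidden units) classifies each pixel into
{background, vessel, optic disc, fovea, microaneurysm, haemorrhage, hard
exudate, soft exudate} from a 9×9 patch of four views of the preprocessed
raster: the raster itself, white top-hats at 1 px and 3 px scales (bright
dots, and the scale contrast that separates single-pixel noise from
lesions), and a 3 px black top-hat (dark dots).  Training patches are
class-balanced (up to 8000 coordinates per class drawn across all training
images); float training uses scikit-learn's MLPClassifier with strong L2
(alpha 0.3) — heavy-tailed weights quantize poorly, and the regularization
keeps weight magnitudes in a narrow band.  After training, output biases
are tempered toward the pixel-class priors measured on the training masks
(shift of 0.4 × (log prior − log uniform)), a standard correction for the
balanced-sampling bias that would otherwise flood rare-lesion classes with
false positives.

Quantization replaces every weight by a signed sum of at most S distinct
terms from {2^-1, …, 2^-S} (default S = 3), so a multiplier becomes a few
shifts and adds; the representable set is {k·2^-S : |k| ≤ 2^S − 1} and the
quantizer returns the nearest element, ties toward smaller magnitude.
Error diffusion adds the cumulative signed error of all earlier weights to
the value being quantized while recording each error against the original
weight; it drives the average signed error toward zero.  Conventions and
refinements:

* Pre-scaling is per output neuron (per weight-matrix column): the column
  is divided by a power of two so entries are fractional — undoing the
  scale is itself a bit-shift.  Candidate scales are the smallest covering
  power of two and its two halvings (outliers then saturate at the
  representable extreme); the candidate with the smallest reconstruction
  error wins, measured through calibration activations when a calibration
  patch set is supplied.
* Diffusion runs down each fan-in column in input-index order; adjacent
  patch pixels are correlated, so consecutive errors partially cancel in
  the pre-activation.
* With calibration, the mean quantization-induced shift of each layer's
  pre-activation is absorbed into the (float) biases — biases feed adders,
  not multipliers, so this keeps the forward pass multiplier-free.
* The quantized forward pass uses a piecewise-linear tanh with slopes
  1, 1/2, 1/4, 0 (breakpoints 0.5, 1, 2); it is odd, continuous,
  non-decreasing, bounded by ±1 and within 0.06 of tanh everywhere.

Under these choices the quantized segmenter agrees with the float one on
more than 90% of pixels at S = 3 on the synthetic fixtures.

## Adaptive Gabor features

Kernels follow G(x,y) = g_sigma(x,y) · exp(2·pi·j·mu·(x cos θ + y sin θ))
sampled on a (2k+1)² integer grid (x = column offset, y = row offset,
row-major).  The kernel mean is subtracted (DC removal) so constant
illumination yields zero response; filtering is correlation under reflect
padding (FFT-based).  Per-tile adaptation estimates θ from the structure
tensor's dominant gradient orientation, mu from the radial FFT magnitude
peak (DC excluded, Hann window), and sigma = 0.56/mu (about one octave);
flat tiles fall back to configured defaults with a flag.  A fixed fallback
bank (default θ ∈ {0°,…,150°} step 30°, mu ∈ {0.05, 0.1, 0.2} c/px;
support 2k+1 ≥ 6·sigma) provides mean / standard deviation / energy of the
response magnitude per 4×4 tile.

When a segmentation map is supplied the feature vector adds per-class
response statistics plus grading-oriented segmentation summaries: per
class, log area and connected-component count after discarding components
under 4 px and the classic false-positive modes (microaneurysm components
lying on vessels, hard-exudate components on the optic disc); per-tile
log areas; hard-exudate distance to the field centre and its load split
into three macula-centred bands at R/6 and R/3; total lesion count; and
dark-blob evidence split by adjacency to the main vessel component with
its local thickness (neovascular tufts are thick blobs attached to the
vessel tree, haemorrhages are isolated — the per-pixel classifier cannot
tell the two apart from a 9×9 patch, so the split is structural).

## Feature selection

Trees split on the Gini gain; feature importance is the per-tree average
of the gains at the feature's split nodes, normalized by the maximum.
Selection is two-stage: an unpenalized forest supplies Imp_norm, then a
second forest splits on lambda_i · gain with
lambda_i = 1 − gamma + gamma · Imp_norm applied to features not yet used
on the current tree-building path; features used by stage-2 splits whose
stage-2 normalized importance (accumulated as the penalized gain the trees
actually maximize) clears the threshold are returned, ranked.

Because the importance sums split gains *without* node-size weighting,
gains on statistically tiny nodes are pure noise; the defaults therefore
forbid splits below a quarter of the training set (min 10) and draw a
large candidate set per split (mtry = 0.4 d) so informative features are
visible to the penalty.  Library defaults: gamma 0.7, threshold 0.05,
200 trees, unlimited depth.  The pipeline, which screens ~500 mostly
redundant texture features, uses gamma 0.5 / threshold 0.01 and passes the
top 12 to the classifier.

## Classifier and chicken swarm optimization

The classifier is the module pattern — convolution + pooling modules (valid
cross-correlation, max pooling default) followed by fully connected layers
— whose entire weight vector is optimized by the chicken swarm algorithm;
there is no backpropagation.  Feature-vector inputs may be reshaped onto a
zero-padded square grid for the conv stack (`mode='cnn'`) or fed straight
to the fully connected layers (`mode='mlp'`); the pipeline uses the MLP
head with no hidden layer (a linear softmax over the ~12 selected,
standardized features), which keeps the search space near 100 dimensions —
where a derivative-free swarm is effective — and measurably matches the
accuracy of gradient-trained linear baselines on the same features.

Swarm details: members split by fitness rank into roosters (20%), hens
(60%, half of them mothers) and chicks; a rooster moves multiplicatively
A·(1+N(0, s²)) with s² = 1 unless outclassed by a random other rooster, in
which case s² = exp((fv_l − fv_m)/(|fv_m|+eps)) < 1; a hen moves toward
its rooster (scale S1 = exp((fv_m − fv_ro1)/(|fv_m|+eps))) and toward a
random other member (S2 = exp(fv_ro2 − fv_m)); a chick follows its mother
with FL ~ U[0, 2].  Roles are refreshed from the ranking every G = 10
steps and the best-ever position is archived.  Two implementation choices
matter in practice and are deliberate: (i) per-individual greedy
acceptance — a member keeps its move only if fitness improves — which
extends the elitist archive down to individuals and prevents the swarm
from abandoning good regions when a rooster's multiplicative kick lands
badly (without it the swarm stalls on classification landscapes); and
(ii) optional independent restarts keeping the fittest run (pipeline
default 2).

Fitness is the misclassification rate over the training rows plus a
bounded cross-entropy tie-break evaluated on a stratified held-out quarter
of the training data, scaled strictly below one error step — so the error
rate always dominates and the cross-entropy only orders candidates inside
an error plateau (which is what lets the swarm descend between plateaus).
Search bounds are [−4, 4] per weight for the pipeline (standardized
features need coefficients above 1), swarm size 60, 5000 steps.

## Pipeline and evaluation

`run_pipeline` executes generate → preprocess → segment → extract →
select → train → evaluate with one seed; every stage seed derives from it,
so a run is reproducible from (config, seed) alone.  The split is
stratified 80/20 by joint label.  Evaluation reports accuracy and
macro-averaged one-vs-rest sensitivity, specificity, precision and F1 from
the multi-class confusion matrix; preprocessing quality is reported as
RMSE / PSNR (dB, 8-bit range, infinite for identical rasters) / SSIM / MSE
of the denoised raster against its input.  The default study runs 200
samples over the 8 balanced joint grades (160 train / 40 test); at these
sizes a full run takes a few minutes on one CPU core.

## Numerical conventions and degenerate inputs

* Quantizer ties round toward smaller magnitude; out-of-range diffusion
  targets clamp to the representable extreme.
* Histogram equalization passes constant images through unchanged.
* Wavelet boundary handling is symmetric padding; reconstructions are
  cropped to the source shape; requesting more levels than the image
  supports reports the feasible maximum.
* Zero-variance Gabor tiles return the configured default parameters with
  a fallback flag; empty per-class pixel sets yield zero statistics and a
  unit distance sentinel (1.0, in image-height units) for "no exudate".
* Forest splitting needs at least two classes and finite features; all-
  zero-gain forests yield all-zero normalized importances and an empty
  selection.  Importance ties would normalize to 1 jointly; ranking breaks
  ties toward the lower feature index.
* Swarms need N ≥ 4 so every role is populated; exponent arguments are
  clipped at ±50 before exp().

## Known limitations

* Severe-NPDR vs proliferative discrimination rests on the structural
  tuft evidence; the per-pixel classifier cannot label tuft interiors as
  vessel, so this distinction is the pipeline's weakest.
* Microaneurysm pixel recall is modest (~0.3–0.6 depending on conditions);
  counts remain informative because precision is controlled by the prior
  correction and the component-size filter.
* The end-to-end accuracy is measured on 40 held-out samples per seed, so
  single-seed figures carry a binomial standard error of about ±0.08.
* The CSA classifier underfits relative to gradient training on the same
  features when the weight space grows beyond a few hundred dimensions;
  the pipeline's linear head is sized accordingly.
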