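# Methods

`slideattn` implements a weakly-supervised pipeline for predicting a
binary slide-level label — lymph-node metastasis (LNM) status in
muscle-invasive bladder cancer — from H&E whole-slide images (WSIs),
together with the clinical and combined logistic classifiers used to
benchmark it and the statistics used to compare them. This note records
the models, the choices made where the design was open, and what the
synthetic experiments do and do not establish.

## The multiple-instance model

A WSI is a bag of patch-level instances with one binary label. Under the
standard MIL assumption a positive bag contains at least one positive
instance (a "witness"); a negative bag contains none. Instance labels are
never observed in real data.

Each patch is encoded to a feature vector `h_k` (dimension `d`). Gated
attention pooling scores every instance,

    e_k = w^T ( tanh(V h_k) ⊙ sigmoid(U h_k) ),     a = softmax(e),

and forms the bag embedding `z = Σ_k a_k h_k`, which a linear head maps
to two class scores. The attention weights `a` are simultaneously the
per-patch importance scores used for interpretation.

Training minimizes the binary smooth top-1 SVM loss

    L(s, y) = τ · log Σ_{j∈{0,1}} exp( (α·1[j≠y] + s_j − s_y) / τ ),

a temperature-smoothed multiclass hinge: as τ→0 it converges uniformly
(gap ≤ τ·log 2) to `max_j(α·1[j≠y] + s_j − s_y)`. Defaults τ = 1,
α = 1 (the smoothed-hinge literature's common values; nothing in the
problem fixes them).

Optimization: Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e−4, ℓ2 weight
decay 1e−5, one bag per step (bags have variable size), at most 200
epochs, early stopping when the monitored loss fails to improve its best
value by a relative 1e−4 for 20 consecutive epochs; the best-epoch
weights are kept. The monitored loss is the training-fold loss by
default; validation-loss monitoring is available (`monitor="val"`).

Open design points, and what we chose:

* **Attention hidden size.** We default to `L = min(128, 4·d)`. A fixed
  wide layer (L = 128) at small feature dimension is badly conditioned:
  on 10-dimensional benchmark bags it fails to optimize (training AUROC
  stalls ≈0.85) while any L ≤ 4·d trains to zero loss. At realistic
  feature dimensions (d ≥ 32) the default recovers L = 128.
* **Initialization.** The attention score vector `w` starts at zero, so
  attention begins exactly uniform and V/U break the symmetry. A random
  `w` can lock attention onto an arbitrary direction early, and at a
  1e−4 learning rate it never recovers.
* **Restarts.** The attention objective is non-convex and single runs
  occasionally sharpen attention onto a spurious instance (a distinct
  local optimum reached in roughly a quarter of seeds on the benchmark).
  `train` therefore runs 3 independent initializations and keeps the one
  with the best final training-side loss; held-out data never enters the
  selection. Deterministic given the caller's seed.
* **Head.** A single linear layer from the pooled embedding to two class
  scores — the minimal head consistent with the two-score loss.
* **Patient-level prediction.** A patient's score is the mean of their
  slides' positive-class probabilities (`CVResult.patient_scores`);
  slide-level scores are also reported.

Cross-validation is five-fold, split at the *patient* level and
stratified by label, so slides of one patient never straddle folds; each
slide receives exactly one out-of-fold score, and the fold assignment is
shared with the clinical classifiers.

## Image preprocessing

* **Foreground.** Otsu's threshold (maximal between-class variance) on
  the HSV saturation channel of a 32×-downsampled thumbnail after a 3×3
  median filter: tissue is chromatic, glass is near-achromatic. The
  histogram scan keeps one candidate per distinct partition (cuts
  through empty bins duplicate their left neighbour) and returns the
  first maximizer within a 1e−10 relative tolerance, so exact ties are
  broken low rather than by round-off.
* **Tiling.** Non-overlapping 448×448 patches at 0.5 µm/px (20×), stride
  equal to the patch, partial edge patches dropped, coordinates 0-based
  and half-open in base-level pixels. A patch is emitted when ≥ 50% of
  its footprint is foreground (configurable); slides at other
  resolutions are resampled bilinearly, refusing upsampling beyond 8×.
* **Blank filter.** A pixel is background when its grayscale intensity is
  ≥ 220/255 or its HSV saturation is ≤ 0.05; a patch is excluded when its
  background fraction *strictly exceeds* 80%.

## Stain normalization

In optical density (Beer–Lambert, `OD = −log10((I+ε)/I₀)`, ε = 1 grey
level, I₀ = 255) stains mix linearly: `OD = C·S` with `S` the 2×3 stain
matrix (unit-norm, non-negative rows) and `C ≥ 0` the concentrations.
`S` is estimated by sparse NMF — `min ½‖OD − C S‖² + λ‖C‖₁` over
C ≥ 0, S ≥ 0 — solved by exact alternating minimization: both blocks are
two-variable non-negative quadratic programs solved in closed form by
active-set enumeration, fully vectorized over pixels. λ defaults to 0.1;
the fit uses ≤ 10,000 non-background pixels; initialization at the
classical H&E vectors. Rows are ordered by the convention that
hematoxylin has the larger OD_red/OD_blue ratio (it transmits blue).

Normalization keeps the source concentration field, scales each stain by
`ref_99th / src_99th` percentile concentrations, and recombines with the
reference stain matrix — structure is preserved up to a per-stain
positive scaling. The concentration transform at mapping time is the
exact unpenalized NNLS (the percentiles are computed with the same
transform so the ratio is consistent). The shipped reference model is
fitted on a synthetic H&E-like fixture rendered from the classical
vectors, so no image data ships with the package.

Identifiability caveat: the stain matrix is only well determined when
some pixels are (nearly) single-stain, as in real tissue (nuclei ≈ pure
hematoxylin, stroma ≈ pure eosin); the synthetic H&E generator therefore
plants a fraction of near-pure pixels, and its stain-matrix jitter
preserves each stain's chromatic identity — real staining variation
never turns hematoxylin into eosin.

## Features and reduction

The encoder is pluggable (any callable patch → vector with a declared
`dim`). The default offline encoder is a seeded Gaussian random
projection of the 56×56 thumbnail; a pretrained CNN trunk (2048-d
global-average-pooled features) plugs into the same interface. The
reducer is a single-hidden-layer autoencoder (in → hidden ReLU → in
linear, MSE, Adam, lr 1e−3, batch 256), mirroring a 2048 → 512 reduction
at full scale; training can subsample 200 patches per slide. Feature
standardization (per-dimension z-scoring) is fitted on training folds
only.

## Heatmaps

Raw attention sums to one over a variable patch count, so display scores
are percentile ranks (fraction of patches with strictly smaller raw
score plus half the tie fraction) min-max rescaled to [0, 1] — invariant
under any strictly monotone transform of the raw scores; plain min-max
is available by flag. Rendering fills each patch footprint with a fixed
blue-white-red ramp (control points (0,0,255) / (255,255,255) /
(255,0,0)) alpha-blended at 0.6 over the (optionally downsampled) slide;
uncovered pixels are untouched. Top-k patch selection (default k = 15)
breaks ties by ascending (y, x).

## Clinical and combined classifiers

Logistic regression of LNM status on age (years), gender (male = 1), pT
stage (ordinal 2/3/4, one coefficient per step), LVI (0/1), and
histologic grade (high = 1); the combined model adds the MIL slide score
on its probability scale as one continuous covariate. Missing clinical
values are handled by complete-case exclusion. Fits are Newton/IRLS to
tight tolerance with Wald standard errors; reports give coefficient,
p-value, and `exp(β)` with 95% Wald CIs. Perfect separation and
collinear designs raise explicit errors. Cross-validated evaluation
reuses the MIL fold assignment, and only out-of-fold MIL scores enter
the combined model.

## Evaluation statistics

* AUROC in Mann–Whitney form (ties count ½), computed via midranks.
* CIs from per-fold AUROCs as mean ± 1.96·sd/√k truncated to [0, 1]; for
  external-style evaluation the same formula applies to per-repeat
  AUROCs from independent training seeds.
* DeLong's paired test from per-sample structural components (V10/V01
  with the 1/½/0 kernel), two-sided normal p; a zero-variance difference
  returns p = 1 with the degenerate-comparison convention.
* Pearson chi-squared on 2×2 tables without continuity correction by
  default (cells in the intended use are large); Yates by flag.

## The synthetic data: what it emulates and what it does not

* **Feature bags** instantiate the MIL assumption exactly: positive bags
  receive `max(1, round(witness_rate·bag_size))` witness instances drawn
  from N(μ_pos, σ²I), everything else from N(μ_neg, σ²I). Defaults
  (200 bags of 50 instances, d = 10, witness rate 0.1, μ gap 1 per
  dimension at σ = 1) put an oracle detector near AUROC 0.99, i.e.
  detectable but not trivial.
* **Toy slides** are rendered textures with a per-pixel ground-truth
  mask: near-white background (≥ 235), tumor as dense purple nuclei on
  violet, plain stroma as pink oriented strokes, and — only on positive
  slides — inflamed stroma: pink strokes under a dense small dark-blue
  infiltrate, the discriminative class (mirroring the association
  between peritumoral lymphocytic inflammation and node status that
  attention analysis surfaces on real slides). The inflamed regions are
  compact (about one patch footprint each, 1–2 per slide), so the
  discriminative tissue is a small fraction of the slide, as in reality.
  The infiltrate is dense enough to dominate a patch's color statistics;
  a linear encoder can then see it, which is what the default random
  projection relies on.
* **Cohorts** draw covariates with marginals typical of
  muscle-invasive bladder cancer series (~40% LVI+, ~75% male, ~93%
  high-grade, pT3 modal) and labels from a logistic model with known
  coefficients, enabling parameter-recovery tests.

None of this claims histological realism; passing tests show the
pipeline's mechanics and statistics are correct under the stated
generative assumptions, not that the model reaches any particular
performance on real cohorts.

## Problem sizes used in validation

The validation protocol (tests and `scripts/acceptance.py`) runs at
scaled-down sizes chosen for a single-CPU workflow:

* MIL benchmark: 200 training / 50 held-out bags (50 instances, 10-d,
  witness rate 0.1); expectation: held-out AUROC ≥ 0.95 and higher mean
  attention on witnesses in ≥ 95% of positive test bags.
* End-to-end slide study: 40 slides of 1792² px tiled at 224 px (so each
  bag holds ~20–36 patches and the inflamed region covers a small
  fraction of them), random-projection encoder (d = 128), stain
  normalization to the shipped reference, five-fold CV with the
  optimization-step budget matched to the benchmark (~40k bag steps,
  i.e. max_epochs 1250 at 32 training bags, patience 100); expectation:
  out-of-fold AUROC ≥ 0.9 and higher mean normalized attention inside
  planted inflamed regions than outside for ≥ 90% of positive slides
  (patches count as "inside" from 5% footprint overlap).
* DeLong calibration: 2000 null datasets (n = 100; both classifiers read
  one latent signal through exchangeable noise) — type-I error at
  α = 0.05 within [0.03, 0.07].
* Stain recovery: 10 synthetic H&E images from known jittered stain
  matrices — cosine ≥ 0.99 per stain vector, self-normalization mean
  absolute difference ≤ 5 grey levels.
* Logistic recovery: n = 2000, LVI = 1.0 and pT = 0.5 recovered within
  ±0.2. (The intercept and the rare-category grade coefficient have
  standard errors above that band at this n and are not part of the
  check.)
* Reducer: data in an exact low-dimensional subspace reconstructed to
  MSE ≤ 1e−3 (≤ 1e−6 for rank-1), with the optimization budget extended
  (400–500 epochs at lr 5e−3) at the small test dimensions.

## Known limitations

* No pyramidal/vendor WSI readers: slides are plain TIFF/PNG arrays in
  memory; gigapixel inputs need a tiled reader in front of the library.
* No pen-mark, blur, or artifact detection.
* The smooth top-1 SVM loss is implemented for the binary case only.
* The NumPy training loop is single-threaded; it is sized for the
  synthetic studies, not for training on real cohorts at scale.
* Stain separation assumes exactly two stains and benefits from
  near-pure pixels; images violating that (e.g. heavy background ink)
  will fit poorly.
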