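# Methods

This note records the models, conventions, defaults and design decisions
behind `scentpipe`, at the level of detail a maintainer or reviewer needs
to judge what the package's tests do and do not demonstrate.

## Data model

A raw sample is the matrix I(t, m) of ion counts over a strictly
increasing retention-time axis (minutes) and a raw (possibly non-integer)
m/z axis. The on-disk carrier is a plain CSV matrix (first column time,
header row m/z, integer counts round-trip bit-exactly); mzML is supported
through pyteomics as an optional extra, mapping MS1 spectra onto the union
m/z grid by nearest channel. NaN anywhere is treated as corruption and
grounds for rejecting the sample in `validate_dataset` — never imputed —
mirroring the practice of excluding corrupted acquisitions from multi-site
cohorts.

## Preprocessing stack

Default order: round → quantile noise correction → baseline drift
correction → internal-standard normalization, each stage toggleable and
reorderable via `PreprocessConfig.stages`. (Published descriptions of
such stacks disagree among themselves about whether baseline correction
precedes or follows quantile correction; we follow the detailed numbered
convention and surface the order as configuration.)

* **Rounding** (half-up, so 23.5 → 24): channels sharing a rounded bin are
  summed; total ion count is conserved exactly. Half-up avoids the
  parity-dependent binning of banker's rounding.
* **Segmentation**: N = ⌈T_total/ΔT⌉ equal frames tiling [0, T_total];
  41 min at ΔT = 1.5 gives 28 frames of width 41/28 ≈ 1.46 min.
* **Quantile correction**: within each (frame, bin) cell, the
  15th-percentile threshold uses sorted linear interpolation at rank
  (n−1)q — numpy's default — and is subtracted with clamping at 0.
  One subtlety is worth stating precisely: with this interpolating
  quantile, the corrected cell's *interpolated* q-quantile is not exactly
  zero on tie-free data (it is a fraction of the gap between the
  neighbouring order statistics), and a second application subtracts that
  small residue. The exact statements — zero quantile and idempotence —
  hold under the floor-rank quantile, and the tests assert exactly that,
  bounding the interpolation residue by the gap between the flanking
  order statistics (the provable bound). On real ion
  counts the point is mostly moot because baseline counts are heavily
  tied.
* **Baseline drift**: per-channel modified-polynomial fitting (iteratively
  refit a degree-2 polynomial after clipping the working signal to the
  current fit until convergence), subtracted and clamped at 0. Degree 2 is
  the default because the drifts this removes are slow, smooth trends; a
  TIC-only mode exists for users who prefer correcting the summed trace.
  The routine is implemented in-package with numpy polynomial fits.
* **Mirex normalization**: the internal standard elutes in the
  29.4–29.8 min window. Its area is the trapezoidal integral of the
  maximum-area contiguous above-baseline run of the windowed TIC. The peak
  is called *undetected* when that area is below 5× the window's median
  noise-floor area (median of the lower half of the window's TIC samples
  times the window width — a robust baseline estimate that ignores the
  peak itself). Detected samples are rescaled to a common reference area;
  undetected samples are left unscaled per sample and, at dataset level,
  rescaled by the median scale factor of detected samples from the same
  source batch. Normalization runs after noise/baseline correction by
  default, so the area is measured on cleaned signal.

## Empirical-Bayes batch correction

Model: for batch b and feature g, the observed value is
x = α_g + δ_bg·(clean deviation) + γ_bg, with multiplicative scale
distortions δ_bg > 0 and additive shifts γ_bg. Fitting proceeds as in the
classic empirical-Bayes batch-adjustment template:

1. Standardize each feature by its grand mean α_g and pooled
   *within-batch* SD (so pure location shifts do not inflate the scale;
   variance floored at 1e-8).
2. Naive per-(batch, feature) estimates: γ̂ = standardized batch mean
   offset; δ̂ = batch SD over pooled SD.
3. Batch-level hyperpriors across features: γ ~ N(μ, σ²) by ML
   (mean/SD); δ ~ G(α, β) by ML (log-moment shape approximation refined by
   Newton on log a − ψ(a) = s, with a cap for near-degenerate samples).
   Because the naive estimates carry sampling noise that inflates the
   fitted prior spread (at 30 samples per batch the gamma shape would be
   biased low by ~9%), a moment-level sampling-noise correction is applied
   by default: the SD-ratio c₄ bias constant rescales the mean and the
   expected sampling variance is removed from the fitted spread before
   re-forming (α, β) and σ.
4. Shrinkage: γ* is the standard precision-weighted posterior mean between
   γ̂ (weight n_b·τ²) and μ (weight δ̂²); δ* is a pseudo-count blend
   (n_b·δ̂ + α·E[δ])/(n_b + α), using the gamma shape as the prior's
   effective sample size — the gamma prior is not conjugate for a scale
   likelihood, so this documented approximation stands in for the exact
   posterior mean.
5. Adjustment: x_adj = (x − α_g − γ*)/δ* + α_g, optionally clamped at 0
   for count-like data.

**Identifiability.** An additive shift common to *all* batches is
indistinguishable from the grand location and is absorbed into α_g; only
between-batch contrasts are estimable. For simulations where the clean
data live on a known reference scale, `fit_eb` accepts
`reference_location` / `reference_scale`, which is how the
hyperparameter-recovery tests make the shift-prior mean identifiable.

**Order preservation.** The adjustment preserves within-sample feature
ordering only up to the per-feature spread of α_g and of the estimated
corrections: for feature pairs whose gap is below that spread, the
α_g(1 − 1/δ*) term can flip the order even under feature-constant
contamination. The property test therefore asserts order preservation for
clearly separated pairs; it is not a universal guarantee.

**Audits.** `source_clustering_audit` runs k-means (20 restarts, fixed
seed) on standardized features and reports accuracy after
maximum-accuracy (Hungarian) cluster-to-site matching; chance is ~1/k,
though the optimistic matching sits slightly above it on pure noise.
`pca_audit` reports the ratio of mean between-centroid distance to mean
within-batch spread in the first two PCs.

## Image encoding

Heatmaps place time on x, m/z on y (low m/z at the bottom), resampled to
256×256 by area-weighted binning, with intensity mapped through log1p and
per-image min-max to 8 bits and colored by a fixed monotone-lightness
lookup table computed analytically in code — so encoding is deterministic
and ordering-preserving, and a global intensity rescale leaves pixel
ordering unchanged up to 8-bit quantization. Per-image normalization is
the default (global dataset-level normalization is available; it changes
what a downstream classifier can learn, notably erasing per-sample scale).
The pseudo-3D projection draws one trace per channel back-to-front with a
fixed oblique shear. Compression of a full-scale run
(≈3.5e6 values × 32 bits) into one image is
(3.5e6·32)/(256·256·3·8) ≈ 71.2.

## Domain-adversarial classifier

Built on a small in-package numpy neural-network kernel (im2col 3×3
convolutions, ReLU, average pooling, dense layers, batch norm, Adam,
float64) with exact, finite-difference-verified gradients — deliberately
framework-free so the gradient-reversal contract is directly auditable.

* **Backbone** (`small_cnn`): four 3×3 conv blocks (8, 16, 32, 32
  channels; 2× average pooling after the first three) on 32×32 inputs
  (images average-pooled down and standardized per image), then a dense
  projection to a 32-dimensional latent with batch normalization. The
  latent batch norm is load-bearing: it forces unit variance per latent
  dimension, which removes the degenerate "collapse everything to a
  constant" solution of adversarial training. A ResNet18 option is not
  provided in this build; the config rejects it explicitly.
* **Heads**: linear disease head (3 classes, cross-entropy); linear
  source head (one logit per site, cross-entropy).
* **Reversal contract**: the source head itself *minimizes* L_q; the
  backbone receives −λ·∂L_q/∂θ from the source branch (identity forward,
  negated and λ-scaled backward). The logged objective per epoch is
  L_total = L₀ − λ·L_q, and the identity is exact on logged values.
* **Maximally trained adversary**: a gradient-reversal game against a
  lagging adversary is won by stepping the features across the current
  decision boundary — which raises the online L_q while leaving the
  source fully decodable to any freshly trained classifier. (This is
  exactly the failure mode that residual-bias probes expose.) The source
  head is therefore refit to L2-regularized optimality (multinomial
  logistic regression, C = 1) on the current frozen latent features twice
  per epoch; between refits it also descends its own gradient. Against a
  near-optimal adversary the only way to raise L_q is genuine mixing of
  the sources in latent space.
* **Schedule**: λ is held at 0 for the first 25% of epochs (letting the
  disease signal form) and then ramped sigmoidally to its configured
  value; the main learning rate (Adam, 2e-3) follows a cosine decay so
  the tug-of-war settles by the final epoch. Gradients are clipped at
  global norm 5. Defaults: 45 epochs, batch 25, seed-deterministic
  initialization and batch order.
* **Residual-bias probe**: freeze the backbone, train a fresh
  logistic-regression source classifier on the latent features, and
  report stratified 5-fold cross-validated accuracy. This is the
  package's quantitative residual-bias measure; chance is 1/n_sources.

## Synthetic data: what it emulates, and what it does not

The generator draws, per sample: Gaussian peaks (σ ≈ 0.1–0.22 min) with
sparse Dirichlet-weighted m/z fingerprints from a fixed library (the
library seed is independent of the dataset seed, so different datasets
share one "chemistry"); class-dependent amplitude multipliers
(1.0 / 1.8 / 2.8 for Control / LowRisk / HighRisk) on three signature
peaks with 15% lognormal per-sample jitter; a strong internal-standard
peak at 29.6 min (amplitude 20000, σ = 0.05 min — a spiked internal
standard is by design a dominant peak in a quiet elution window, which
the peak library keeps clear) with 5% dropout; per-sample multiplicative
factors from per-site gamma priors (default means 0.6 / 1.0 / 1.6 / 2.4
at shape 50) and additive shifts from per-site normal priors (means 0,
30, 60, 90; SD 5); two persistent per-site stripe channels (amplitude
150, minutes 4–36) emulating steady instrument artifacts at fixed m/z;
a degree-2 drift polynomial (±30 counts) and a truncated-normal noise
floor (mean 20, SD 5). The default grid is 1000 timesteps × 64 channels
over 41 minutes — a desk-scale stand-in for the full ≈7300 × 480 grid,
which remains available by config but is not what the tests run.

The image-classification fixture used in the adversarial tests is a
smaller grid (400 × 32, 8 peaks) with the same structure; its
`class_source_correlation` parameter skews each site's class mix toward
one dominant class (probability ρ + (1−ρ)/3), producing the regime where
a classifier can cheat by reading the site.

What the generator does **not** emulate: real fragmentation chemistry,
retention-time warping between runs, co-eluting compound overlap,
non-separable peak shapes, and inter-site differences beyond
location/scale/stripe structure. Consequently, passing tests demonstrate
that the pipeline removes the *modeled* bias classes and preserves the
*modeled* class signal at these effect sizes — not that it would achieve
any particular accuracy on clinical data, where the class signal is far
subtler and bias is only partly captured by this family of distortions.

## Evaluation conventions

Stratified 5-fold cross-validation with shuffled, seed-deterministic
splits; fold confusion counts are summed before pooled metrics are
computed (per-fold accuracies reported as mean ± SD alongside).
Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), macro
averages are unweighted class means, and zero-division cases report 0
with an explicit flag. The two-class view maps LowRisk and HighRisk to
PCa+ in both truth and prediction of the *same* three-class model (no
binary retraining), so merged accuracy can only rise.

## Numerical choices and degenerate inputs

Quantile: numpy linear interpolation (see above). Variance floors: 1e-8
on feature scales; factor estimates floored at 1e-6. Gamma ML shape
capped at 1e8 for near-constant inputs. Empty segment cells, single-source
training with λ > 0, unseen batch labels at correction time, and k > n
clustering are hard errors; an undetectable Mirex peak is a flagged
fallback, not an error. All randomness flows through
`numpy.random.default_rng(seed)`; training, generation and probing are
bit-deterministic given seeds.

## Known limitations

* The adversarial equilibrium is stochastic: probe accuracies at λ > 0
  fluctuate by a few percentage points across seeds; claims about λ
  trends are therefore made on medians over 5 seeds.
* The gamma prior's posterior for scale factors is approximated by a
  pseudo-count blend (non-conjugacy), and hyperparameter recovery of the
  shift-prior spread runs close to the information limit at 500 features.
* Batch correction models location/scale distortions only; the
  adversarial stage exists precisely because real residual bias is richer
  than that.
* The CLI covers the core workflows but is a thin convenience layer; the
  library API is the primary interface.
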