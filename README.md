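# scentpipe

Machine-olfaction analysis of GC-MS urine volatilomics for prostate-cancer
risk classification. Instead of reducing a chromatogram to a list of named
compounds and concentrations, `scentpipe` treats the full time × m/z ion
intensity surface I(t, m) as the object of interest: it cleans it, removes
source-site batch effects, renders it as a fixed-size image, and classifies
the image with a small convolutional network trained adversarially so that
the collection site cannot be read back out of its latent features.

It is written for researchers working with multi-site GC-MS cohorts —
where principal-component analysis of raw signal routinely clusters
samples by *hospital* rather than by disease — and for anyone who wants a
self-contained, dependency-light reference implementation of
empirical-Bayes batch correction plus gradient-reversal domain-adversarial
training with honest residual-bias audits.

## What it does

**Preprocessing** (per sample): m/z values are rounded to integer bins,
m = round(m/z_raw); the run is tiled into N = ⌈T_total/ΔT⌉ frames (41 min
at ΔT = 1.5 gives N = 28); within each (frame Tᵢ, bin m) the lowest
15th-percentile intensity Q₁₅(Tᵢ, m) is subtracted with clamping,
I_corr = max(I − Q₁₅, 0); a per-channel modified-polynomial baseline is
removed; and the whole sample is rescaled so the internal-standard (Mirex)
peak area in the 29.4–29.8 min window matches a common reference.

**Batch correction**: per-feature standardization followed by
empirical-Bayes shrinkage of per-(site, feature) additive shifts
(normal prior N(μ, σ²)) and multiplicative scale factors (gamma prior
G(α, β), hyperparameters fit by maximum likelihood across features), then

    x_adj = (x − α_g − γ*) / δ* + α_g.

k-means and PCA audits quantify how much site structure survives.

**Imaging**: the corrected surface is encoded as a 256×256×3 8-bit image
(heatmap or pseudo-3D peak projection; ~71× compression of a full-scale
run), optionally as 28 zoomed tiles.

**Adversarial classification**: a small CNN backbone feeds a disease head
(Control / LowRisk / HighRisk) and a source head through a gradient
reversal layer; the optimized objective is

    L_total(θ, λ) = L₀(θ) − λ·L_q(θ),   λ ∈ [0, 1].

A frozen-feature *residual-bias probe* — a fresh linear classifier trained
on the latent features — reports how much site information survives.

**Evaluation**: stratified 5-fold cross-validation, pooled confusion
matrices, per-class precision/recall/F1, and a two-class view merging
LowRisk + HighRisk into PCa+.

Because the underlying clinical chromatograms are not publicly deposited,
the package ships a first-class synthetic-data generator
(`scentpipe.synthetic_data`) producing datasets with known ground truth:
Gaussian peaks with m/z fingerprints, class-dependent signature peaks, a
Mirex peak with dropout, site-specific gamma/normal batch effects,
persistent stripe artifacts, drift, and a noise floor.

## Worked example

```python
import numpy as np
from scentpipe.synthetic_data import SimConfig, generate_dataset
from scentpipe.preprocess import round_mz, segment_time
from scentpipe.batch_correct import (
    build_feature_matrix, fit_eb, apply_eb, source_clustering_audit,
)

cfg = SimConfig(n_per_cell=10, seed=1)       # 4 sites x 3 classes x 10
dataset, truth = generate_dataset(cfg)
binned = [(round_mz(c), m) for c, m in dataset.records]
fm = build_feature_matrix(binned, segment_time(41.0, 1.5))

print("k-means site audit, raw      :", round(source_clustering_audit(fm), 3))
corrected = apply_eb(fm, fit_eb(fm))
print("k-means site audit, corrected:", round(source_clustering_audit(corrected), 3))
```

prints

```
k-means site audit, raw      : 0.992
k-means site audit, corrected: 0.3
```

i.e. before correction a trivial k-means recovers the collection site for
99% of samples purely from batch structure; after empirical-Bayes
correction it falls to near the 25% chance level for four sites. The same
audit motivates the adversarial stage: train with
`scentpipe.adversarial.train_adversarial(images, risks, sources,
AdvConfig(lam=0.5))` and measure what is left with
`residual_bias_probe(...)`.

A CLI mirrors the library: `scentpipe simulate | validate | preprocess |
debias | imagify | train | probe | evaluate` (see `scentpipe --help`).

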