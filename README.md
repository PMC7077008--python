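# glandrisk

Gland-morphometry recurrence-risk pipeline for early-stage colon
adenocarcinoma (ECA) histology.

In early-stage (node-negative) colon adenocarcinoma only about one
patient in five relapses, yet routine H&E grading separates these
patients poorly. The architectural signal is in the glands: aggressive
tumors show disordered gland *orientation* (neighboring glands no
longer align) and heterogeneous gland *shape* (irregular, convoluted
boundaries). `glandrisk` turns digitized H&E tissue-microarray cores
into a locked binary recurrence classifier built on exactly that
signal, and validates it the way a pathology study would: confusion
metrics, chi-square associations, Kaplan–Meier / log-rank survival
contrasts and Cox proportional-hazards regression.

## What it computes

For each image the pipeline segments glands (or imports external
contours), then extracts a frozen catalog of 386 named morphometric
features in three families:

1. **Shape/size aggregates** — per-gland area, perimeter, circularity
   `4πA/P²`, eccentricity, solidity, minor/major axis ratio,
   equivalent diameter, box-counting fractal dimension of the boundary
   and ten boundary-Fourier harmonics, aggregated image-wide by
   mean/SD/median/range.
2. **Local disorder statistics** — each descriptor's mean, SD, entropy
   and energy over every gland's k-nearest-neighbor neighborhood,
   aggregated image-wide (e.g. `mean_circularity_entropy`,
   `sd_fractal_dimension_energy`).
3. **Orientation-tensor features** — each gland's axial orientation
   θ ∈ [0°, 180°) is quantized into B = 18 bins; orientations of
   neighboring gland pairs form a symmetric B×B co-occurrence matrix
   p(i, j) per gland, from which Haralick-type measures are computed
   with the *circular* bin distance d(i, j) = min(|i−j|, B−|i−j|):
   contrast average Σ d·q(d), contrast energy Σ d²·q(d), contrast
   variance, entropy −Σ p log₂ p, energy Σ p², information measures
   IMC1 = (H(X,Y) − HXY1)/max(HX, HY) and
   IMC2 = √(1 − e^{−2(HXY2 − H(X,Y))}), and marginal statistics —
   reported as image mean and SD (`mean_tensor_*`, `sd_tensor_*`).

Feature selection is greedy minimum-redundancy-maximum-relevance
(mRMR, MID scheme) on features discretized at μ ± σ: the first pick
maximizes I(f; y), each later pick maximizes
I(f; y) − (1/|S|) Σ_{s∈S} I(f; s). The selected features (default
m = 5) feed three candidates — linear SVM, random forest, linear
discriminant — compared by stratified five-fold cross-validation; the
best is **locked** and thereafter immutable.

A synthetic tissue generator (non-overlapping perturbed-ellipse glands
with von Mises axial orientations of concentration κ, pseudo-H&E
rendering, and outcome linkage through the disorder score 1/(1+κ))
makes every stage testable without patient data.

## Worked example

```
glandrisk synth --n-patients 20 --kappa 1.0 --seed 5 --out demo
glandrisk run --images demo --cohort demo/cohort.csv --out demo_run --seed 5
```

The first command writes 20 synthetic cores (PNG images, GeoJSON truth
contours, 16-bit label masks) and a linked `cohort.csv`. The second
segments, extracts features, selects and trains, predicts risk and
runs the survival analysis. A smaller programmatic run:

```python
import pandas as pd
from glandrisk import (SynthConfig, sample_layout, extract_features,
                       mrmr_select, crossval_train, lock_down, two_arm_cohort)

cfgs, cohort = two_arm_cohort(n_per_arm=20, seed=1)   # ordered vs disordered
X = pd.DataFrame([extract_features(sample_layout(c)[0]).values for c in cfgs])
sel = mrmr_select(X, cohort["recurrence"].to_numpy(), 5)
print(sel.selected)
locked = lock_down([crossval_train(X[sel.selected], cohort["recurrence"].to_numpy(),
                                   m, seed=1) for m in ("svm", "rf", "dac")])
print(locked.model_type, round(locked.mean_cv_accuracy, 3))
```

prints

```
['mean_tensor_max_probability', 'mean_fractal_dimension_mean',
 'sd_tensor_contrast_energy', 'sd_tensor_info_measure2',
 'sd_tensor_intensity_average']
svm 1.0
```

— the selector keeps orientation-tensor disorder features, and the
locked linear SVM separates ordered (κ = 20) from disordered (κ = 0.5)
cores perfectly under cross-validation, because the generator links
recurrence almost deterministically to orientation disorder.

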