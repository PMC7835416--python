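# nirkpls

RBF-kernel partial least squares (RBF-PLS) calibration for near-infrared
hyperspectral imaging (NIRHI) data, written for chemometricians building
quantitative quality models of agricultural products — the motivating case
is predicting sugar (SU, %), vitamin C (VC, mg/kg) and organic acid
(OA, g/kg) contents of pomelo fruit from 1000–2500 nm reflectance spectra.

## The method

Classical PLS regresses a response **y** on latent variables of the
predictor matrix **X** (n samples × p wavelengths) and is linear by
construction. NIR spectra of complex tissue respond to every constituent
at once, so the spectrum → analyte map is not linear. RBF-PLS replaces
**X** by the Gaussian kernel Gram matrix

    K_ij = exp(−‖x_i − x_j‖² / σ²)

(note the σ² denominator — not the 2σ² of some textbook conventions),
double-centers it,

    M = K − (1/n)·1·K − (1/n)·K·1 + (1/n²)·1·K·1,

and runs a NIPALS-style iteration with deflation on (M, Y): each latent
component repeats v ← E·u/‖E·u‖, c ← Fᵀv, u ← F·c/‖F·c‖ until v
stabilises, then deflates E ← (I − vvᵀ)E(I − vvᵀ) and F ← F − vvᵀF.
Predictions for any centered kernel block M⁎ (training or test rows vs the
n training samples) follow

    Y′ = M⁎ U (Vᵀ M U)⁻¹ Vᵀ Y  (+ the training mean of Y).

Model capacity is governed by the kernel width σ and the number of latent
variables s; both are selected by exhaustive grid search (the reference
scan is σ ∈ {0.01, 0.02, …, 64.00} — 6,400 candidates — crossed with
s ∈ 1…20) minimising the validation RMSE, with RMSE defined with an (n−1)
denominator and CC the Pearson correlation of predicted vs reference
values. Samples are split 2:1:1 into calibration / validation / testing
(248 → 120/64/64); the selected (σ\*, s\*) is refit on the calibration set
and scored once on the untouched testing set.

The package also covers the two ends of the pipeline: a hyperspectral
ROI extractor (ENVI header+BIL or NumPy cubes → two 5×5 regions of
interest → 50 pixel spectra → one averaged spectrum per sample) and a
synthetic NIR generator with truncated-normal analyte distributions and a
controllable nonlinear spectrum→analyte link, so everything is testable
without instrument data.

## Worked example

```python
import numpy as np
from nirkpls import (SyntheticConfig, generate_dataset, split_samples,
                     compare_with_linear_pls)

ds = generate_dataset(SyntheticConfig(), seed=1)      # 248 samples, 188 bands
split = split_samples(248, (120, 64, 64), seed=1)     # 2:1:1 design
X, ref = ds.spectra.X, ds.reference

res = compare_with_linear_pls(
    X[split.calibration], ref.iloc[split.calibration],
    X[split.validation], ref.iloc[split.validation],
    np.geomspace(0.01, 64.0, 20), np.arange(1, 13))

for a, r in res.items():
    b = r["best"]
    print(f"{a}: sigma*={b['sigma']:.4g} s*={b['s']}  "
          f"RBF-PLS RMSE_V={r['rbf_pls'].rmse:.4g} CC_V={r['rbf_pls'].cc:.3f}  "
          f"PLS RMSE_V={r['pls'].rmse:.4g} CC_V={r['pls'].cc:.3f}")
```

prints

```
SU: sigma*=0.2525 s*=12  RBF-PLS RMSE_V=0.435 CC_V=0.949  PLS RMSE_V=0.5814 CC_V=0.908
VC: sigma*=0.2525 s*=7  RBF-PLS RMSE_V=25.11 CC_V=0.931  PLS RMSE_V=28.02 CC_V=0.915
OA: sigma*=0.2525 s*=10  RBF-PLS RMSE_V=0.3435 CC_V=0.956  PLS RMSE_V=0.513 CC_V=0.896
```

Reading: per analyte, the grid-searched kernel width and component count,
the kernel model's validation RMSE (in analyte units: % for SU, mg/kg for
VC, g/kg for OA) and correlation, and the linear-PLS baseline selected on
the same split. The kernel model reaches lower validation error on all
three analytes because the synthetic spectra carry a quadratic
spectrum→analyte term that a linear model cannot absorb; the selected
σ\* ≈ 0.25 tracks the typical sample-to-sample spectral distance (≈ 0.31
for this seed).

The same workflow is available from a shell:

```sh
nirkpls generate --out fixtures --seed 1 --cubes 3       # synthetic data (+ ENVI cubes)
nirkpls extract-roi fixtures/cube_*.bil \
    --roi 2,2,5,5 --roi 8,8,5,5 --out roi_spectra.csv    # 50 pixels -> 1 spectrum
nirkpls run --config examples/config.yaml --out results  # full pipeline
```

`nirkpls run` writes, per analyte, the validation RMSE/CC surface over the
(σ, s) grid, the selected optimum, a 200-iteration refinement trace, the
validation and testing reports, and the predicted-vs-reference pairs of
the testing set, plus a MANIFEST recording config hash, seeds and
versions.

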