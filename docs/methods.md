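# Methods

## Model

RBF-PLS is kernel partial least squares with a Gaussian radial basis
kernel. For training spectra x_1…x_n the Gram matrix is

    K_ij = exp(−‖x_i − x_j‖² / σ²).

The exponent denominator is σ², not 2σ²; widths quoted here are therefore
√2 times smaller than they would be in the 2σ² convention. K is
double-centered,

    M = K − (1/n)·1·K − (1/n)·K·1 + (1/n²)·1·K·1,

which is algebraically J K J with J = I − (1/n)·1 and equals centering the
implicit feature map; all row and column sums of M vanish. A test block
K_test (t × n, kernel of each test sample against each training sample) is
centered with the training marginals,

    M_test = K_test − (1/n)·1_t·K − (1/n)·K_test·1_n + (1/n²)·1_t·K·1_n,

so its rows sum to zero and a test row duplicating a training sample
reproduces the corresponding row of M.

### Training loop

Y is column-centered before fitting (the prediction equation returns
zero-mean output for centered inputs, so the mean is restored at predict
time). With E = M and F = Y_centered, each latent component runs

    v ← E u / ‖E u‖      (kernel score)
    c ← Fᵀ v             (response loading)
    u ← F c / ‖F c‖      (response score)

from a seeded random unit u until ‖Δv‖ < tol (default 1e−10) or max_iter
(default 200) sweeps, then deflates

    E ← (I − v vᵀ) E (I − v vᵀ),   F ← F − v vᵀ F,

and repeats until s components are accumulated or a residual norm drops
below tol. Successive v's are orthonormal by construction. Two readings
of the published procedure are deliberately disambiguated here:

* the kernel score is computed from the *deflated* E (and the response
  loading from the deflated F). Multiplying the untouched K forever while
  deflating E would make the deflation steps inert — every component would
  be the same dominant direction. The literal variant is kept behind the
  `literal_k` switch for comparison.
* components are extracted one at a time. Updating an n × s block U in
  one sweep (the literal reading of "randomly initialize U") is a power
  iteration that collapses all columns onto the dominant direction and
  renders VᵀMU singular; sequential extraction with deflation is the
  standard NIPALS resolution and keeps the s-component model the exact
  prefix of any larger fit — a property the grid search exploits.

For a single response the inner loop is deterministic: c is a scalar, so
u is proportional to the deflated F after the first sweep regardless of
the random initialisation, and the loop converges immediately. The
random seed therefore matters only for multi-response fits.

### Prediction

    Y′ = M⁎ U (Vᵀ M U)⁻¹ Vᵀ Y_centered + ȳ

for any centered block M⁎ (training M or a test M_test). The inner s × s
matrix is inverted by pseudo-inverse with relative cutoff 1e−12 —
near-duplicate samples make it ill-conditioned — and a genuinely singular
system raises an error naming the condition number. With s = n−1 and
distinct samples the formula interpolates the training responses (V spans
the range of M, which contains centered Y), giving the full-rank
regression floor used as a correctness check.

In the large-width limit M → (2/σ²)·(centered Gram of X) + O(σ⁻⁴) and
the prediction operator is invariant to scaling M, so RBF-PLS collapses
onto classical linear PLS with the same s; the implementation is checked
against scikit-learn's NIPALS PLS at σ = 10³ × the maximum pairwise
distance.

### Iteration trace

The training procedure exposes a 200-iteration refinement curve in two
interpretations: per-sweep validation RMSE recorded inside a single fit
(`mode="sweep"`, padded at its converged value), and validation RMSE over
repeated refits with re-randomized initialisation (`mode="restart"`, the
default). The reported curve is the best-so-far envelope, which is
non-increasing by construction. Because single-response fits are
deterministic (above), both modes flatten essentially immediately for one
analyte at a time; the curve is still recorded and exported for parity
with multi-response use.

## Model selection

* Split: uniformly random disjoint calibration/validation/testing subsets
  in the 2:1:1 design, 248 → 120/64/64 by default (one published account
  of the same campaign says 128 calibration samples; the explicit
  120/64/64 enumeration is used). Seeded and reproducible.
* RMSE uses the (n−1) denominator exactly as defined for this workflow —
  about 0.8% larger than the 1/n form at n = 64. CC is the sample Pearson
  estimator; no R² substitution, no Fisher transform.
* Grid search fits one model per σ at max(s) components and reads every
  smaller s off the same fit (exact by the prefix property); each cell is
  identical to an independent refit at that (σ, s), which the tests assert
  to 1e−10. Ties are broken by smaller s, then smaller σ (parsimony; the
  procedure definition is silent on ties). A failed cell records NaN and
  never aborts the sweep.
* The full 6,400 × 20 scan is supported; at n_cal = 120 it is ~6,400 kernel
  fits and takes on the order of an hour on one CPU. Routine runs and the
  shipped tests use 20 log-spaced widths crossed with s ∈ 1…12, which
  selects within the same order of magnitude.
* The validation-selected (σ\*, s\*) is refit on the calibration set and
  scored once on the testing set, which is asserted disjoint at runtime.

## Synthetic data

The generator emulates the calibration campaign the package was built
around: n = 248 samples, reflectance spectra on 1000–2500 nm at 8 nm
(188 bands), three analytes with truncated-normal distributions matching
the campaign's descriptive statistics (SU: mean 11.51, SD 1.78, range
8.63–14.52 %; VC: 487.71 ± 82.91, 347.51–623.02 mg/kg; OA: 11.12 ± 1.39,
8.91–13.68 g/kg). Truncation (rather than resampling) keeps draws
reproducible and bounded.

Each spectrum is a fixed smooth baseline (slow polynomial plus the 1450
and 1940 nm water bands) minus analyte-weighted Gaussian absorption peaks
placed on plausible NIR overtone/combination bands, with 1440 nm shared
by SU and VC and 2270 nm by SU and OA to mimic natural band overlap. The
linear term is −z_a × (peak profile) with z_a the standardized analyte
value; the nonlinear term, scaled by `nonlinearity` (default 1.0), adds
−0.5·(z_a² − 1) on the same profiles plus z_a·z_b cross terms on shared
peaks, both zero-mean under the generative distribution. I.i.d. Gaussian
noise of SD `noise_sd` (default 0.005 reflectance units, a few per mille
of full scale — a clean lab instrument) is added per band. Peak
amplitudes (0.02–0.035 per SD) keep spectra within (0, 1). With
`nonlinearity=0` and `noise_sd=0` the spectra are an exact linear map of
the three analytes and linear PLS with s = 3 recovers them to numerical
precision — the identifiability floor. At the defaults the quadratic term
is strong enough that the kernel model beats linear PLS on every analyte
while CC_V stays above 0.9.

Cubes for the ROI pipeline broadcast one spectrum over a spatial grid
with i.i.d. per-pixel noise, so the 50-pixel ROI mean deviates from the
input spectrum with SD pixel_noise_sd/√50.

What the generator does **not** emulate: multiplicative scatter and
path-length effects, temperature/moisture baseline drift, spatial
heterogeneity of real fruit tissue, detector nonlinearity, and
band-to-band correlated noise. Passing tests therefore demonstrate
algorithmic correctness and the qualitative kernel-vs-linear ordering
under a controlled nonlinear link, not instrument-grade performance on
real fruit.

## Numerical choices and degenerate inputs

* Kernel distances via `scipy.spatial.distance.cdist(..., 'sqeuclidean')`;
  self-kernels are exactly symmetric with unit diagonal.
* σ-grid sizes are computed in integer arithmetic
  (⌊(hi−lo)/step + ½⌋ + 1) so that 0.01…64 step 0.01 yields exactly 6,400
  candidates despite float drift; the endpoint is included when within
  half a step.
* A constant response centers to zero and yields a zero-component model
  that predicts the training mean — the defined degenerate behaviour.
* Duplicated training rows are handled by the pseudo-inverse cutoff;
  identical inputs receive identical predictions by kernel symmetry.
* Non-convergence of an inner loop sets a warning flag and raises a
  `ConvergenceWarning` rather than failing silently.
* All randomness (splits, initialisation, synthetic draws) flows through
  `numpy.random.default_rng` seeds; a pipeline run's artifacts are
  byte-reproducible for a fixed config + seed.

## Problem sizes used in the shipped checks

Unit and acceptance tests run on reduced problems chosen to exercise the
same code paths as the full scan: centering up to n = 200, fit/predict
oracles at n = 6–30, grid-search/exhaustive agreement on a 5 × 3 grid,
and the full default dataset (n = 248) with 20 log-spaced widths ×
s ∈ 1…12 for the kernel-vs-linear comparison. The acceptance script uses
the same sizes.

## Known limitations

* Single-response fits are deterministic, so the restart-mode refinement
  curve is flat for one analyte at a time; it becomes informative only
  for multi-response fits.
* The σ² kernel convention means published widths using 2σ² conventions
  must be rescaled by √2 before comparison.
* Only Gaussian RBF kernels are implemented; no sparse or low-rank kernel
  approximations, so memory is O(n²) and the method is intended for
  n up to a few thousand samples.
* Spectra are used raw; no SNV, derivative or scatter correction is
  applied before kernelization.
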