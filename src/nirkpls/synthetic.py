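"""Synthetic NIR hyperspectral data with a controllable nonlinear
spectrum-analyte link.

The generator emulates the study conditions of a pomelo-quality
calibration campaign: 248 fruit samples, reflectance spectra over
1000-2500 nm at 8 nm resolution (188 bands), and three analytes — sugar
(SU, %), vitamin C (VC, mg/kg) and organic acid (OA, g/kg) — drawn from
truncated normal distributions with the campaign's descriptive statistics
(e.g. SU: mean 11.51, SD 1.78, range 8.63-14.52).

Each spectrum is a fixed smooth baseline (slow polynomial plus the 1450
and 1940 nm water bands) minus analyte-weighted Gaussian absorption
peaks, plus a nonlinear term (squares and cross products of the
standardized analyte values on the same peak shapes) and i.i.d. noise.
Some peak locations are shared between analytes to mimic the natural
overlap of NIR bands.  With ``nonlinearity=0`` and ``noise_sd=0`` the
spectra are an exact linear map of the analyte values; at the defaults
the quadratic term gives kernel methods a genuine edge over linear PLS.

Cubes for the ROI pipeline are rendered by broadcasting one spectrum over
a spatial grid with per-pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .hypercube import HyperCube
from .tables import ANALYTE_UNITS, SpectraTable


@dataclass(frozen=True)
class AnalyteSpec:
    """Distribution and spectral signature of one analyte."""

    name: str
    unit: str
    mean: float
    sd: float
    min: float
    max: float
    peak_centers: tuple  # nm
    peak_widths: tuple   # nm (Gaussian SD)
    peak_amps: tuple     # reflectance units per SD of the analyte

    def __post_init__(self) -> None:
        if not self.min < self.mean < self.max:
            raise ValueError(
                f"{self.name}: need min < mean < max, got "
                f"{self.min}/{self.mean}/{self.max}"
            )
        if self.sd <= 0:
            raise ValueError(f"{self.name}: SD must be positive")
        if not len(self.peak_centers) == len(self.peak_widths) == len(self.peak_amps):
            raise ValueError(f"{self.name}: peak tuples must have equal length")


# Campaign descriptive statistics; peak centers sit on real NIR
# overtone/combination bands, with 1440 nm shared by SU and VC and
# 2270 nm shared by SU and OA ("natural overlapping signals").
DEFAULT_ANALYTES = (
    AnalyteSpec("SU", ANALYTE_UNITS["SU"], 11.51, 1.78, 8.63, 14.52,
                peak_centers=(1200.0, 1440.0, 2100.0, 2270.0),
                peak_widths=(45.0, 35.0, 55.0, 40.0),
                peak_amps=(0.030, 0.025, 0.035, 0.020)),
    AnalyteSpec("VC", ANALYTE_UNITS["VC"], 487.71, 82.91, 347.51, 623.02,
                peak_centers=(1140.0, 1440.0, 1680.0, 2010.0),
                peak_widths=(40.0, 35.0, 50.0, 45.0),
                peak_amps=(0.025, 0.020, 0.030, 0.025)),
    AnalyteSpec("OA", ANALYTE_UNITS["OA"], 11.12, 1.39, 8.91, 13.68,
                peak_centers=(1380.0, 1730.0, 1930.0, 2270.0),
                peak_widths=(40.0, 50.0, 60.0, 40.0),
                peak_amps=(0.025, 0.030, 0.020, 0.022)),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the generated dataset (defaults = campaign)."""

    n_samples: int = 248
    wavelength_lo: float = 1000.0   # nm
    wavelength_hi: float = 2500.0   # nm
    resolution: float = 8.0         # nm -> 188 bands over the default range
    analytes: tuple = DEFAULT_ANALYTES
    nonlinearity: float = 1.0       # mixing coefficient of the quadratic term
    noise_sd: float = 0.005         # reflectance units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0 or self.nonlinearity < 0:
            raise ValueError("noise_sd and nonlinearity must be >= 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wavelength_lo, self.wavelength_hi + 1e-9,
                         self.resolution)


@dataclass
class SyntheticDataset:
    """Generated spectra + reference chemistry + generative ground truth."""

    spectra: SpectraTable
    reference: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------

def draw_reference(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Per-analyte truncated-normal reference values, one row per sample."""
    rng = np.random.default_rng(seed)
    n = config.n_samples
    out = {}
    for spec in config.analytes:
        if spec.sd == 0:
            out[spec.name] = np.full(n, spec.mean)
            continue
        a = (spec.min - spec.mean) / spec.sd
        b = (spec.max - spec.mean) / spec.sd
        out[spec.name] = truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd,
                                       size=n, random_state=rng)
    ids = [f"sample_{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(out, index=pd.Index(ids, name="id"))


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _baseline(wl: np.ndarray) -> np.ndarray:
    # slow polynomial plus the two broad water bands every NIR spectrum has
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    base = 0.62 + 0.10 * t - 0.18 * t**2
    base -= 0.08 * _gaussian(wl, 1450.0, 60.0)
    base -= 0.12 * _gaussian(wl, 1940.0, 70.0)
    return base


def _standardize(reference: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    z = np.empty((len(reference), len(config.analytes)))
    for k, spec in enumerate(config.analytes):
        z[:, k] = (reference[spec.name].to_numpy(float) - spec.mean) / spec.sd
    return z


def render_spectra(reference: pd.DataFrame, config: SyntheticConfig,
                   seed: int) -> SpectraTable:
    """Render one reflectance spectrum per reference row.

    Linear part: each analyte subtracts its peak shapes scaled by the
    standardized value z.  Nonlinear part (scaled by
    ``config.nonlinearity``): (z^2 - 1) on the same shapes plus z_a*z_b
    cross terms on shared peaks; both are zero-mean under the generative
    distribution so the baseline stays put.  I.i.d. Gaussian noise of SD
    ``config.noise_sd`` is added per band.
    """
    rng = np.random.default_rng(seed)
    wl = config.wavelengths()
    z = _standardize(reference, config)
    n = len(reference)

    X = np.tile(_baseline(wl), (n, 1))
    shapes = []  # per-analyte summed peak profile, for the truth record
    for k, spec in enumerate(config.analytes):
        profile = np.zeros_like(wl)
        for c, w, a in zip(spec.peak_centers, spec.peak_widths, spec.peak_amps):
            profile += a * _gaussian(wl, c, w)
        shapes.append(profile)
        X -= np.outer(z[:, k], profile)
        if config.nonlinearity > 0:
            X -= config.nonlinearity * 0.5 * np.outer(z[:, k] ** 2 - 1.0, profile)
    if config.nonlinearity > 0:
        # cross terms on peaks shared between analyte pairs
        for i in range(len(config.analytes)):
            for j in range(i + 1, len(config.analytes)):
                shared = set(config.analytes[i].peak_centers) & set(
                    config.analytes[j].peak_centers)
                for c in shared:
                    wi = config.analytes[i].peak_widths[
                        config.analytes[i].peak_centers.index(c)]
                    X -= config.nonlinearity * 0.4 * 0.02 * np.outer(
                        z[:, i] * z[:, j], _gaussian(wl, c, wi))
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)

    ids = [str(i) for i in reference.index]
    return SpectraTable(X, wl, ids)


def render_cube(spectrum, spatial, pixel_noise_sd: float, seed: int,
                wavelengths=None, sample_id: str = "synthetic") -> HyperCube:
    """Broadcast one spectrum over a rows x cols grid with per-pixel noise.

    The mean over any ROI converges to the input spectrum as the pixel
    noise vanishes, which is what the 50-pixel ROI averaging step relies
    on.
    """
    spectrum = np.ravel(np.asarray(spectrum, dtype=float))
    rows, cols = (int(v) for v in spatial)
    if rows < 1 or cols < 1:
        raise ValueError("spatial extents must be >= 1")
    if pixel_noise_sd < 0:
        raise ValueError("pixel_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    data = np.tile(spectrum, (rows, cols, 1))
    if pixel_noise_sd > 0:
        data = data + rng.normal(0.0, pixel_noise_sd, size=data.shape)
    if wavelengths is None:
        wavelengths = np.arange(spectrum.size, dtype=float)
    return HyperCube(data, wavelengths, sample_id)


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Draw reference values and render their spectra (one-stop shop)."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    # independent child seeds for the two stages
    ss = np.random.SeedSequence(config.seed)
    ref_seed, spec_seed = (int(s.generate_state(1)[0] % 2**31)
                           for s in ss.spawn(2))
    reference = draw_reference(config, ref_seed)
    spectra = render_spectra(reference, config, spec_seed)

    clean_cfg = replace(config, noise_sd=0.0)
    clean = render_spectra(reference, clean_cfg, spec_seed)
    d = np.sqrt(np.maximum(
        (clean.X**2).sum(1)[:, None] + (clean.X**2).sum(1)[None, :]
        - 2 * clean.X @ clean.X.T, 0.0))
    truth = {
        "config": config,
        "ref_seed": ref_seed,
        "spec_seed": spec_seed,
        # typical sample-to-sample distance of the noise-free spectra:
        # the generative length scale a tuned kernel width should track
        "length_scale": float(np.median(d[np.triu_indices_from(d, k=1)])),
    }
    return SyntheticDataset(spectra, reference, truth)
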