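"""Sample splitting, RMSE/CC metrics and exhaustive (sigma, s) grid search.

The calibration workflow splits the samples 2:1:1 into calibration,
validation and testing sets (248 -> 120/64/64 by default), fits one
RBF-PLS model per (sigma, s) candidate, scores each on the validation set,
and picks the pair minimising the validation RMSE.  The winner is then
refit on the calibration set and evaluated once on the held-out testing
set.

Conventions:

* RMSE uses an (n-1) denominator: sqrt(sum (y - yhat)^2 / (n-1)).
* CC is the sample Pearson correlation between predicted and reference
  values.
* Grid-search ties are broken by smaller s (parsimony), then smaller
  sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .kernel_pls import KernelParams, KernelPLS


# ---------------------------------------------------------------------------
# splitting

@dataclass
class SplitIndices:
    """Disjoint calibration / validation / testing index sets."""

    calibration: np.ndarray
    validation: np.ndarray
    testing: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.calibration = np.asarray(self.calibration, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        self.testing = np.asarray(self.testing, dtype=int)
        all_idx = np.concatenate([self.calibration, self.validation, self.testing])
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("split sets must be disjoint")

    @property
    def sizes(self):
        return (self.calibration.size, self.validation.size, self.testing.size)


def split_samples(n_total: int, sizes, seed: int) -> SplitIndices:
    """Uniformly random disjoint calibration/validation/testing subsets."""
    n_cal, n_val, n_test = (int(v) for v in sizes)
    if min(n_cal, n_val, n_test) < 1:
        raise ValueError(f"all split sizes must be positive, got {sizes}")
    if n_cal + n_val + n_test > n_total:
        raise ValueError(
            f"split sizes {sizes} exceed the {n_total} available samples"
        )
    perm = np.random.default_rng(seed).permutation(n_total)
    return SplitIndices(
        calibration=np.sort(perm[:n_cal]),
        validation=np.sort(perm[n_cal:n_cal + n_val]),
        testing=np.sort(perm[n_cal + n_val:n_cal + n_val + n_test]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# metrics

def rmse(y, yhat) -> float:
    """Root mean square error with the (n-1) denominator."""
    y = np.ravel(np.asarray(y, dtype=float))
    yhat = np.ravel(np.asarray(yhat, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError("y and yhat lengths differ")
    if y.size < 2:
        raise ValueError("RMSE needs at least two samples (n-1 denominator)")
    return float(np.sqrt(np.sum((y - yhat) ** 2) / (y.size - 1)))


def cc(y, yhat) -> float:
    """Pearson correlation between reference and predicted values."""
    y = np.ravel(np.asarray(y, dtype=float))
    yhat = np.ravel(np.asarray(yhat, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError("y and yhat lengths differ")
    yd = y - y.mean()
    pd_ = yhat - yhat.mean()
    denom = np.sqrt(np.sum(yd**2) * np.sum(pd_**2))
    if denom == 0:
        raise ValueError("correlation undefined: a vector has zero variance")
    return float(np.sum(yd * pd_) / denom)


@dataclass
class EvaluationReport:
    """RMSE/CC of one analyte on one evaluation set (analyte units)."""

    analyte: str
    rmse: float
    cc: float
    set_label: str
    n: int

    def to_dict(self) -> dict:
        return {"analyte": self.analyte, "rmse": self.rmse, "cc": self.cc,
                "set": self.set_label, "n": self.n}


# ---------------------------------------------------------------------------
# grids

def build_sigma_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Arithmetic sigma grid lo, lo+step, ... with the endpoint included
    when it lies within half a step.  The default search uses
    (0.01, 64, 0.01): 6,400 candidates.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if lo <= 0:
        raise ValueError(f"sigma grid must start above 0, got {lo}")
    if hi < lo:
        raise ValueError(f"empty grid: hi={hi} < lo={lo}")
    # integer count avoids float drift (e.g. (64-0.01)/0.01 = 6398.999...)
    n_steps = int(np.floor((hi - lo) / step + 0.5))
    return lo + step * np.arange(n_steps + 1)


# ---------------------------------------------------------------------------
# grid search

@dataclass
class GridSearchSurface:
    """Validation RMSE/CC over the (sigma, s) grid plus the optimum.

    ``rmse_v`` and ``cc_v`` are |sigma| x |s| matrices; a cell that failed
    to fit holds NaN.  ``best`` is a dict with keys sigma, s, rmse_v,
    cc_v.
    """

    sigma_grid: np.ndarray
    s_grid: np.ndarray
    rmse_v: np.ndarray
    cc_v: np.ndarray
    best: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long format (sigma, s, rmse_v, cc_v) for contour plotting."""
        sig, s = np.meshgrid(self.sigma_grid, self.s_grid, indexing="ij")
        return pd.DataFrame({
            "sigma": sig.ravel(), "s": s.ravel().astype(int),
            "rmse_v": self.rmse_v.ravel(), "cc_v": self.cc_v.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _select_best(sigma_grid, s_grid, rmse_v, cc_v) -> dict:
    # argmin with ties broken by smaller s, then smaller sigma
    best = None
    for j, s in enumerate(s_grid):          # s-major: parsimony first
        for i, sig in enumerate(sigma_grid):
            r = rmse_v[i, j]
            if np.isnan(r):
                continue
            if best is None or r < best["rmse_v"]:
                best = {"sigma": float(sig), "s": int(s),
                        "rmse_v": float(r), "cc_v": float(cc_v[i, j])}
    if best is None:
        raise RuntimeError("every grid cell failed to fit")
    return best


def grid_search(X_cal, Y_cal, X_val, Y_val, sigma_grid, s_grid,
                fit_params: dict | None = None) -> GridSearchSurface:
    """Exhaustive sweep of (sigma, s) scored by validation RMSE.

    One model is fitted per sigma at max(s_grid) components; because
    components are extracted sequentially, every smaller s is the exact
    prefix of that fit, so each column of the surface is read off the same
    model (identical, to machine precision, to refitting at that s).
    A failed fit marks its cells NaN; the sweep never aborts.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=int)
    if sigma_grid.size == 0 or s_grid.size == 0:
        raise ValueError("grids must be non-empty")
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_cal = np.ravel(np.asarray(Y_cal, dtype=float))
    y_val = np.ravel(np.asarray(Y_val, dtype=float))
    n_cal = X_cal.shape[0]
    if s_grid.max() > n_cal - 1:
        raise ValueError(
            f"max s={s_grid.max()} exceeds n_cal-1={n_cal - 1}"
        )
    fit_params = dict(fit_params or {})
    s_max = int(s_grid.max())

    rmse_v = np.full((sigma_grid.size, s_grid.size), np.nan)
    cc_v = np.full((sigma_grid.size, s_grid.size), np.nan)
    for i, sigma in enumerate(sigma_grid):
        try:
            model = KernelPLS(KernelParams(sigma=float(sigma), s=s_max,
                                           **fit_params)).fit(X_cal, y_cal)
        except (ValueError, np.linalg.LinAlgError):
            continue
        for j, s in enumerate(s_grid):
            if s > model.n_components_:
                # residual exhausted early: the prefix at n_components_
                # already interpolates, further components do not exist
                s = model.n_components_
            try:
                pred = np.ravel(model.predict(X_val, n_components=int(s)))
                rmse_v[i, j] = rmse(y_val, pred)
                cc_v[i, j] = cc(y_val, pred)
            except (ValueError, np.linalg.LinAlgError):
                continue
    best = _select_best(sigma_grid, s_grid, rmse_v, cc_v)
    return GridSearchSurface(sigma_grid, s_grid, rmse_v, cc_v, best)


# ---------------------------------------------------------------------------
# linear PLS baseline

def linear_pls_predict(X_cal, y_cal, X_new, s: int) -> np.ndarray:
    """Classical linear PLS (NIPALS on centered X/Y) predictions."""
    model = PLSRegression(n_components=int(s), scale=False)
    model.fit(np.asarray(X_cal, float), np.ravel(np.asarray(y_cal, float)))
    return np.ravel(model.predict(np.asarray(X_new, float)))


def select_linear_pls(X_cal, y_cal, X_val, y_val, s_grid) -> dict:
    """Pick the linear-PLS component count by validation RMSE."""
    y_val = np.ravel(np.asarray(y_val, dtype=float))
    best = None
    for s in np.asarray(s_grid, dtype=int):
        pred = linear_pls_predict(X_cal, y_cal, X_val, int(s))
        r = rmse(y_val, pred)
        if best is None or r < best["rmse_v"]:
            best = {"s": int(s), "rmse_v": float(r),
                    "cc_v": float(cc(y_val, pred))}
    return best


def compare_with_linear_pls(X_cal, Y_cal, X_val, Y_val, sigma_grid, s_grid,
                            analytes=None, fit_params=None) -> dict:
    """Paired per-analyte validation reports: grid-searched RBF-PLS vs
    grid-searched linear PLS on the same split.

    ``Y_cal``/``Y_val`` are DataFrames (one column per analyte) or 2-D
    arrays; returns {analyte: {"rbf_pls": EvaluationReport, "pls":
    EvaluationReport, "best": grid best dict, "pls_best": dict}}.
    """
    if isinstance(Y_cal, pd.DataFrame):
        analytes = analytes or list(Y_cal.columns)
        get = lambda Y, a: Y[a].to_numpy(float)  # noqa: E731
    else:
        Y_cal = np.atleast_2d(np.asarray(Y_cal, dtype=float))
        Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float))
        analytes = analytes or [f"y{k}" for k in range(Y_cal.shape[1])]
        get = lambda Y, a: Y[:, analytes.index(a)]  # noqa: E731

    out = {}
    n_val = np.atleast_2d(np.asarray(X_val, dtype=float)).shape[0]
    for a in analytes:
        y_cal, y_val = get(Y_cal, a), get(Y_val, a)
        surface = grid_search(X_cal, y_cal, X_val, y_val,
                              sigma_grid, s_grid, fit_params)
        pls_best = select_linear_pls(X_cal, y_cal, X_val, y_val, s_grid)
        out[a] = {
            "rbf_pls": EvaluationReport(a, surface.best["rmse_v"],
                                        surface.best["cc_v"], "validation", n_val),
            "pls": EvaluationReport(a, pls_best["rmse_v"], pls_best["cc_v"],
                                    "validation", n_val),
            "best": surface.best,
            "pls_best": pls_best,
            "surface": surface,
        }
    return out


def evaluate_on_test(X_cal, y_cal, X_test, y_test, sigma: float, s: int,
                     analyte: str = "y", fit_params=None):
    """Refit at the selected (sigma, s) and score once on the testing set."""
    params = KernelParams(sigma=float(sigma), s=int(s), **(fit_params or {}))
    model = KernelPLS(params).fit(X_cal, np.ravel(np.asarray(y_cal, float)))
    pred = np.ravel(model.predict(X_test))
    y_test = np.ravel(np.asarray(y_test, dtype=float))
    report = EvaluationReport(analyte, rmse(y_test, pred), cc(y_test, pred),
                              "testing", y_test.size)
    return report, pred, model
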