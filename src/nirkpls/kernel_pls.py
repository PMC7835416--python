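"""Gaussian-RBF kernel partial least squares (RBF-PLS).

The method maps spectra into the feature space induced by the kernel

    K(x_i, x_j) = exp(-||x_i - x_j||^2 / sigma^2)

(note the sigma^2 denominator — many textbooks write 2*sigma^2; this
package keeps the sigma^2 convention throughout, so widths are not
directly comparable with implementations using the other form).  The
training Gram matrix K is double-centered to M, which centers the implicit
feature map, and latent variables are then extracted by a NIPALS-style
iteration with deflation:

    E = M, F = Y_centered
    for each of the s components:
        u  <- random unit vector             (seeded)
        repeat until v stabilises:
            v <- E u,   v <- v / ||v||       (kernel score)
            c <- F^T v                       (response loading)
            u <- F c,   u <- u / ||u||       (response score)
        E <- (I - v v^T) E (I - v v^T)       (deflation)
        F <- F - v v^T F

Components are extracted one at a time; the accumulated score matrix V and
response-score matrix U (n x s) feed the prediction equation

    Y' = M_any U (V^T M U)^{-1} V^T Y_centered  + Y_mean

where ``M_any`` is the (test-)centered kernel between new samples and the
training set.  For a single response the inner loop is deterministic — u is
proportional to the deflated residual F whatever the initialisation — and
converges in one sweep.

Model capacity is controlled by the kernel width ``sigma`` and the number
of latent variables ``s``; both are tuned by grid search in
:mod:`nirkpls.selection`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist


class ConvergenceWarning(UserWarning):
    """A component hit ``max_iter`` sweeps before the score stabilised."""


# ---------------------------------------------------------------------------
# kernel and centering primitives

def rbf_kernel(xa, xb, sigma: float) -> float:
    """Scalar Gaussian RBF kernel exp(-||xa - xb||^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {xb.shape}")
    d2 = float(np.sum((xa - xb) ** 2))
    return float(np.exp(-d2 / sigma**2))


def kernel_matrix(Xa, Xb, sigma: float) -> np.ndarray:
    """Gram matrix of the RBF kernel between the rows of Xa and Xb."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError(
            f"feature-count mismatch: {Xa.shape[1]} vs {Xb.shape[1]}"
        )
    d2 = cdist(Xa, Xb, metric="sqeuclidean")
    return np.exp(-d2 / sigma**2)


def center_train_kernel(K) -> np.ndarray:
    """Double-center a square Gram matrix.

    M = K - (1/n) 1 K - (1/n) K 1 + (1/n^2) 1 K 1 with 1 the all-one
    matrix; row and column sums of M vanish.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got shape {K.shape}")
    n = K.shape[0]
    row_means = K.mean(axis=1, keepdims=True)
    col_means = K.mean(axis=0, keepdims=True)
    return K - row_means - col_means + K.mean()


def center_test_kernel(K_test, K) -> np.ndarray:
    """Center a t x n test kernel consistently with the training centering.

    M_test = K_test - (1/n) 1_t K - (1/n) K_test 1_n + (1/n^2) 1_t K 1_n;
    each row of the result sums to zero.
    """
    K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"training kernel must be square, got {K.shape}")
    if K_test.shape[1] != K.shape[0]:
        raise ValueError(
            f"K_test has {K_test.shape[1]} columns but K is {K.shape[0]}-dim"
        )
    train_col_means = K.mean(axis=0, keepdims=True)     # (1/n) 1_t K rows
    test_row_means = K_test.mean(axis=1, keepdims=True)  # (1/n) K_test 1_n
    return K_test - train_col_means - test_row_means + K.mean()


# ---------------------------------------------------------------------------
# model

@dataclass
class KernelParams:
    """Hyperparameters of one RBF-PLS fit.

    sigma : kernel width (same units as the predictor rows).
    s : number of latent variables, 1 <= s <= n-1.
    max_iter : inner-loop sweep cap per component (default 200).
    tol : convergence / deflation tolerance.
    seed : seed for the random initialisation of the response scores.
    literal_k : compatibility switch — compute the kernel score from the
        untouched K instead of the deflated E.
    """

    sigma: float
    s: int
    max_iter: int = 200
    tol: float = 1e-10
    seed: int = 0
    literal_k: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.s < 1:
            raise ValueError(f"s must be >= 1, got {self.s}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class KernelPLS:
    """Fitted RBF-PLS model (build with :meth:`fit` or :func:`fit`)."""

    params: KernelParams
    X_train: np.ndarray = None
    Y_train: np.ndarray = None
    y_mean: np.ndarray = None
    K: np.ndarray = None
    M: np.ndarray = None
    U: np.ndarray = None
    V: np.ndarray = None
    C: np.ndarray = None
    E: np.ndarray = None
    F: np.ndarray = None
    n_components_: int = 0
    converged: bool = True
    trace: list = field(default_factory=list)

    # -- fitting ----------------------------------------------------------

    def fit(self, X, Y, X_val=None, Y_val=None) -> "KernelPLS":
        """Fit on training predictors X (n x p) and responses Y (n x q).

        If a validation set is given, the validation RMSE is recorded in
        ``trace`` after every inner sweep (the iteration trace of the
        training procedure).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        if n < 2:
            raise ValueError("at least two training samples are required")
        if Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        p = self.params
        if p.s > n - 1:
            raise ValueError(f"s={p.s} exceeds n-1={n - 1}")

        self.X_train = X
        self.y_mean = Y.mean(axis=0)
        Yc = Y - self.y_mean
        self.Y_train = Yc
        self.K = kernel_matrix(X, X, p.sigma)
        self.M = center_train_kernel(self.K)

        rng = np.random.default_rng(p.seed)
        E = self.M.copy()
        F = Yc.copy()
        U_cols, V_cols, C_cols = [], [], []
        self.trace = []
        self.converged = True

        M_val = None
        if X_val is not None:
            K_val = kernel_matrix(np.atleast_2d(np.asarray(X_val, float)),
                                  X, p.sigma)
            M_val = center_test_kernel(K_val, self.K)
            Y_val = np.asarray(Y_val, dtype=float)
            if Y_val.ndim == 1:
                Y_val = Y_val[:, None]

        for _ in range(p.s):
            if np.linalg.norm(E) < p.tol or np.linalg.norm(F) < p.tol:
                break  # residuals exhausted before s components
            u = rng.standard_normal(n)
            u /= np.linalg.norm(u)
            A = self.K if p.literal_k else E
            v_prev = None
            converged = False
            for _sweep in range(p.max_iter):
                v = A @ u
                nv = np.linalg.norm(v)
                if nv < p.tol:
                    break  # degenerate direction; residual exhausted
                v /= nv
                c = F.T @ v
                u_new = F @ c
                nu = np.linalg.norm(u_new)
                if nu >= p.tol:
                    u = u_new / nu
                if M_val is not None:
                    self.trace.append(self._partial_val_rmse(
                        V_cols + [v], U_cols + [u], M_val, Y_val))
                if v_prev is not None and np.linalg.norm(v - v_prev) < p.tol:
                    converged = True
                    break
                v_prev = v
            else:
                converged = False
            if nv < p.tol:
                break
            if not converged and p.max_iter > 1:
                self.converged = False
            # deflation: remove the explained direction from both residuals
            Ev = E @ v
            E = E - np.outer(v, v @ E) - np.outer(Ev, v) + np.outer(v, v) * (v @ Ev)
            F = F - np.outer(v, v @ F)
            U_cols.append(u)
            V_cols.append(v)
            C_cols.append(c)

        if not U_cols:
            # centered response (or kernel) is identically zero: the model
            # is the training mean, carried with zero components
            self.U = np.zeros((n, 0))
            self.V = np.zeros((n, 0))
            self.C = np.zeros((Yc.shape[1], 0))
            self.E, self.F = E, F
            self.n_components_ = 0
            return self
        if not self.converged:
            warnings.warn(
                "inner loop hit max_iter before the kernel score stabilised; "
                "returning the best state reached",
                ConvergenceWarning,
            )
        self.U = np.column_stack(U_cols)
        self.V = np.column_stack(V_cols)
        self.C = np.column_stack(C_cols)
        self.E = E
        self.F = F
        self.n_components_ = len(V_cols)
        return self

    def _partial_val_rmse(self, V_cols, U_cols, M_val, Y_val) -> float:
        V = np.column_stack(V_cols)
        U = np.column_stack(U_cols)
        try:
            pred = self._regress(M_val, U, V)
        except np.linalg.LinAlgError:
            return float("nan")
        resid = Y_val - pred
        return float(np.sqrt((resid**2).sum() / max(resid.size - 1, 1)))

    # -- prediction -------------------------------------------------------

    def _regress(self, M_any, U, V) -> np.ndarray:
        inner = V.T @ self.M @ U
        # pseudo-inverse guards against near-duplicate samples
        inv = np.linalg.pinv(inner, rcond=1e-12)
        if not np.all(np.isfinite(inv)):
            cond = np.linalg.cond(inner)
            raise np.linalg.LinAlgError(
                f"V^T M U is singular beyond regularization (cond={cond:.3e})"
            )
        return M_any @ U @ inv @ V.T @ self.Y_train + self.y_mean

    def predict_centered(self, M_any, n_components: int | None = None) -> np.ndarray:
        """Predict from an already-centered kernel block (rows x n)."""
        M_any = np.atleast_2d(np.asarray(M_any, dtype=float))
        if M_any.shape[1] != self.M.shape[0]:
            raise ValueError(
                f"M_any has {M_any.shape[1]} columns, expected {self.M.shape[0]}"
            )
        if self.n_components_ == 0:
            return np.tile(self.y_mean, (M_any.shape[0], 1))
        k = self.n_components_ if n_components is None else n_components
        if not 1 <= k <= self.n_components_:
            raise ValueError(f"n_components must be in 1..{self.n_components_}")
        return self._regress(M_any, self.U[:, :k], self.V[:, :k])

    def predict(self, X_new, n_components: int | None = None) -> np.ndarray:
        """Predict responses for new predictor rows (kernelized vs training)."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        K_new = kernel_matrix(X_new, self.X_train, self.params.sigma)
        return self.predict_centered(center_test_kernel(K_new, self.K),
                                     n_components=n_components)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize arrays + params + trace to a single .npz archive."""
        meta = {"version": 1, "params": asdict(self.params),
                "n_components": self.n_components_, "converged": self.converged}
        np.savez(
            Path(path), meta=np.array(json.dumps(meta)),
            X_train=self.X_train, Y_train=self.Y_train, y_mean=self.y_mean,
            K=self.K, M=self.M, U=self.U, V=self.V, C=self.C,
            E=self.E, F=self.F, trace=np.asarray(self.trace, dtype=float),
        )

    @classmethod
    def load(cls, path) -> "KernelPLS":
        with np.load(Path(path), allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            model = cls(params=KernelParams(**meta["params"]))
            for name in ("X_train", "Y_train", "y_mean", "K", "M",
                         "U", "V", "C", "E", "F"):
                setattr(model, name, npz[name])
            model.trace = npz["trace"].tolist()
            model.n_components_ = int(meta["n_components"])
            model.converged = bool(meta["converged"])
        return model


def fit(X_train, Y_train, params: KernelParams, X_val=None, Y_val=None) -> KernelPLS:
    """Functional entry point: fit an RBF-PLS model."""
    return KernelPLS(params=params).fit(X_train, Y_train, X_val=X_val, Y_val=Y_val)


def predict(model: KernelPLS, M_any) -> np.ndarray:
    """Functional entry point: predict from a centered kernel block."""
    return model.predict_centered(M_any)


# ---------------------------------------------------------------------------
# iteration tracing (Fig.-5-style refinement curves)

def refinement_trace(X_cal, Y_cal, X_val, Y_val, params: KernelParams,
                     n_iter: int = 200, mode: str = "restart"):
    """Record a 200-iteration validation-RMSE refinement curve.

    ``mode="restart"`` re-fits with a re-randomized initialisation at each
    iteration and records that fit's validation RMSE; ``mode="sweep"``
    records the per-sweep trace of a single fit, held at its converged
    value once the inner loop stops.  Returns ``(rmse_per_iter,
    best_so_far)``, both length ``n_iter``; the best-so-far curve is the
    running minimum and therefore the monotone refinement envelope.
    """
    from .selection import rmse as _rmse  # local import avoids a cycle

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    values = []
    if mode == "restart":
        base = np.random.default_rng(params.seed)
        for _ in range(n_iter):
            p_i = KernelParams(sigma=params.sigma, s=params.s,
                               max_iter=params.max_iter, tol=params.tol,
                               seed=int(base.integers(2**31)),
                               literal_k=params.literal_k)
            model = KernelPLS(p_i).fit(X_cal, Y_cal)
            pred = model.predict(X_val)
            values.append(_rmse(np.ravel(Y_val), np.ravel(pred)))
    elif mode == "sweep":
        p_i = KernelParams(sigma=params.sigma, s=params.s,
                           max_iter=params.max_iter, tol=params.tol,
                           seed=params.seed, literal_k=params.literal_k)
        model = KernelPLS(p_i).fit(X_cal, Y_cal, X_val=X_val, Y_val=Y_val)
        values = list(model.trace)
        if not values:
            pred = model.predict(X_val)
            values = [_rmse(np.ravel(Y_val), np.ravel(pred))]
        values = values[:n_iter] + [values[-1]] * max(0, n_iter - len(values))
    else:
        raise ValueError(f"unknown trace mode '{mode}'")
    values = np.asarray(values, dtype=float)
    return values, np.minimum.accumulate(values)
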