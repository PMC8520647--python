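"""Locally weighted LASSO regression.

The cost model is linear, y = b0 + x'b + e, fitted by minimizing the
weighted L1-penalized least-squares objective

    (1/2m) sum_i w_i (y_i - b0 - x_i'b)^2  +  (lam/m) sum_j |b_j|

by cyclic coordinate descent with soft-thresholding; the intercept is never
penalized.  Per-observation weights w_i come from a Gaussian kernel centred
at the query point,

    w_i = exp(-||x_i - x||^2 / (2 tau^2)),

so refitting at each query yields a *locally* weighted fit: nearby patients
dominate the estimate, distant ones barely contribute.  tau -> inf recovers
the global LASSO.  An optional coefficient budget sum_j |b_j| <= sigma_cap is
enforced through the standard constrained/penalized equivalence by bisecting
on lam.

Features are standardized internally (weighted mean 0, weighted variance 1)
before penalization — L1 shrinkage is scale sensitive — and coefficients are
reported on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DomainError

__all__ = [
    "LWLassoConfig",
    "LWLassoModel",
    "soft_threshold",
    "kernel_weights",
    "lambda_max",
    "fit",
    "predict",
    "cv_lambda",
    "LocallyWeightedLasso",
]


@dataclass(frozen=True)
class LWLassoConfig:
    """Solver settings: penalty ``lam`` (>= 0), kernel bandwidth ``tau``
    (> 0; None means use sqrt(p)/2 on the standardized scale), optional
    coefficient budget ``sigma_cap``, iteration cap and tolerance on the
    (standardized) coefficient change."""

    lam: float = 0.0
    tau: Optional[float] = None
    sigma_cap: Optional[float] = None
    max_iter: int = 10_000
    tol: float = 1e-6
    weighting: str = "loss"  # "loss": w_i multiplies the squared residuals;
    # "penalty": a per-coefficient weight vector multiplies |b_j| instead

    def __post_init__(self):
        if self.lam < 0:
            raise ConfigError(f"lam: must be >= 0, got {self.lam}")
        if self.tau is not None and self.tau <= 0:
            raise ConfigError(f"tau: must be > 0, got {self.tau}")
        if self.tol <= 0:
            raise ConfigError(f"tol: must be > 0, got {self.tol}")
        if self.weighting not in ("loss", "penalty"):
            raise ConfigError(f"weighting: unknown {self.weighting!r}")


@dataclass
class LWLassoModel:
    """A fitted weighted-LASSO model on the original feature scale."""

    beta0: float
    beta: np.ndarray
    feature_names: Optional[list] = None
    lam: float = 0.0
    converged: bool = True
    n_sweeps: int = 0
    objective_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.beta):
            raise DomainError(
                f"dimension mismatch: model has {len(self.beta)} features, "
                f"query has {X.shape[1]}")
        return self.beta0 + X @ self.beta


def soft_threshold(z, lam):
    """sign(z) * max(|z| - lam, 0), the LASSO coordinate update."""
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def kernel_weights(query: np.ndarray, X: np.ndarray, tau: float) -> np.ndarray:
    """Gaussian kernel weights exp(-||x_i - x||^2 / (2 tau^2)) of every
    training row against one query point; in (0, 1], equal to 1 iff the row
    coincides with the query."""
    if tau <= 0:
        raise DomainError(f"tau: must be > 0, got {tau}")
    X = np.asarray(X, dtype=float)
    query = np.asarray(query, dtype=float)
    d2 = np.sum((X - query) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * tau**2))


def _weighted_standardize(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    wsum = w.sum()
    mu = (w @ X) / wsum
    var = (w @ (X - mu) ** 2) / wsum
    scale = np.sqrt(var)
    zero = scale <= 0
    if zero.any():
        warnings.warn(
            f"zero-variance feature(s) at indices {np.where(zero)[0].tolist()}; "
            f"their coefficients are fixed to 0")
    safe = np.where(zero, 1.0, scale)
    Xs = (X - mu) / safe
    ybar = float(w @ y / wsum)
    return Xs, y - ybar, mu, safe, zero, ybar


def lambda_max(X, y, weights=None) -> float:
    """Smallest lam at which every coefficient is exactly zero (standardized,
    centered design): max_j |sum_i w_i xs_ij (y_i - ybar_w)|."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    Xs, yc, *_ = _weighted_standardize(X, y, w)
    return float(np.max(np.abs((w * yc) @ Xs)))


def _cd_solve(Xs, yc, w, lam, max_iter, tol, beta_init=None, penalty_weights=None):
    """Coordinate descent on the standardized, centered problem.

    Objective: (1/2m) sum w r^2 + (lam/m) sum pw_j |b_j|.
    Returns (beta, converged, sweeps, objective path).
    """
    m, p = Xs.shape
    pw = np.ones(p) if penalty_weights is None else np.asarray(penalty_weights, float)
    wX = w[:, None] * Xs
    denom = np.einsum("ij,ij->j", wX, Xs) / m  # (1/m) sum w x_j^2
    beta = np.zeros(p) if beta_init is None else beta_init.copy()
    r = yc - Xs @ beta
    path = []
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            if denom[j] <= 0:
                beta[j] = 0.0
                continue
            rho = (wX[:, j] @ r) / m + denom[j] * beta[j]
            bnew = soft_threshold(rho, lam * pw[j] / m) / denom[j]
            delta = bnew - beta[j]
            if delta != 0.0:
                r -= Xs[:, j] * delta
                beta[j] = bnew
                max_delta = max(max_delta, abs(delta))
        obj = float((w * r) @ r / (2 * m) + lam / m * np.abs(pw * beta).sum())
        path.append(obj)
        if max_delta < tol:
            converged = True
            break
    return beta, converged, sweeps, np.asarray(path)


def fit(
    X,
    y,
    weights=None,
    config: Optional[LWLassoConfig] = None,
    feature_names: Optional[Sequence[str]] = None,
    penalty_weights=None,
    beta_init=None,
) -> LWLassoModel:
    """Fit a weighted LASSO by cyclic coordinate descent.

    ``weights`` are per-observation loss weights (all ones when None).  With
    ``config.weighting == "penalty"`` the observation weights are kept at 1
    and ``penalty_weights`` (one per coefficient) multiply the L1 terms
    instead.  If ``config.sigma_cap`` is set and the fit at ``config.lam``
    exceeds the budget sum |b_j| <= sigma_cap, lam is increased by bisection
    until the budget holds.
    """
    config = config or LWLassoConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise DomainError("X must be 2-D with rows matching y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values in X or y")
    if config.weighting == "penalty":
        if weights is not None:
            raise ConfigError("penalty weighting takes penalty_weights, "
                              "not observation weights")
        w = np.ones(len(y))
    else:
        w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise DomainError("observation weights must be >= 0 with positive sum")
        penalty_weights = None
    Xs, yc, mu, scale, zero_var, ybar = _weighted_standardize(X, y, w)

    def solve(lam, init=None):
        return _cd_solve(Xs, yc, w, lam, config.max_iter, config.tol,
                         beta_init=init, penalty_weights=penalty_weights)

    beta_s, converged, sweeps, path = solve(
        config.lam, None if beta_init is None else np.asarray(beta_init) * scale)

    lam_used = config.lam
    if config.sigma_cap is not None:
        # enforce the budget sum|b_j| <= sigma_cap on the ORIGINAL scale
        def budget(bs):
            return float(np.abs(bs / scale).sum())

        if budget(beta_s) > config.sigma_cap:
            lo, hi = config.lam, lambda_max(X, y, w)
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                bs_mid, *_ = solve(mid, init=beta_s)
                if budget(bs_mid) > config.sigma_cap:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-10 * max(hi, 1.0):
                    break
            beta_s, converged, sweeps, path = solve(hi, init=beta_s)
            lam_used = hi
    if not converged:
        warnings.warn(f"coordinate descent hit max_iter={config.max_iter} "
                      f"without converging to tol={config.tol}")
    beta = np.where(zero_var, 0.0, beta_s / scale)
    beta0 = ybar - float(mu @ beta)
    return LWLassoModel(
        beta0=beta0, beta=beta,
        feature_names=list(feature_names) if feature_names is not None else None,
        lam=lam_used, converged=converged, n_sweeps=sweeps, objective_path=path)


def predict(model: LWLassoModel, X) -> np.ndarray:
    """Global-model prediction b0 + X b (see :class:`LocallyWeightedLasso`
    for query-local refits)."""
    return model.predict(X)


def cv_lambda(X, y, n_folds: int = 5, n_lambdas: int = 20,
              lambda_min_ratio: float = 1e-4, seed: int = 0,
              config: Optional[LWLassoConfig] = None,
              objective: str = "mse") -> float:
    """Pick lam by k-fold cross-validation over a descending log-spaced grid
    from lambda_max, with warm starts along the path.

    ``objective`` is the validation loss to minimize: "mse" (default) or
    "relative" (mean absolute relative error, the loss behind the pipeline's
    accuracy percentage; records with y = 0 are skipped)."""
    config = config or LWLassoConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n_folds < 2 or n_folds > n:
        raise ConfigError(f"n_folds: must be in [2, n], got {n_folds}")
    if objective not in ("mse", "relative"):
        raise ConfigError(f"objective: unknown {objective!r}")
    lmax = lambda_max(X, y)
    if lmax <= 0:
        return 0.0
    grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    mse = np.zeros(n_lambdas)
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        Xtr, ytr = X[mask], y[mask]
        Xte, yte = X[fold], y[fold]
        w = np.ones(mask.sum())
        Xs, yc, mu, scale, zero, ybar = _weighted_standardize(Xtr, ytr, w)
        beta_s = None
        for i, lam in enumerate(grid):
            beta_s, *_ = _cd_solve(Xs, yc, w, lam, config.max_iter, config.tol,
                                   beta_init=beta_s)
            beta = np.where(zero, 0.0, beta_s / scale)
            pred = (ybar - mu @ beta) + Xte @ beta
            if objective == "mse":
                mse[i] += float(np.sum((pred - yte) ** 2))
            else:
                ok = yte != 0
                mse[i] += float(np.sum(np.abs(pred[ok] - yte[ok]) / np.abs(yte[ok])))
    return float(grid[int(np.argmin(mse))])


class LocallyWeightedLasso:
    """Estimator wrapping the weighted-LASSO solver with query-local refits.

    ``fit`` stores the training design (standardized for kernel distances)
    and a global fit; ``predict(X, local=True)`` refits the coefficients at
    each query using Gaussian kernel weights centred there (the weights are
    rescaled to mean 1 so the penalty strength stays comparable across
    queries), warm-started from the global solution.  ``local=False`` returns
    the global LASSO prediction.
    """

    def __init__(self, lam="cv", tau: Optional[float] = None,
                 cv_folds: int = 5, seed: int = 0,
                 config: Optional[LWLassoConfig] = None,
                 cv_objective: str = "mse"):
        self.lam = lam
        self.tau = tau
        self.cv_folds = cv_folds
        self.seed = seed
        self.config = config or LWLassoConfig()
        self.cv_objective = cv_objective

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._Xz = (X - self._mu) / self._sd
        self._X = X
        self._y = y
        self._names = list(feature_names) if feature_names is not None else None
        if self.lam == "cv":
            folds = min(self.cv_folds, len(y))
            self.lam_ = cv_lambda(X, y, n_folds=max(2, folds), seed=self.seed,
                                  config=self.config, objective=self.cv_objective)
        else:
            self.lam_ = float(self.lam)
        # bandwidth on the standardized scale; default tau = sqrt(p)/2 keeps
        # e^-4 weight at a typical random-pair distance of sqrt(2p)
        self.tau_ = self.tau if self.tau is not None else 0.5 * np.sqrt(X.shape[1])
        cfg = LWLassoConfig(lam=self.lam_, tau=self.tau_,
                            max_iter=self.config.max_iter, tol=self.config.tol)
        self._cfg = cfg
        self.global_model_ = fit(X, y, config=cfg, feature_names=self._names)
        return self

    def predict(self, X, local: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not local:
            return self.global_model_.predict(X)
        Xq = (X - self._mu) / self._sd
        out = np.empty(len(X))
        warm = self.global_model_.beta
        for i, (q, qz) in enumerate(zip(X, Xq)):
            w = kernel_weights(qz, self._Xz, self.tau_)
            s = w.sum()
            if s <= 1e-300:
                w = np.ones_like(w)      # query far outside the data: global fit
            else:
                w = w * (len(w) / s)     # mean-1 normalization
            model = fit(self._X, self._y, weights=w, config=self._cfg,
                        beta_init=warm)
            out[i] = float(model.predict(q)[0])
        return out
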