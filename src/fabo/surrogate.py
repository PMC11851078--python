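"""Probabilistic surrogates over the selected representation.

Three regressors with predictive uncertainty:

* a zero-mean GP with a shared-length-scale RBF kernel — the surrogate the
  adaptive loop uses on its selected feature subset (hard feature
  elimination: deselected features get zero weight);
* an ARD-RBF GP over the full feature pool — the soft-deselection baseline
  in which each feature gets its own length scale;
* a random forest whose uncertainty is the spread of per-tree predictions.

Inputs are expected standardized per cycle (labeled rows only); the GP
prior mean is zero.  Kernel hyperparameters (signal variance, length
scale(s), noise variance) maximize the log marginal likelihood via
multi-restart optimization from seeded initializations, with Cholesky
jitter escalated x10 from 1e-8 up to 1e-2 on numerical failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

JITTER_INITIAL = 1e-8
JITTER_MAX = 1e-2

_LS_BOUNDS = (1e-2, 1e3)
_SIGNAL_BOUNDS = (1e-3, 1e3)
_NOISE_BOUNDS = (1e-8, 1e1)


@dataclass
class GPHyperparameters:
    """Fitted kernel hyperparameters.

    ``length_scales`` has length 1 in shared mode and one entry per feature
    in ARD mode.
    """

    signal_variance: float
    length_scales: np.ndarray
    noise_variance: float

    def __post_init__(self) -> None:
        self.length_scales = np.atleast_1d(np.asarray(self.length_scales, float))
        if self.signal_variance <= 0 or (self.length_scales <= 0).any():
            raise ValueError("signal variance and length scales must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be non-negative")

    def to_dict(self) -> dict:
        return {
            "signal_variance": float(self.signal_variance),
            "length_scales": [float(v) for v in self.length_scales],
            "noise_variance": float(self.noise_variance),
        }


@dataclass
class SurrogatePosterior:
    """A fitted surrogate exposing batched (mean, std) prediction."""

    predict_fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    kind: str
    training_size: int
    n_features: int
    hyperparameters: GPHyperparameters | None = None
    log_marginal_likelihood: float | None = None
    _model: object = None

    def predict(self, X_query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X_query = np.atleast_2d(np.asarray(X_query, float))
        if X_query.shape[1] != self.n_features:
            raise ValueError(
                f"query has {X_query.shape[1]} features; surrogate was trained "
                f"on {self.n_features}"
            )
        mean, std = self.predict_fn(X_query)
        return np.asarray(mean, float).ravel(), np.asarray(std, float).ravel()


def _make_kernel(mode: str, n_features: int) -> ConstantKernel:
    ls = 1.0 if mode == "shared" else np.ones(n_features)
    return (
        ConstantKernel(1.0, _SIGNAL_BOUNDS)
        * RBF(ls, _LS_BOUNDS)
        + WhiteKernel(1e-2, _NOISE_BOUNDS)
    )


def _extract_hyperparameters(kernel) -> GPHyperparameters:
    prod, white = kernel.k1, kernel.k2
    return GPHyperparameters(
        signal_variance=float(prod.k1.constant_value),
        length_scales=np.atleast_1d(prod.k2.length_scale),
        noise_variance=float(white.noise_level),
    )


def fit_gp(
    X_sel: np.ndarray,
    y: np.ndarray,
    mode: str = "shared",
    restarts: int = 5,
    rng_seed: int | None = None,
    fixed_hyperparameters: GPHyperparameters | None = None,
) -> SurrogatePosterior:
    """Fit a zero-mean RBF-kernel GP by marginal-likelihood maximization.

    Parameters
    ----------
    X_sel, y : arrays
        Standardized training inputs (n x k) and targets (n,).
    mode : {"shared", "ard"}
        One length scale for all features, or one per feature.
    restarts : int
        Total optimizer runs (1 = single run from the default init).
    rng_seed : int, optional
        Seeds the restart initializations.
    fixed_hyperparameters : GPHyperparameters, optional
        Skip optimization and condition on these values (used for
        closed-form checks and for tying ARD to shared mode).
    """
    X = np.atleast_2d(np.asarray(X_sel, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] < 1 or X.shape[0] != len(y):
        raise ValueError("X_sel and y must have matching, non-zero length")
    if mode not in ("shared", "ard"):
        raise ValueError("mode must be 'shared' or 'ard'")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    if fixed_hyperparameters is not None:
        h = fixed_hyperparameters
        ls = h.length_scales if mode == "ard" else float(h.length_scales[0])
        kernel = (
            ConstantKernel(h.signal_variance, "fixed")
            * RBF(ls, "fixed")
            + WhiteKernel(max(h.noise_variance, 1e-12), "fixed")
        )
        optimizer = None
    else:
        kernel = _make_kernel(mode, X.shape[1])
        optimizer = "fmin_l_bfgs_b"

    jitter = JITTER_INITIAL
    gpr = None
    while True:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gpr = GaussianProcessRegressor(
                    kernel=kernel,
                    alpha=jitter,
                    optimizer=optimizer,
                    n_restarts_optimizer=max(0, restarts - 1),
                    normalize_y=False,
                    random_state=rng_seed,
                )
                gpr.fit(X, y)
            break
        except np.linalg.LinAlgError:
            jitter *= 10
            if jitter > JITTER_MAX:
                raise np.linalg.LinAlgError(
                    f"kernel matrix singular even at jitter {JITTER_MAX}"
                )

    lml = float(gpr.log_marginal_likelihood_value_)
    if not np.isfinite(lml):
        raise ValueError("non-finite marginal likelihood at fitted hyperparameters")

    def _predict(Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean, std = gpr.predict(Xq, return_std=True)
        return mean, std

    return SurrogatePosterior(
        predict_fn=_predict,
        kind="gp_shared" if mode == "shared" else "gp_ard",
        training_size=X.shape[0],
        n_features=X.shape[1],
        hyperparameters=_extract_hyperparameters(gpr.kernel_),
        log_marginal_likelihood=lml,
        _model=gpr,
    )


def gp_loo_log_density(posterior: SurrogatePosterior) -> float:
    """Leave-one-out predictive log-density of a fitted GP.

    Uses the closed form mu_i = y_i - [K^-1 y]_i / [K^-1]_ii,
    sigma_i^2 = 1 / [K^-1]_ii on the training kernel matrix, so no refits
    are needed.  Used by the subset-size schedule to compare feature
    counts on equal footing.
    """
    gpr = posterior._model
    if gpr is None or not posterior.kind.startswith("gp"):
        raise ValueError("LOO log-density is defined for fitted GP surrogates")
    X, y = gpr.X_train_, gpr.y_train_
    K = gpr.kernel_(X) + gpr.alpha * np.eye(len(y))
    c, low = cho_factor(K, lower=True)
    K_inv = cho_solve((c, low), np.eye(len(y)))
    alpha = K_inv @ y
    diag = np.diag(K_inv)
    var = 1.0 / diag
    mu = y - alpha / diag
    resid2 = (y - mu) ** 2
    return float(-0.5 * np.sum(np.log(2 * np.pi * var) + resid2 / var))


def fit_random_forest(
    X_sel: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    rng_seed: int | None = None,
) -> SurrogatePosterior:
    """Random-forest surrogate; uncertainty = spread of per-tree predictions.

    The mean prediction averages the individual trees; the predictive
    standard deviation is the sample standard deviation across trees.
    """
    X = np.atleast_2d(np.asarray(X_sel, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if n_trees < 2:
        raise ValueError("ensemble variance needs at least 2 trees")
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=rng_seed, bootstrap=True
    )
    forest.fit(X, y)

    def _predict(Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        per_tree = np.stack([t.predict(Xq) for t in forest.estimators_])
        return per_tree.mean(axis=0), per_tree.std(axis=0, ddof=1)

    return SurrogatePosterior(
        predict_fn=_predict,
        kind="random_forest",
        training_size=X.shape[0],
        n_features=X.shape[1],
        _model=forest,
    )
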