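"""Per-cycle representation update: mRMR, Spearman ranking, random subsets.

The representation is re-selected at every optimization cycle from the
labeled data acquired so far.  mRMR (maximum relevance, minimum redundancy)
greedily builds an ordered subset: the first two features are taken purely
by relevance (univariate F-statistic against the target), and every later
step maximizes relevance / mean|corr with already-selected features|.
Spearman selection is the univariate alternative: rank features by the
absolute Spearman rank correlation with the target.

All ties break toward the lower column index so selection is a pure
function of (X_labeled, y, k, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: floor on the mean-redundancy denominator of the quotient mRMR score
REDUNDANCY_FLOOR = 1e-6
#: F-statistics are capped at the value attained at r^2 = 1 - _R2_CAP_GAP,
#: preserving the ordering of perfect predictors without infinities
_R2_CAP_GAP = 1e-12


@dataclass
class FeatureSubset:
    """An ordered selected representation.

    ``indices`` are pool column indices in selection order (mRMR) or score
    rank (Spearman); ``scores`` are the matching selection scores.
    """

    indices: np.ndarray
    scores: np.ndarray
    method: str
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.indices) != self.k or len(self.scores) != self.k:
            raise ValueError("indices/scores length must equal k")
        if len(np.unique(self.indices)) != self.k:
            raise ValueError("selected indices must be unique")


def f_statistic_relevance(X_labeled: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Univariate linear-regression F-statistic of each feature vs the target.

    With Pearson correlation r over n rows, F = (n-2) * r^2 / (1 - r^2);
    equal to the squared t-statistic of the univariate slope.  Perfect
    correlation is capped at a large finite value.  Degenerate (constant)
    columns score 0 — callers should pre-mask them.
    """
    X = np.asarray(X_labeled, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("F-statistic needs at least 3 labeled rows")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.nan_to_num(r, nan=0.0)
    r2 = np.clip(r**2, 0.0, 1.0 - _R2_CAP_GAP)
    return (n - 2) * r2 / (1.0 - r2)


def _pearson_matrix(X: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """|Pearson corr| between every column of X and the selected columns."""
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    norms = np.where(norms > 0, norms, 1.0)
    Z = Xc / norms
    return np.abs(Z.T @ Z[:, selected])


def mrmr_select(
    X_labeled: np.ndarray,
    y: np.ndarray,
    k: int,
    *,
    form: str = "quotient",
    seed_first_two_by_relevance: bool = True,
    redundancy_floor: float = REDUNDANCY_FLOOR,
    rng: np.random.Generator | None = None,
) -> FeatureSubset:
    """Greedy mRMR selection of k features from the labeled rows.

    Steps 1 and 2 take the two highest-relevance features; each later step
    takes the remaining feature maximizing

        quotient form:    relevance / max(eps, mean|corr with selected|)
        difference form:  relevance - mean|corr with selected|

    ``redundancy_floor`` is the eps above; raising it toward infinity
    disables the redundancy term, reducing the method to top-k relevance.
    If every relevance is zero (target carries no linear signal yet) the
    selection falls back to a random subset, with a warning.
    """
    X = np.asarray(X_labeled, float)
    p = X.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > p:
        raise ValueError(f"k={k} exceeds available features ({p})")
    if form not in ("quotient", "difference"):
        raise ValueError("form must be 'quotient' or 'difference'")

    relevance = f_statistic_relevance(X, y)
    if not (relevance > 0).any():
        logger.warning("all relevances zero; falling back to random subset")
        rng = np.random.default_rng(0) if rng is None else rng
        return random_select(p, k, rng)

    order = _mrmr_order(
        X, relevance, k, form, seed_first_two_by_relevance, redundancy_floor
    )
    return FeatureSubset(order[:, 0].astype(int), order[:, 1], "mrmr", k)


def mrmr_order(
    X_labeled: np.ndarray,
    y: np.ndarray,
    k_max: int,
    *,
    form: str = "quotient",
    seed_first_two_by_relevance: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Full greedy mRMR ordering up to ``k_max`` features.

    Greedy selection is prefix-nested: the first k entries of the ordering
    equal :func:`mrmr_select` with that k, so campaign code can score one
    ordering at several subset sizes without re-running the greedy loop.
    Returns ``(indices, scores)``; raises if every relevance is zero.
    """
    X = np.asarray(X_labeled, float)
    relevance = f_statistic_relevance(X, y)
    if not (relevance > 0).any():
        raise ValueError("all relevances zero")
    order = _mrmr_order(
        X, relevance, k_max, form, seed_first_two_by_relevance, REDUNDANCY_FLOOR
    )
    return order[:, 0].astype(int), order[:, 1]


def _mrmr_order(
    X: np.ndarray,
    relevance: np.ndarray,
    k: int,
    form: str,
    seed_first_two: bool,
    redundancy_floor: float = REDUNDANCY_FLOOR,
) -> np.ndarray:
    p = X.shape[1]
    selected: list[int] = []
    scores: list[float] = []
    remaining = np.ones(p, dtype=bool)

    n_seed = min(2 if seed_first_two else 1, k)
    # np.argmax returns the first (lowest-index) maximum, our tie rule
    for _ in range(n_seed):
        rel_masked = np.where(remaining, relevance, -np.inf)
        j = int(np.argmax(rel_masked))
        selected.append(j)
        scores.append(float(relevance[j]))
        remaining[j] = False

    # incremental mean |corr| with the selected set
    corr_sum = np.zeros(p)
    if selected:
        corr_sum += _pearson_matrix(X, np.array(selected)).sum(axis=1)
    while len(selected) < k:
        mean_corr = corr_sum / len(selected)
        if form == "quotient":
            combined = relevance / np.maximum(redundancy_floor, mean_corr)
        else:
            combined = relevance - mean_corr
        combined = np.where(remaining, combined, -np.inf)
        j = int(np.argmax(combined))
        selected.append(j)
        scores.append(float(combined[j]))
        remaining[j] = False
        corr_sum += _pearson_matrix(X, np.array([j]))[:, 0]

    return np.column_stack([np.array(selected, float), np.array(scores)])


def spearman_scores(X_labeled: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Spearman rho| of each feature with the target (average-rank ties).

    Constant columns get score 0.
    """
    X = np.asarray(X_labeled, float)
    y = np.asarray(y, float)
    if X.shape[0] < 3:
        raise ValueError("Spearman selection needs at least 3 labeled rows")
    ranks_X = stats.rankdata(X, axis=0)
    ranks_y = stats.rankdata(y)
    Xc = ranks_X - ranks_X.mean(axis=0)
    yc = ranks_y - ranks_y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xc.T @ yc) / (sx * sy)
    return np.abs(np.nan_to_num(rho, nan=0.0))


def spearman_select(X_labeled: np.ndarray, y: np.ndarray, k: int) -> FeatureSubset:
    """Top-k features by |Spearman rank correlation| with the target."""
    X = np.asarray(X_labeled, float)
    p = X.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > p:
        raise ValueError(f"k={k} exceeds available features ({p})")
    rho = spearman_scores(X, y)
    # stable sort on (-|rho|, column index): ties go to the lower index
    order = np.lexsort((np.arange(p), -rho))
    top = order[:k]
    return FeatureSubset(top, rho[top], "spearman", k)


def random_select(p: int, k: int, rng: int | np.random.Generator) -> FeatureSubset:
    """Uniform random subset of k distinct feature indices (seeded)."""
    if k > p:
        raise ValueError(f"k={k} exceeds available features ({p})")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = gen.choice(p, size=k, replace=False)
    return FeatureSubset(idx, np.zeros(k), "random", k)


def choose_k(
    n_labeled: int,
    k_min: int,
    k_max: int,
    strategy: str = "loo_grid",
    surrogate_eval=None,
    *,
    p_available: int | None = None,
    ramp_alpha: float = 0.5,
    grid_size: int = 3,
) -> int:
    """Subset size for this cycle, within the configured bounds.

    The bounds the campaigns use (5-40 for uptake-like tasks, 5-20 for
    band-gap-like) cap how large the representation may grow; the size is
    additionally capped at n_labeled - 2 so the surrogate keeps residual
    degrees of freedom.

    Strategies
    ----------
    loo_grid (default)
        Evaluate a coarse grid of sizes with ``surrogate_eval(k)`` — the
        leave-one-out predictive log-density of the surrogate fitted on the
        top-k features — and return the maximizer (ties to the smaller k).
    ramp
        clip(round(ramp_alpha * n_labeled), k_min, k_max); no model fits.
    """
    if k_min > k_max or k_min < 1:
        raise ValueError(f"infeasible bounds k_min={k_min}, k_max={k_max}")
    if n_labeled < 3:
        raise ValueError("need at least 3 labeled rows")
    hi = min(k_max, n_labeled - 2)
    if p_available is not None:
        hi = min(hi, p_available)
    lo = min(k_min, hi)
    if hi <= lo:
        return lo
    if strategy == "ramp":
        return int(np.clip(round(ramp_alpha * n_labeled), lo, hi))
    if strategy != "loo_grid":
        raise ValueError(f"unknown strategy {strategy!r}")
    if surrogate_eval is None:
        raise ValueError("loo_grid strategy requires a surrogate_eval callback")
    grid = np.unique(np.round(np.geomspace(lo, hi, num=grid_size)).astype(int))
    best_k, best_val = int(grid[0]), -np.inf
    for kk in grid:
        val = float(surrogate_eval(int(kk)))
        if np.isfinite(val) and val > best_val:
            best_k, best_val = int(kk), val
    return best_k


def load_fixed_features(path, feature_names: list[str]) -> np.ndarray:
    """Read a one-column text file of feature names into column indices."""
    names = [ln.strip() for ln in open(path) if ln.strip()]
    lookup = {n: i for i, n in enumerate(feature_names)}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise ValueError(f"fixed features not in pool: {missing}")
    return np.array([lookup[n] for n in names], dtype=int)
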