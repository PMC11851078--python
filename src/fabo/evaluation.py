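"""Benchmark metrics and trial aggregation.

Three metrics summarize a retrospective screening trace against the fully
labeled pool: the *best rank* (rank 1 = optimal candidate under the
campaign direction) of the best candidate acquired so far, the *best value*
of the objective acquired so far, and the *top-k capture* — how many of the
pool's k best candidates (default 100) have been acquired.  All three are
reconstructible from a trace file plus the oracle; no surrogate state is
needed, and rank-based metrics are invariant to strictly monotone
transformations of the property.

Ties share the minimum (competition) rank.  Aggregation across trials uses
the per-iteration mean and sample standard deviation; truncated traces are
padded by carrying the last value forward (flagged in the summary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .campaign import CampaignTrace
from .data_model import CandidatePool, PropertyOracle


class PoolRanking:
    """Competition (min) ranks of every pool value under the direction."""

    def __init__(self, oracle: PropertyOracle, pool_ids) -> None:
        self.oracle = oracle
        values = oracle.values_for(pool_ids)
        # rankdata ranks ascending; internal convention maximizes sign*value
        self.ranks = rankdata(-oracle.sign * values, method="min").astype(int)
        self._by_id = {str(i): int(r) for i, r in zip(pool_ids, self.ranks)}
        self._by_value: dict[float, int] = {}
        for v, r in zip(values, self.ranks):
            self._by_value[float(v)] = min(self._by_value.get(float(v), r), int(r))

    def rank_of_id(self, candidate_id: str) -> int:
        return self._by_id[str(candidate_id)]

    def rank_of_value(self, value: float) -> int:
        if float(value) not in self._by_value:
            raise ValueError(f"value {value!r} not attained by any pool candidate")
        return self._by_value[float(value)]


def rank_of(value: float, oracle: PropertyOracle, pool_ids=None) -> int:
    """Competition rank (1 = optimal) of a property value within the pool."""
    ids = list(oracle.values) if pool_ids is None else pool_ids
    return PoolRanking(oracle, ids).rank_of_value(value)


def _acquisition_ranks(trace: CampaignTrace, ranking: PoolRanking) -> np.ndarray:
    return np.array([ranking.rank_of_id(r.candidate_id) for r in trace.records], int)


def best_rank_trajectory(
    trace: CampaignTrace, oracle: PropertyOracle, pool_ids=None
) -> np.ndarray:
    """Cumulative-minimum rank over the acquisitions; non-increasing."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    ranking = oracle if isinstance(oracle, PoolRanking) else PoolRanking(
        oracle, list(oracle.values) if pool_ids is None else pool_ids
    )
    return np.minimum.accumulate(_acquisition_ranks(trace, ranking))


def top_k_capture(
    trace: CampaignTrace, oracle: PropertyOracle, k: int = 100, pool_ids=None
) -> np.ndarray:
    """Running count of acquisitions whose pool rank is <= k; non-decreasing."""
    ranking = oracle if isinstance(oracle, PoolRanking) else PoolRanking(
        oracle, list(oracle.values) if pool_ids is None else pool_ids
    )
    if k > len(ranking.ranks):
        raise ValueError(f"k={k} exceeds pool size {len(ranking.ranks)}")
    ranks = _acquisition_ranks(trace, ranking)
    return np.cumsum(ranks <= k)


def iterations_to_optimum(trace: CampaignTrace, ranking: PoolRanking) -> int | None:
    """1-based record index at which rank 1 is first acquired; None if never."""
    traj = np.minimum.accumulate(_acquisition_ranks(trace, ranking))
    hits = np.flatnonzero(traj == 1)
    return int(hits[0]) + 1 if len(hits) else None


@dataclass
class BenchmarkSummary:
    """Per-iteration trial statistics for the three metrics."""

    n_trials: int
    n_iterations: int
    top_k: int
    mean_best_rank: np.ndarray
    std_best_rank: np.ndarray
    mean_best_value: np.ndarray
    std_best_value: np.ndarray
    mean_top_k_capture: np.ndarray
    std_top_k_capture: np.ndarray
    terminal_best_ranks: list[int]
    terminal_best_values: list[float]
    iterations_to_optimum: list[int | None]
    any_padded: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _ser(x):
            return [float(v) for v in np.asarray(x)]

        return {
            "n_trials": self.n_trials,
            "n_iterations": self.n_iterations,
            "top_k": self.top_k,
            "mean_best_rank": _ser(self.mean_best_rank),
            "std_best_rank": _ser(self.std_best_rank),
            "mean_best_value": _ser(self.mean_best_value),
            "std_best_value": _ser(self.std_best_value),
            "mean_top_k_capture": _ser(self.mean_top_k_capture),
            "std_top_k_capture": _ser(self.std_top_k_capture),
            "terminal_best_ranks": [int(r) for r in self.terminal_best_ranks],
            "terminal_best_values": [float(v) for v in self.terminal_best_values],
            "iterations_to_optimum": [
                None if v is None else int(v) for v in self.iterations_to_optimum
            ],
            "any_padded": self.any_padded,
            "extra": self.extra,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _pad_lvcf(arr: np.ndarray, length: int) -> np.ndarray:
    if len(arr) >= length:
        return arr[:length]
    return np.concatenate([arr, np.full(length - len(arr), arr[-1], dtype=arr.dtype)])


def aggregate(
    traces: list[CampaignTrace],
    oracle: PropertyOracle,
    pool_ids=None,
    top_k: int = 100,
) -> BenchmarkSummary:
    """Per-iteration mean/sample-std of the three metrics across trials."""
    if not traces:
        raise ValueError("need at least one trace")
    ids = list(oracle.values) if pool_ids is None else pool_ids
    ranking = PoolRanking(oracle, ids)
    length = max(len(t) for t in traces)
    any_padded = any(len(t) < length for t in traces)

    rank_rows, value_rows, capture_rows, ito = [], [], [], []
    for t in traces:
        ranks = np.minimum.accumulate(_acquisition_ranks(t, ranking))
        best_int = np.maximum.accumulate(oracle.sign * t.values())
        best_val = oracle.sign * best_int
        capture = np.cumsum(_acquisition_ranks(t, ranking) <= top_k)
        rank_rows.append(_pad_lvcf(ranks.astype(float), length))
        value_rows.append(_pad_lvcf(best_val, length))
        capture_rows.append(_pad_lvcf(capture.astype(float), length))
        ito.append(iterations_to_optimum(t, ranking))

    R = np.vstack(rank_rows)
    V = np.vstack(value_rows)
    C = np.vstack(capture_rows)
    ddof = 1 if len(traces) > 1 else 0

    return BenchmarkSummary(
        n_trials=len(traces),
        n_iterations=length,
        top_k=top_k,
        mean_best_rank=R.mean(axis=0),
        std_best_rank=R.std(axis=0, ddof=ddof),
        mean_best_value=V.mean(axis=0),
        std_best_value=V.std(axis=0, ddof=ddof),
        mean_top_k_capture=C.mean(axis=0),
        std_top_k_capture=C.std(axis=0, ddof=ddof),
        terminal_best_ranks=[int(r[-1]) for r in rank_rows],
        terminal_best_values=[float(v[-1]) for v in value_rows],
        iterations_to_optimum=ito,
        any_padded=any_padded,
        # the iteration axis counts every labeling call, initial design
        # included; subtract n_init for the acquisitions-only axis
        extra={
            "records_include_initial_design": True,
            "n_init": traces[0].config.get("n_init"),
        },
    )


def feature_composition(trace: CampaignTrace, pool: CandidatePool) -> np.ndarray:
    """Per-iteration (n_geometric, n_chemical, k) for the selected subset.

    Initial-design and random-search records have k = 0.  Counts are
    recomputed from the trace's stored column indices against the pool's
    group map, so they can be audited independently of what the campaign
    logged in n_geometric/n_chemical.
    """
    if pool.feature_groups is None:
        raise ValueError(
            "pool has no feature-group map; load one or use the "
            "default-chemical fallback when reading groups"
        )
    labels = pool.group_labels()
    rows = []
    for r in trace.records:
        cols = r.selected_features or []
        n_geo = int(sum(labels[c] == "geometric" for c in cols))
        rows.append((n_geo, len(cols) - n_geo, len(cols)))
    return np.array(rows, int)


def geometric_fraction(trace: CampaignTrace, pool: CandidatePool, last: int = 50) -> float:
    """Mean selected geometric-feature fraction over the final ``last``
    cycles that actually selected features."""
    comp = feature_composition(trace, pool)
    comp = comp[comp[:, 2] > 0]
    if len(comp) == 0:
        raise ValueError("trace has no feature-selecting cycles")
    tail = comp[-last:]
    return float(np.mean(tail[:, 0] / tail[:, 2]))


def plot_search_efficiency(
    summaries: dict[str, BenchmarkSummary],
    out_dir: str | Path,
    prefix: str = "search_efficiency",
) -> list[Path]:
    """Mean +/- 1 sd band per metric, one curve per run; returns file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = [
        ("best_rank", "Best rank (log scale)", True),
        ("best_value", "Best objective value", False),
        ("top_k_capture", "Candidates in top-k", False),
    ]
    paths = []
    for key, ylabel, logy in metrics:
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, s in summaries.items():
            mean = getattr(s, f"mean_{key}")
            std = getattr(s, f"std_{key}")
            x = np.arange(1, len(mean) + 1)
            ax.plot(x, mean, label=name)
            ax.fill_between(x, mean - std, mean + std, alpha=0.2)
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("Labeling calls (including initial design)")
        ax.set_ylabel(ylabel)
        ax.legend()
        fig.tight_layout()
        p = out_dir / f"{prefix}_{key}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
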