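"""The feature-adaptive closed loop and baseline loops.

Each optimization cycle: (1) label the chosen candidate and add it to the
labeled set, (2) re-select the feature representation from the labeled data
only, (3) re-fit the surrogate on the selected columns, (4) score the
unlabeled pool with the acquisition function and pick the next candidate.

Variants share the identical loop skeleton and differ only in how steps
2-4 are filled in:

* ``fabo`` — adaptive selection (mRMR or Spearman) + shared-RBF GP;
* ``random_search`` — no model; uniform choice among unlabeled candidates;
* ``random_features`` — random subset re-drawn every cycle + GP;
* ``fixed_features`` — a constant, externally supplied subset + GP;
* ``full_ard`` — all (non-degenerate) features, ARD-RBF GP, no selection;
* ``rf_surrogate`` — adaptive selection with a random-forest surrogate.

Restricted-pool experiments (geometric-only / chemical-only) reuse the same
loop on a group-filtered pool, so they are configuration-only.

Seed plumbing: trial_seed is spawned deterministically from (master_seed,
trial index); each trial draws sub-streams for the initial design, feature
selection, surrogate restarts and tie-breaking in a fixed order.  Inserting
a new random consumer is a breaking change by policy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .acquisition import AcquisitionConfig, score_candidates, select_next
from .data_model import (
    CandidatePool,
    DegenerateFeaturesError,
    LabeledSet,
    PropertyOracle,
    fit_standardizer,
    drop_degenerate_features,
)
from .feature_selection import (
    choose_k,
    mrmr_order,
    random_select,
    spearman_select,
)
from .surrogate import fit_gp, fit_random_forest, gp_loo_log_density

logger = logging.getLogger(__name__)

VARIANTS = (
    "fabo",
    "random_search",
    "random_features",
    "fixed_features",
    "full_ard",
    "rf_surrogate",
)
SELECTION_METHODS = ("mrmr", "spearman")
K_STRATEGIES = ("loo_grid", "ramp")


@dataclass
class CampaignConfig:
    """Everything needed to reproduce a benchmark run.

    ``budget`` counts labeling calls after the ``n_init`` seeded initial
    design, so a trial acquires n_init + budget candidates in total.
    """

    budget: int = 250
    n_init: int = 10
    n_trials: int = 20
    selection_method: str = "mrmr"
    k_min: int = 5
    k_max: int = 40
    k_strategy: str = "loo_grid"
    ramp_alpha: float = 0.5
    loo_grid_size: int = 3
    mrmr_form: str = "quotient"
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    surrogate_kind: str = "gp"
    gp_restarts: int = 5
    rf_n_trees: int = 100
    variant: str = "fabo"
    restrict_group: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.acquisition, dict):
            self.acquisition = AcquisitionConfig(**self.acquisition)
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if self.n_init < 2:
            raise ValueError("n_init must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.selection_method not in SELECTION_METHODS:
            raise ValueError(f"selection_method must be one of {SELECTION_METHODS}")
        if self.k_strategy not in K_STRATEGIES:
            raise ValueError(f"k_strategy must be one of {K_STRATEGIES}")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")
        if self.restrict_group not in (None, "geometric", "chemical"):
            raise ValueError("restrict_group must be None, 'geometric' or 'chemical'")
        if self.surrogate_kind not in ("gp", "random_forest"):
            raise ValueError("surrogate_kind must be 'gp' or 'random_forest'")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class IterationRecord:
    iteration: int  # 1-based, counting initial design records too
    candidate_id: str
    value: float  # raw property value
    best_so_far: float  # raw, best under the campaign direction
    acquisition_kind: str  # "init", "ei", "ucb", "random", "random_fallback"
    acquisition_score: float | None = None  # score of the chosen candidate
    k: int = 0
    selected_features: list[int] | None = None
    n_geometric: int = 0
    n_chemical: int = 0
    gp_hyperparameters: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CampaignTrace:
    records: list[IterationRecord]
    trial_seed: int
    config: dict
    n_candidates: int
    truncated: bool = False

    def acquired_ids(self) -> list[str]:
        return [r.candidate_id for r in self.records]

    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records], float)

    def best_so_far(self) -> np.ndarray:
        return np.array([r.best_so_far for r in self.records], float)

    def __len__(self) -> int:
        return len(self.records)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            header = {
                "trial_seed": self.trial_seed,
                "config": self.config,
                "n_candidates": self.n_candidates,
                "truncated": self.truncated,
            }
            fh.write(json.dumps({"header": header}, sort_keys=True) + "\n")
            for r in self.records:
                fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "CampaignTrace":
        with open(path) as fh:
            lines = [json.loads(ln) for ln in fh if ln.strip()]
        if not lines or "header" not in lines[0]:
            raise ValueError(f"malformed trace file {path}: missing header line")
        h = lines[0]["header"]
        records = [IterationRecord(**d) for d in lines[1:]]
        return cls(records, h["trial_seed"], h["config"], h["n_candidates"], h["truncated"])


def _group_counts(pool: CandidatePool, cols: Sequence[int]) -> tuple[int, int]:
    labels = pool.group_labels()
    n_geo = int(sum(labels[c] == "geometric" for c in cols))
    return n_geo, len(cols) - n_geo


def run_trial(
    pool: CandidatePool,
    oracle: PropertyOracle,
    config: CampaignConfig,
    trial_seed: int,
    fixed_feature_indices: Sequence[int] | None = None,
) -> CampaignTrace:
    """Run one retrospective screening campaign.

    The trace holds one record per labeling call (n_init + budget, unless
    the pool is exhausted first, in which case it is truncated with a
    logged notice).
    """
    if config.restrict_group is not None:
        pool = pool.restrict_to_group(config.restrict_group)
    oracle.check_covers(pool)
    if config.variant == "fixed_features":
        if fixed_feature_indices is None or len(fixed_feature_indices) == 0:
            raise ValueError("fixed_features variant needs fixed_feature_indices")
        fixed_idx = np.asarray(fixed_feature_indices, int)
        if (fixed_idx < 0).any() or (fixed_idx >= pool.n_features).any():
            raise ValueError("fixed feature indices outside the pool")

    ss = np.random.SeedSequence(trial_seed)
    init_ss, select_ss, surrogate_ss, tie_ss = ss.spawn(4)
    init_rng = np.random.default_rng(init_ss)
    select_rng = np.random.default_rng(select_ss)
    surrogate_rng = np.random.default_rng(surrogate_ss)
    tie_rng = np.random.default_rng(tie_ss)

    n = pool.n_candidates
    sign = oracle.sign
    labeled = LabeledSet()
    unlabeled = np.ones(n, dtype=bool)
    records: list[IterationRecord] = []
    best_int = -np.inf

    def _label(idx: int, kind: str, **extra) -> None:
        nonlocal best_int
        raw = oracle.value(pool.ids[idx])
        labeled.add(idx, raw)
        unlabeled[idx] = False
        best_int = max(best_int, sign * raw)
        records.append(
            IterationRecord(
                iteration=len(records) + 1,
                candidate_id=str(pool.ids[idx]),
                value=raw,
                best_so_far=sign * best_int,
                acquisition_kind=kind,
                **extra,
            )
        )

    init_size = min(config.n_init, n)
    for idx in init_rng.choice(n, size=init_size, replace=False):
        _label(int(idx), "init")

    truncated = False
    for it in range(config.budget):
        if not unlabeled.any():
            logger.info("pool exhausted after %d records; truncating trace", len(records))
            truncated = True
            break
        if config.variant == "random_search":
            idx = int(select_rng.choice(np.flatnonzero(unlabeled)))
            _label(idx, "random")
            continue

        X_lab = pool.X[labeled.index_array()]
        y_int = sign * labeled.y_array()
        try:
            keep = drop_degenerate_features(X_lab)
        except DegenerateFeaturesError:
            logger.warning("all features degenerate at cycle %d; random fallback", it)
            idx = int(select_rng.choice(np.flatnonzero(unlabeled)))
            _label(idx, "random_fallback")
            continue
        avail = np.flatnonzero(keep)
        n_lab = len(labeled)
        fit_seed = int(surrogate_rng.integers(2**31))

        posterior = None
        if config.variant == "fixed_features":
            sel_global = fixed_idx
            fit_cols = np.array([c for c in fixed_idx if keep[c]], int)
            if len(fit_cols) == 0:
                logger.warning("fixed subset fully degenerate at cycle %d; random fallback", it)
                idx = int(select_rng.choice(np.flatnonzero(unlabeled)))
                _label(idx, "random_fallback")
                continue
            mode = "shared"
        elif config.variant == "full_ard":
            sel_global = avail
            fit_cols = avail
            mode = "ard"
        else:
            hi = max(1, min(config.k_max, n_lab - 2, len(avail)))
            lo = min(config.k_min, hi)
            if lo < config.k_min:
                logger.warning("k clamped to %d (< k_min) at cycle %d", lo, it)
            if config.variant == "random_features":
                k = int(select_rng.integers(lo, hi + 1))
                sub = random_select(len(avail), k, select_rng)
                sel_global = avail[sub.indices]
            else:  # fabo / rf_surrogate: adaptive selection
                sel_global, posterior, stats = _adaptive_selection(
                    X_lab, y_int, avail, lo, hi, config, select_rng, fit_seed
                )
            fit_cols = sel_global
            mode = "shared"

        if posterior is None:
            stats = fit_standardizer(X_lab[:, fit_cols], y_int)
            Z_lab = stats.transform_X(X_lab[:, fit_cols])
            z_y = stats.transform_y(y_int)
            if config.variant == "rf_surrogate" or config.surrogate_kind == "random_forest":
                posterior = fit_random_forest(Z_lab, z_y, config.rf_n_trees, fit_seed)
            else:
                posterior = fit_gp(Z_lab, z_y, mode, config.gp_restarts, fit_seed)

        Z_pool = stats.transform_X(pool.X[:, fit_cols])
        mean, std = posterior.predict(Z_pool)
        best_obs_std = float(stats.transform_y(np.array([best_int]))[0])
        scores, kind = score_candidates(mean, std, best_obs_std, it, config.acquisition)
        idx = select_next(scores, unlabeled, config.acquisition.tie_rule, tie_rng)

        sel_list = [int(c) for c in sel_global]
        n_geo, n_chem = _group_counts(pool, sel_list)
        hypers = (
            posterior.hyperparameters.to_dict()
            if posterior.hyperparameters is not None
            else None
        )
        _label(
            idx,
            kind,
            acquisition_score=float(scores[idx]),
            k=len(sel_list),
            selected_features=sel_list,
            n_geometric=n_geo,
            n_chemical=n_chem,
            gp_hyperparameters=hypers,
        )
        logger.info(
            "cycle %d: id=%s value=%.4g best=%.4g k=%d acq=%s",
            it, records[-1].candidate_id, records[-1].value,
            records[-1].best_so_far, len(sel_list), kind,
        )

    return CampaignTrace(
        records=records,
        trial_seed=int(trial_seed),
        config=config.to_dict(),
        n_candidates=n,
        truncated=truncated,
    )


def _adaptive_selection(X_lab, y_int, avail, lo, hi, config, select_rng, fit_seed):
    """Select features adaptively and, for the GP path, choose k by the
    configured schedule.

    Returns (global column indices, posterior or None, standardizer or
    None); the posterior is populated when the schedule's best grid fit can
    be reused as the cycle's surrogate.
    """
    X_av = X_lab[:, avail]
    if config.selection_method == "mrmr":
        try:
            order, _ = mrmr_order(X_av, y_int, hi, form=config.mrmr_form)
        except ValueError:
            logger.warning("all relevances zero; random subset fallback")
            sub = random_select(len(avail), lo, select_rng)
            return avail[sub.indices], None, None
    else:
        order = spearman_select(X_av, y_int, hi).indices

    use_gp = config.variant != "rf_surrogate" and config.surrogate_kind != "random_forest"
    if lo == hi:
        return avail[order[:lo]], None, None
    if config.k_strategy == "ramp" or not use_gp:
        # the LOO schedule is defined by the GP; the forest surrogate ramps
        k = choose_k(
            len(y_int), lo, hi, "ramp",
            p_available=len(avail), ramp_alpha=config.ramp_alpha,
        )
        return avail[order[: min(k, len(order))]], None, None

    cache: dict[int, tuple] = {}

    def _eval(k: int) -> float:
        cols = avail[order[:k]]
        stats = fit_standardizer(X_lab[:, cols], y_int)
        Z = stats.transform_X(X_lab[:, cols])
        zy = stats.transform_y(y_int)
        post = fit_gp(Z, zy, "shared", config.gp_restarts, fit_seed)
        cache[k] = (cols, post, stats)
        return gp_loo_log_density(post)

    k = choose_k(
        len(y_int), lo, hi, "loo_grid", _eval,
        p_available=len(avail), grid_size=config.loo_grid_size,
    )
    k = min(k, len(order))
    if k in cache:
        return cache[k]
    return avail[order[:k]], None, None


def spawn_trial_seeds(master_seed: int, n_trials: int) -> list[int]:
    """Deterministic per-trial seeds from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n_trials)
    return [int(c.generate_state(1)[0]) for c in children]


def run_benchmark(
    pool: CandidatePool,
    oracle: PropertyOracle,
    config: CampaignConfig,
    fixed_feature_indices: Sequence[int] | None = None,
    n_jobs: int = 1,
) -> list[CampaignTrace]:
    """Run ``config.n_trials`` independent trials with paired derived seeds.

    Results are identical for serial and parallel execution because all
    randomness is derived per trial from (master_seed, trial index).
    """
    seeds = spawn_trial_seeds(config.master_seed, config.n_trials)
    if n_jobs == 1:
        traces = []
        for i, s in enumerate(seeds):
            try:
                traces.append(run_trial(pool, oracle, config, s, fixed_feature_indices))
            except Exception as exc:
                raise RuntimeError(f"trial {i} (seed {s}) failed: {exc}") from exc
        return traces
    return list(
        Parallel(n_jobs=n_jobs)(
            delayed(run_trial)(pool, oracle, config, s, fixed_feature_indices)
            for s in seeds
        )
    )
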