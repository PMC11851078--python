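"""Seeded synthetic candidate pools with known informative structure.

The generator emulates the statistical shape of precomputed MOF descriptor
pools: a small geometric block (8 features, about 2.5% of the pool — pore
diameters, surface areas, density and the like) next to a large chemical
block (revised-autocorrelation- and stoichiometry-style descriptors) with
heavy redundancy, i.e. groups of strongly correlated columns.  Targets
depend on geometry only (high-pressure-uptake-like), on a geometry/
chemistry mixture (low-pressure-uptake-like), or on chemistry only with a
minimization direction (band-gap-like).

Because the true informative support is known, every selection and
recovery claim is testable without downloading real descriptor tables.
The target nonlinearities are fixed, documented polynomials with
interactions: smooth enough for an RBF-kernel GP to learn from ~100
labeled points, but not so simple that random search trivially wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_model import CandidatePool, PropertyOracle

logger = logging.getLogger(__name__)

TASKS = ("sparse_geometric", "mixed", "chemistry_min")
PRESETS = ("high_pressure_like", "low_pressure_like", "band_gap_like")

#: coefficients of the geometric target
#:   f_g = a1*g1 + a2*g1^2 + a3*g2 + a4*g2^2 + a5*g1*g2 + a6*g3
_GEOMETRIC_COEFFS = (1.0, -0.7, 0.8, -0.5, 0.6, 0.4)
#: coefficients of the chemical target over the m informative columns
#:   f_c = s - b1*s^2 + b2*c1*c2,   s = sum(c_j)/sqrt(m)
_CHEMICAL_COEFFS = (0.4, 0.5)
#: correlated copies spawned per informative feature
_N_COPIES = 3
#: informative geometric columns (of the 8-column geometric block)
_N_INFORMATIVE_GEO = 3


@dataclass
class SyntheticTaskSpec:
    """Shape and difficulty of a synthetic screening task.

    ``noise_sd`` is relative: the label noise standard deviation is
    noise_sd * sd(noise-free target) over the pool.  Defaults reproduce
    the emulated pool shape: 8 geometric + 312 chemical features, so the
    geometric share is 8/320 = 2.5%.
    """

    n_candidates: int = 2000
    n_geometric: int = 8
    n_chemical: int = 312
    task: str = "sparse_geometric"
    n_informative_chemical: int = 10
    redundancy_rho: float = 0.9
    noise_sd: float = 0.05
    seed: int = 0
    k_min: int = 5
    k_max: int = 40

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.n_geometric < _N_INFORMATIVE_GEO:
            raise ValueError(f"need at least {_N_INFORMATIVE_GEO} geometric features")
        if not (1 <= self.n_informative_chemical <= self.n_chemical):
            raise ValueError("n_informative_chemical must be in [1, n_chemical]")
        if not (0.0 <= self.redundancy_rho < 1.0):
            raise ValueError("redundancy_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_candidates < 10:
            raise ValueError("n_candidates must be >= 10")

    @property
    def direction(self) -> str:
        return "minimize" if self.task == "chemistry_min" else "maximize"


@dataclass
class GroundTruth:
    """True support of the target, for recovery tests."""

    informative_indices: np.ndarray
    target_function: str
    direction: str

    def to_dict(self) -> dict:
        return {
            "informative_indices": [int(i) for i in self.informative_indices],
            "target_function": self.target_function,
            "direction": self.direction,
        }


def _correlated_copy(rng: np.random.Generator, base: np.ndarray, rho: float) -> np.ndarray:
    return rho * base + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(base))


def _f_geometric(G: np.ndarray) -> np.ndarray:
    a1, a2, a3, a4, a5, a6 = _GEOMETRIC_COEFFS
    g1, g2, g3 = G[:, 0], G[:, 1], G[:, 2]
    return a1 * g1 + a2 * g1**2 + a3 * g2 + a4 * g2**2 + a5 * g1 * g2 + a6 * g3


def _f_chemical(C: np.ndarray) -> np.ndarray:
    b1, b2 = _CHEMICAL_COEFFS
    m = C.shape[1]
    s = C.sum(axis=1) / np.sqrt(m)
    out = s - b1 * s**2
    if m >= 2:
        out = out + b2 * C[:, 0] * C[:, 1]
    return out


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def make_pool(
    spec: SyntheticTaskSpec,
) -> tuple[CandidatePool, PropertyOracle, GroundTruth]:
    """Generate a pool, its retrospective oracle, and the ground truth.

    Deterministic given ``spec.seed``.  The label noise draw is re-sampled
    (from fresh derived substreams, at most 10 times) until the noisy
    optimum coincides with the noise-free optimum, so the task's target
    candidate is a real optimum of the underlying function rather than a
    noise spike; a warning is logged if stability is not reached.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, rho = spec.n_candidates, spec.redundancy_rho

    # geometric block: 3 informative, then copies of the first informative
    # columns (pore metrics correlate in real pools), rest independent
    G = rng.standard_normal((n, spec.n_geometric))
    n_geo_copies = min(2, spec.n_geometric - _N_INFORMATIVE_GEO)
    for j in range(n_geo_copies):
        G[:, _N_INFORMATIVE_GEO + j] = _correlated_copy(rng, G[:, j], rho)

    # chemical block: m informative leading columns, _N_COPIES correlated
    # copies each, remaining columns independent noise
    m = spec.n_informative_chemical
    C = rng.standard_normal((n, spec.n_chemical))
    n_copies = min(_N_COPIES, max(0, (spec.n_chemical - m) // max(m, 1)))
    for j in range(m):
        for c in range(n_copies):
            col = m + j * n_copies + c
            C[:, col] = _correlated_copy(rng, C[:, j], rho)

    f_g = _f_geometric(G)
    f_c = _f_chemical(C[:, :m])

    geo_cols = np.arange(spec.n_geometric)
    chem_cols = spec.n_geometric + np.arange(spec.n_chemical)
    if spec.task == "sparse_geometric":
        f = f_g
        informative = geo_cols[:_N_INFORMATIVE_GEO]
        fn_id = "geometric_quadratic"
    elif spec.task == "mixed":
        f = 0.5 * _zscore(f_g) + 0.5 * _zscore(f_c)
        informative = np.concatenate([geo_cols[:_N_INFORMATIVE_GEO], chem_cols[:m]])
        fn_id = "mixed_half_geometric_half_chemical"
    else:  # chemistry_min
        f = f_c
        informative = chem_cols[:m]
        fn_id = "chemical_quadratic"

    sgn = 1.0 if spec.direction == "maximize" else -1.0
    sd_f = float(np.std(f, ddof=1))
    noise_scale = spec.noise_sd * sd_f
    y = f.copy()
    if noise_scale > 0:
        target_arg = int(np.argmax(sgn * f))
        for attempt in range(10):
            noise_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(1000 + attempt,))
            )
            y = f + noise_scale * noise_rng.standard_normal(n)
            if int(np.argmax(sgn * y)) == target_arg:
                break
        else:
            logger.warning(
                "noisy optimum differs from noise-free optimum after 10 redraws; "
                "consider a different seed"
            )

    ids = np.array([f"cand-{i:06d}" for i in range(n)], dtype=object)
    names = [f"geo_{j + 1:02d}" for j in range(spec.n_geometric)] + [
        f"chem_{j + 1:04d}" for j in range(spec.n_chemical)
    ]
    groups = {nm: ("geometric" if nm.startswith("geo_") else "chemical") for nm in names}
    X = np.hstack([G, C])

    pool = CandidatePool(ids, X, names, groups)
    oracle = PropertyOracle(dict(zip(ids, y)), spec.direction)
    truth = GroundTruth(np.asarray(informative, int), fn_id, spec.direction)
    return pool, oracle, truth


def paper_shape_preset(
    name: str, n_candidates: int = 2000, seed: int = 0
) -> SyntheticTaskSpec:
    """Task presets mirroring the three emulated case-study regimes.

    * ``high_pressure_like`` — geometry-driven target, maximize, k in [5, 40];
    * ``low_pressure_like`` — mixed geometry/chemistry target, maximize,
      k in [5, 40];
    * ``band_gap_like`` — chemistry-driven target, minimize, k in [5, 20].
    """
    if name == "high_pressure_like":
        return SyntheticTaskSpec(
            n_candidates=n_candidates, task="sparse_geometric", seed=seed,
            k_min=5, k_max=40,
        )
    if name == "low_pressure_like":
        return SyntheticTaskSpec(
            n_candidates=n_candidates, task="mixed", seed=seed, k_min=5, k_max=40,
        )
    if name == "band_gap_like":
        return SyntheticTaskSpec(
            n_candidates=n_candidates, task="chemistry_min", seed=seed,
            k_min=5, k_max=20,
        )
    raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def save_task_spec(spec: SyntheticTaskSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
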