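"""Core domain types and tabular I/O for candidate pools.

A *candidate pool* is the fixed set of molecules/materials a screening
campaign searches over: one row per candidate, numeric descriptor columns
(heterogeneous units), and an identifier column.  A *property oracle* maps
candidate ids to the scalar objective (e.g. CO2 uptake in mol kg^-1, band
gap in eV) and stands in for the expensive labeling experiment: labels are
revealed only when a candidate is acquired.

Minimization tasks are handled at the oracle boundary by negating labels,
so every downstream component maximizes; traces always store raw values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_GEOMETRIC = "geometric"
GROUP_CHEMICAL = "chemical"
VALID_GROUPS = (GROUP_GEOMETRIC, GROUP_CHEMICAL)


class DegenerateFeaturesError(ValueError):
    """Raised when every feature is constant on the labeled rows.

    Callers should fall back to random acquisition for the cycle.
    """


@dataclass
class CandidatePool:
    """Fixed pool of candidates with their descriptor matrix.

    Parameters
    ----------
    ids : sequence of str
        Unique candidate identifiers.
    X : ndarray of shape (n_candidates, n_features)
        Descriptor matrix; must be finite.
    feature_names : sequence of str
        Column names, same order as ``X`` columns.
    feature_groups : mapping feature name -> {"geometric", "chemical"}, optional
        Features absent from the map default to "chemical".
    """

    ids: np.ndarray
    X: np.ndarray
    feature_names: list[str]
    feature_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.feature_names = list(self.feature_names)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids length does not match number of rows in X")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match X columns")
        if self.X.shape[1] < 1:
            raise ValueError("pool must have at least one feature")
        uniq, counts = np.unique(self.ids, return_counts=True)
        if (counts > 1).any():
            dups = [str(u) for u in uniq[counts > 1]]
            raise ValueError(f"duplicate candidate ids: {dups}")
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"missing/non-finite value at row id={self.ids[bad[0]]!r}, "
                f"column {self.feature_names[bad[1]]!r}"
            )
        if self.feature_groups is not None:
            unknown = set(self.feature_groups) - set(self.feature_names)
            if unknown:
                raise ValueError(f"feature_groups keys not in pool: {sorted(unknown)}")
            bad_groups = {g for g in self.feature_groups.values() if g not in VALID_GROUPS}
            if bad_groups:
                raise ValueError(f"invalid group labels: {sorted(bad_groups)}")

    @property
    def n_candidates(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def group_of(self, feature_name: str) -> str:
        """Group of a feature; unmapped features default to chemical."""
        if self.feature_groups is None:
            return GROUP_CHEMICAL
        return self.feature_groups.get(feature_name, GROUP_CHEMICAL)

    def group_labels(self) -> np.ndarray:
        """Per-column group labels in column order."""
        return np.array([self.group_of(n) for n in self.feature_names], dtype=object)

    def restrict_to_group(self, group: str) -> "CandidatePool":
        """Pool containing only the columns of one descriptor group."""
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {VALID_GROUPS}")
        keep = [i for i, n in enumerate(self.feature_names) if self.group_of(n) == group]
        if not keep:
            raise ValueError(f"pool has no features in group {group!r}")
        names = [self.feature_names[i] for i in keep]
        groups = None
        if self.feature_groups is not None:
            groups = {n: self.feature_groups[n] for n in names if n in self.feature_groups}
        return CandidatePool(self.ids, self.X[:, keep], names, groups)


@dataclass
class PropertyOracle:
    """Retrospective labeling oracle: id -> scalar property.

    ``direction`` fixes whether the campaign seeks the maximum or the
    minimum of the property.  ``sign`` converts raw labels to the internal
    maximization convention (internal = sign * raw).
    """

    values: dict
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")
        self.values = {k: float(v) for k, v in self.values.items()}
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite label for id {k!r}")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "maximize" else -1.0

    def value(self, candidate_id) -> float:
        return self.values[candidate_id]

    def values_for(self, ids: Sequence) -> np.ndarray:
        return np.array([self.values[i] for i in ids], dtype=float)

    def check_covers(self, pool: CandidatePool) -> None:
        missing = [str(i) for i in pool.ids if i not in self.values]
        if missing:
            raise ValueError(f"labels missing for pool ids: {missing[:10]}")


@dataclass
class LabeledSet:
    """Ordered record of acquired pool indices and their raw labels."""

    indices: list[int] = field(default_factory=list)
    y: list[float] = field(default_factory=list)

    def add(self, index: int, value: float) -> None:
        if index in self.indices:
            raise ValueError(f"candidate index {index} already labeled")
        self.indices.append(int(index))
        self.y.append(float(value))

    def __len__(self) -> int:
        return len(self.indices)

    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def y_array(self) -> np.ndarray:
        return np.asarray(self.y, dtype=float)


@dataclass
class StandardizationStats:
    """Per-column location/scale for features and the target.

    Sample (n-1) standard deviations throughout.  Retained columns must
    have strictly positive std; degenerate columns are the caller's job
    (see :func:`drop_degenerate_features`).
    """

    means: np.ndarray
    stds: np.ndarray
    target_mean: float
    target_std: float

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.means) / self.stds

    def inverse_transform_X(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.stds + self.means

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, float) - self.target_mean) / self.target_std

    def inverse_transform_y(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, float) * self.target_std + self.target_mean

    def inverse_transform_y_std(self, s: np.ndarray) -> np.ndarray:
        return np.asarray(s, float) * self.target_std


def fit_standardizer(X_sub: np.ndarray, y: np.ndarray) -> StandardizationStats:
    """Fit per-column standardization on the labeled rows.

    Requires >= 2 rows (sample std undefined otherwise).  Columns with
    zero variance must be masked out beforehand; a zero target std is
    replaced by 1 so constant targets pass through unchanged.
    """
    X_sub = np.asarray(X_sub, float)
    y = np.asarray(y, float)
    if X_sub.ndim != 2:
        raise ValueError("X_sub must be 2-dimensional")
    if X_sub.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    means = X_sub.mean(axis=0)
    stds = X_sub.std(axis=0, ddof=1)
    if (stds <= 0).any():
        bad = np.flatnonzero(stds <= 0)
        raise ValueError(
            f"zero-variance columns {bad.tolist()}; apply drop_degenerate_features first"
        )
    t_std = float(np.std(y, ddof=1))
    if t_std <= 0:
        t_std = 1.0
    return StandardizationStats(means, stds, float(np.mean(y)), t_std)


def drop_degenerate_features(X_labeled: np.ndarray) -> np.ndarray:
    """Boolean keep-mask excluding columns constant over the labeled rows.

    Recomputed every cycle: a column constant on the first few labeled rows
    may vary once more candidates are acquired.
    """
    X_labeled = np.asarray(X_labeled, float)
    if X_labeled.ndim != 2 or X_labeled.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mask = np.ptp(X_labeled, axis=0) > 0
    if not mask.any():
        raise DegenerateFeaturesError(
            "all features are constant on the labeled rows; "
            "fall back to random acquisition for this cycle"
        )
    return mask


def _read_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # exact float parsing so save -> load round-trips bitwise
    return pd.read_csv(path, sep=delimiter, float_precision="round_trip")


def load_pool(
    features_path: str | Path,
    groups_path: str | Path | None = None,
    id_column: str = "id",
    delimiter: str = ",",
) -> CandidatePool:
    """Read a candidate pool from a delimited table with a header row.

    All non-id columns must be numeric and complete; rows with missing
    values are rejected (never imputed — imputation would silently change
    selection scores downstream).
    """
    df = _read_table(features_path, delimiter)
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not found in {features_path}")
    ids = df[id_column].astype(str).to_numpy(dtype=object)
    feat = df.drop(columns=[id_column])
    if feat.shape[1] == 0:
        raise ValueError("no feature columns found")
    non_numeric = [c for c in feat.columns if not pd.api.types.is_numeric_dtype(feat[c])]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns: {non_numeric}")
    if feat.isna().any().any():
        r, c = np.argwhere(feat.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row id={ids[r]!r}, column {feat.columns[c]!r}"
        )
    groups = load_groups(groups_path, list(feat.columns), delimiter) if groups_path else None
    return CandidatePool(ids, feat.to_numpy(dtype=float), list(feat.columns), groups)


def load_groups(
    groups_path: str | Path,
    feature_names: Sequence[str],
    delimiter: str = ",",
) -> dict[str, str]:
    """Read a feature -> group map; unmapped features default to chemical."""
    df = _read_table(groups_path, delimiter)
    if df.shape[1] < 2:
        raise ValueError("groups file needs two columns: feature, group")
    fcol, gcol = df.columns[:2]
    groups = {str(f): str(g) for f, g in zip(df[fcol], df[gcol])}
    bad = {g for g in groups.values() if g not in VALID_GROUPS}
    if bad:
        raise ValueError(f"invalid group labels in {groups_path}: {sorted(bad)}")
    missing = [n for n in feature_names if n not in groups]
    if missing:
        logger.warning(
            "%d features absent from group map default to 'chemical'", len(missing)
        )
        for n in missing:
            groups[n] = GROUP_CHEMICAL
    unknown = set(groups) - set(feature_names)
    for n in unknown:
        del groups[n]
    return groups


def save_pool(pool: CandidatePool, features_path: str | Path, id_column: str = "id") -> None:
    """Write a pool back to CSV with full float precision (round-trip safe)."""
    df = pd.DataFrame(pool.X, columns=pool.feature_names)
    df.insert(0, id_column, pool.ids)
    df.to_csv(features_path, index=False, float_format="%.17g")


def save_groups(pool: CandidatePool, groups_path: str | Path) -> None:
    rows = [(n, pool.group_of(n)) for n in pool.feature_names]
    pd.DataFrame(rows, columns=["feature", "group"]).to_csv(groups_path, index=False)


def load_oracle(
    labels_path: str | Path,
    direction: str = "maximize",
    pool: CandidatePool | None = None,
    delimiter: str = ",",
) -> PropertyOracle:
    """Read a two-column (id, value) label table as a PropertyOracle."""
    df = _read_table(labels_path, delimiter)
    if df.shape[1] < 2:
        raise ValueError("labels file needs two columns: id, value")
    icol, vcol = df.columns[:2]
    if not pd.api.types.is_numeric_dtype(df[vcol]):
        raise ValueError(f"label column {vcol!r} is not numeric")
    if df[vcol].isna().any():
        raise ValueError("labels contain missing values")
    oracle = PropertyOracle(dict(zip(df[icol].astype(str), df[vcol])), direction)
    if pool is not None:
        oracle.check_covers(pool)
    return oracle


def save_oracle(oracle: PropertyOracle, labels_path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(oracle.values), "value": list(oracle.values.values())}
    ).to_csv(labels_path, index=False, float_format="%.17g")
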