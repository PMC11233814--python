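"""Domain types and table I/O shared by every stage of the pipeline.

The tabular unit is a :class:`FeatureTable`: one microstructure measure
(e.g. FA, MD or NoS) as a subjects x fiber-clusters matrix. Continuous
regression targets (neurocognitive component scores) live in a
:class:`ScoreVector` aligned to the same subjects. Splitting and
standardization are defined here so that training-only statistics are
enforced in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("association", "projection", "commissural", "cerebellar", "superficial")


class DataError(ValueError):
    """Raised for malformed tables, labels or category maps."""


@dataclass
class FeatureTable:
    """One measure's subjects x clusters matrix plus identifiers.

    Parameters
    ----------
    measure_name:
        Short name of the microstructure measure ("FA", "MD", "NoS", ...).
    subject_ids:
        Ordered unique subject identifiers, length ``n``.
    feature_ids:
        Ordered unique cluster identifiers, length ``d``.
    values:
        Real ``n x d`` matrix; empty-cluster entries are zero-filled at load.
    category_map:
        Optional mapping feature_id -> anatomical category; when present it
        must cover every feature_id.
    """

    measure_name: str
    subject_ids: np.ndarray
    feature_ids: np.ndarray
    values: np.ndarray
    category_map: dict | None = None

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.subject_ids) != n:
            raise DataError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.feature_ids) != d:
            raise DataError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if len(set(self.subject_ids)) != n:
            raise DataError("duplicate subject ids")
        if len(set(self.feature_ids)) != d:
            raise DataError("duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite feature values after zero-filling")
        if self.category_map is not None:
            missing = [f for f in self.feature_ids if f not in self.category_map]
            if missing:
                raise DataError(f"category_map misses {len(missing)} feature ids, e.g. {missing[0]!r}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ScoreVector:
    """Continuous regression labels aligned to subjects."""

    subject_ids: np.ndarray
    scores: np.ndarray
    score_name: str = "score"

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) != len(self.subject_ids):
            raise DataError("scores must be a vector aligned 1:1 with subject_ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DataError("duplicate subject ids in scores")
        if not np.all(np.isfinite(self.scores)):
            raise DataError("non-finite score values")


def check_aligned(table: FeatureTable, scores: ScoreVector) -> None:
    """Require identical subject order between a table and its labels."""
    if len(table.subject_ids) != len(scores.subject_ids) or not np.array_equal(
        table.subject_ids, scores.subject_ids
    ):
        raise DataError(
            f"subjects of table {table.measure_name!r} and scores "
            f"{scores.score_name!r} are not aligned"
        )


@dataclass
class SplitSpec:
    """Disjoint, exhaustive train/validation/test index sets."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple = (0.70, 0.10, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        parts = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        n = len(parts)
        if len(np.unique(parts)) != n or set(parts.tolist()) != set(range(n)):
            raise DataError("split is not a partition of 0..n-1")

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.val_idx) + len(self.test_idx)


def make_split(n: int, fractions: tuple = (0.70, 0.10, 0.20), seed: int = 0) -> SplitSpec:
    """Random 70/10/20-style partition of ``range(n)``, deterministic in ``seed``.

    Validation and test sizes are floored; the remainder goes to train.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError("fractions must sum to 1")
    if n < 10:
        raise DataError("need at least 10 subjects to split")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise DataError(f"n={n} too small for fractions {fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(
        train_idx=perm[:n_train],
        val_idx=perm[n_train : n_train + n_val],
        test_idx=perm[n_train + n_val :],
        fractions=tuple(fractions),
        seed=seed,
    )


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics from training rows only.

    Zero-variance training columns get scale 1 so they map to exactly 0.
    """

    location: np.ndarray
    scale: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.location) / self.scale

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.scale + self.location


def fit_standardizer(table: FeatureTable | np.ndarray, train_idx: Sequence[int]) -> Standardizer:
    """Fit per-feature location/scale on the training rows of ``table``."""
    values = table.values if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    if train_idx.size == 0:
        raise DataError("empty training index set")
    rows = values[train_idx]
    location = rows.mean(axis=0)
    scale = rows.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return Standardizer(location=location, scale=scale)


# ---------------------------------------------------------------------------
# File I/O. Tables are CSV/TSV with a header row: first column subject id,
# remaining columns one feature each. Blank cells mark empty clusters and
# load as 0; any other non-numeric cell is an error.
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def load_feature_table(
    path: str | Path,
    measure_name: str,
    category_map: Mapping | None = None,
) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise DataError(f"{path}: need a subject-id column plus >=1 feature column")
    subject_ids = df.iloc[:, 0].to_numpy(dtype=object)
    if len(set(subject_ids)) != len(subject_ids):
        raise DataError(f"{path}: duplicate subject ids")
    feats = df.iloc[:, 1:]
    try:
        numeric = feats.apply(pd.to_numeric, axis=0)
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: non-numeric feature cell: {exc}") from exc
    values = numeric.to_numpy(dtype=float)
    values = np.nan_to_num(values, nan=0.0)  # empty cluster -> 0
    return FeatureTable(
        measure_name=measure_name,
        subject_ids=subject_ids,
        feature_ids=feats.columns.to_numpy(dtype=object),
        values=values,
        category_map=dict(category_map) if category_map is not None else None,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(table.values, columns=table.feature_ids)
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, sep=_sep_for(path), index=False)


def load_scores(path: str | Path, score_name: str | None = None) -> ScoreVector:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str}, float_precision="round_trip")
    if df.shape[1] != 2:
        raise DataError(f"{path}: label file must have exactly (subject_id, score) columns")
    return ScoreVector(
        subject_ids=df.iloc[:, 0].to_numpy(dtype=object),
        scores=pd.to_numeric(df.iloc[:, 1]).to_numpy(dtype=float),
        score_name=score_name if score_name is not None else str(df.columns[1]),
    )


def write_scores(scores: ScoreVector, path: str | Path) -> None:
    df = pd.DataFrame({"subject_id": scores.subject_ids, scores.score_name: scores.scores})
    df.to_csv(path, sep=_sep_for(Path(path)), index=False)


def load_category_map(path: str | Path) -> dict:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] != 2:
        raise DataError(f"{path}: category map must have (feature_id, category) columns")
    cats = df.iloc[:, 1]
    bad = sorted(set(cats) - set(CATEGORIES))
    if bad:
        raise DataError(f"{path}: unknown categories {bad}; expected one of {CATEGORIES}")
    return dict(zip(df.iloc[:, 0], cats))


def write_category_map(category_map: Mapping, path: str | Path) -> None:
    df = pd.DataFrame(
        {"feature_id": list(category_map.keys()), "category": list(category_map.values())}
    )
    df.to_csv(path, sep=_sep_for(Path(path)), index=False)
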