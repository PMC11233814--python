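"""Ensembling across microstructure measures by unweighted averaging.

One regressor is trained per measure table (e.g. FA, MD, NoS); the ensemble
prediction for a subject is the arithmetic mean of the member predictions.
Members must target the same score and the tables must be aligned on
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import DataError, FeatureTable
from .models import TrainedRegressor


@dataclass
class EnsembleModel:
    """A list of per-measure regressors aggregated by arithmetic mean."""

    members: list[TrainedRegressor]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        names = {m.score_name for m in self.members}
        if len(names) > 1:
            raise ValueError(f"members target different scores: {sorted(names)}")

    def predict(self, tables: Sequence[FeatureTable]) -> np.ndarray:
        return ensemble_predict(self, tables)


def ensemble_predict(model: EnsembleModel, tables: Sequence[FeatureTable]) -> np.ndarray:
    """Elementwise mean of member predictions over subject-aligned tables."""
    if len(tables) != len(model.members):
        raise ValueError(
            f"{len(model.members)} members but {len(tables)} feature tables"
        )
    ref = tables[0].subject_ids
    for t in tables[1:]:
        if not np.array_equal(t.subject_ids, ref):
            raise DataError(
                f"tables {tables[0].measure_name!r} and {t.measure_name!r} "
                "are not subject-aligned"
            )
    preds = np.asarray([m.predict(t) for m, t in zip(model.members, tables)])
    if np.all(preds == preds[0]):
        return preds[0].copy()  # identical members: exact, no rounding from the mean
    return preds.mean(axis=0)
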