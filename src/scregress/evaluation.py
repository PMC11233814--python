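"""Accuracy metric and the repeated-split comparison protocol.

Prediction accuracy is Pearson's r between ground-truth and predicted
scores. Experiments are repeated over independent train/validation/test
splits (10 in the full protocol) with every compared method receiving the
identical splits, and methods are compared with paired t-tests on the
split-wise r values; a repeated-measures ANOVA is available as the omnibus
companion across three or more methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureTable, ScoreVector, SplitSpec, make_split


class DegenerateStatistic(ValueError):
    """A statistic is undefined for this input (constant vector, zero variance)."""


def pearson_r(truth: np.ndarray, pred: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input (undefined r)."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape or truth.ndim != 1 or len(truth) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if np.ptp(truth) == 0 or np.ptp(pred) == 0:
        raise DegenerateStatistic("Pearson r is undefined for a constant vector")
    return float(stats.pearsonr(truth, pred).statistic)


@dataclass
class EvalResult:
    """Per-split Pearson r values for one method, with summary statistics."""

    per_split_r: np.ndarray
    method: str
    score_name: str

    def __post_init__(self) -> None:
        self.per_split_r = np.asarray(self.per_split_r, dtype=float)
        if np.any(np.abs(self.per_split_r) > 1 + 1e-12):
            raise ValueError("Pearson r values must lie in [-1, 1]")

    @property
    def mean(self) -> float:
        return float(self.per_split_r.mean())

    @property
    def std(self) -> float:
        return float(self.per_split_r.std(ddof=1)) if len(self.per_split_r) > 1 else 0.0


# A method factory receives the tables, scores, the split and a seed, and
# returns test-set predictions aligned with split.test_idx.
MethodFactory = Callable[[Sequence[FeatureTable], ScoreVector, SplitSpec, int], np.ndarray]


def repeated_experiment(
    tables: Sequence[FeatureTable] | FeatureTable,
    scores: ScoreVector,
    method: MethodFactory,
    n_splits: int = 10,
    base_seed: int = 0,
    method_name: str = "method",
) -> EvalResult:
    """Train/evaluate ``method`` once per split and collect test-set r values.

    Splits are generated deterministically from ``base_seed``; calling this
    with the same ``base_seed`` for several methods gives each method the
    identical splits, as the comparison protocol requires.
    """
    if isinstance(tables, FeatureTable):
        tables = [tables]
    n = tables[0].n_subjects
    rs = []
    for k in range(n_splits):
        split = make_split(n, seed=base_seed + k)
        pred = method(tables, scores, split, base_seed + k)
        rs.append(pearson_r(scores.scores[split.test_idx], pred))
    return EvalResult(per_split_r=np.asarray(rs), method=method_name, score_name=scores.score_name)


def paired_comparison(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on split-aligned accuracy vectors.

    Returns ``(t, p)``. Identical vectors give t = 0, p = 1; a constant
    nonzero difference (zero variance) is degenerate and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D vectors of length >= 2")
    diff = a - b
    if np.allclose(diff, 0):
        return 0.0, 1.0
    if np.std(diff) <= 1e-10 * (1.0 + abs(diff.mean())):
        raise DegenerateStatistic("zero-variance nonzero differences: t is infinite")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def repeated_measures_anova(results: Mapping[str, np.ndarray]) -> tuple[float, float]:
    """Omnibus one-way within-subject (repeated-measures) ANOVA across methods.

    ``results`` maps method name -> per-split r vector, all split-aligned.
    No sphericity correction is applied. Returns ``(F, p)``.
    """
    from statsmodels.stats.anova import AnovaRM

    names = list(results)
    if len(names) < 3:
        raise ValueError("omnibus ANOVA needs >= 3 methods")
    lengths = {len(np.asarray(v)) for v in results.values()}
    if len(lengths) != 1:
        raise ValueError("all methods need the same number of splits")
    n = lengths.pop()
    long = pd.DataFrame(
        {
            "split": np.tile(np.arange(n), len(names)),
            "method": np.repeat(names, n),
            "r": np.concatenate([np.asarray(results[m], dtype=float) for m in names]),
        }
    )
    table = AnovaRM(long, depvar="r", subject="split", within=["method"]).fit().anova_table
    return float(table["F Value"].iloc[0]), float(table["Pr > F"].iloc[0])
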