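"""Synthetic tractometry-style data with a known planted signal.

Emulates the tabular representation the pipeline consumes: per measure
(FA/MD/NoS-like) an n_subjects x 953 matrix, a sparse linear signal on a
known subset of features, Gaussian label noise at a controlled
signal-to-noise ratio, zero-inflation emulating empty fiber clusters, and an
optional cluster -> anatomical-category map over the five tract categories.

Because the latent features are i.i.d. standard normal and the label is
``y = s + eps`` with ``s`` the planted linear signal, the best achievable
test correlation (the noise ceiling) is available in closed form:

    r_max = sqrt(var(s) / (var(s) + noise_sd**2)).

The generator records this ceiling so recovery tests can compare a model's
accuracy against what the noise allows. Labels are rescaled to sample
standard deviation 1, so scores span roughly [-3, 3] like neurocognitive
component scores; rescaling leaves all correlations unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import (
    CATEGORIES,
    FeatureTable,
    ScoreVector,
    load_category_map,
    load_feature_table,
    load_scores,
    write_category_map,
    write_feature_table,
    write_scores,
)

# affine maps from the standardized latent scale to realistic raw scales
_MEASURE_SCALES = {
    "FA": (0.5, 0.1),       # fractional anisotropy, dimensionless in [0, 1]
    "MD": (7.8e-4, 8e-5),   # mean diffusivity, mm^2/s
    "NoS": (300.0, 120.0),  # streamline count
}
_DEFAULT_MEASURES = ("FA", "MD", "NoS")


def noise_sd_for_ceiling(signal_var: float, r_max: float) -> float:
    """Noise standard deviation that yields a given noise ceiling."""
    if not 0 < r_max <= 1:
        raise ValueError("r_max must be in (0, 1]")
    return float(np.sqrt(signal_var * (1.0 / r_max**2 - 1.0)))


@dataclass
class SyntheticSpec:
    """Parameters of the generated study.

    ``noise_sd=None`` solves the noise level for ``target_ceiling`` (default
    0.6) from the drawn effect weights. Zero-inflation is applied after the
    label is built, so zeros corrupt the observed features the way empty
    clusters corrupt real tables; keep the rate low (<= 0.05) when testing
    recovery against the closed-form ceiling.
    """

    n_subjects: int = 1000
    n_features: int = 953
    n_informative: int = 50
    n_measures: int = 3
    noise_sd: float | None = None
    target_ceiling: float = 0.6
    zero_inflation_rate: float = 0.02
    nonlinear: bool = False
    score_name: str = "PC1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not 0 <= self.zero_inflation_rate < 1:
            raise ValueError("zero_inflation_rate must be in [0, 1)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.n_measures <= len(_DEFAULT_MEASURES):
            raise ValueError(f"n_measures must be in 1..{len(_DEFAULT_MEASURES)}")

    @property
    def measure_names(self) -> tuple:
        return _DEFAULT_MEASURES[: self.n_measures]


@dataclass
class GroundTruth:
    """What was planted: informative features, weights, noise and ceiling."""

    informative: dict          # measure -> list of informative feature ids
    weights: dict              # measure -> list of weights (aligned with informative)
    informative_ids: list      # union across measures
    signal_var: float
    noise_sd: float
    r_max: float
    signal: np.ndarray = field(repr=False)

    def to_json_dict(self) -> dict:
        return {
            "informative": {m: list(map(str, v)) for m, v in self.informative.items()},
            "weights": {m: [float(w) for w in v] for m, v in self.weights.items()},
            "informative_ids": list(map(str, self.informative_ids)),
            "signal_var": self.signal_var,
            "noise_sd": self.noise_sd,
            "r_max": self.r_max,
        }


def generate_dataset(spec: SyntheticSpec) -> tuple[list[FeatureTable], ScoreVector, GroundTruth]:
    """Draw one synthetic study: feature tables, labels and the ground truth.

    Latent features are i.i.d. standard normal per measure. The informative
    subset is split across measures (round-robin) so the measures carry
    complementary signal and ensembling has something to exploit. Observed
    features are affine maps of the latent values onto measure-typical
    scales, then zero-inflated.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_subjects, spec.n_features
    measures = spec.measure_names

    subject_ids = np.array([f"sub-{i:05d}" for i in range(n)], dtype=object)
    feature_ids = np.array([f"cluster_{j:04d}" for j in range(d)], dtype=object)
    category_map = dict(zip(feature_ids, rng.choice(CATEGORIES, size=d)))

    informative_idx = np.sort(rng.choice(d, size=spec.n_informative, replace=False))
    # round-robin partition across measures: complementary information
    per_measure_idx = {m: informative_idx[k :: len(measures)] for k, m in enumerate(measures)}
    # fixed-magnitude signed weights: every planted feature carries the same
    # effect size, so "informative" is a well-defined, recoverable property
    per_measure_w = {
        m: rng.choice([-1.0, 1.0], size=len(idx)) for m, idx in per_measure_idx.items()
    }

    latent = {m: rng.standard_normal((n, d)) for m in measures}
    signal = np.zeros(n)
    for m in measures:
        signal += latent[m][:, per_measure_idx[m]] @ per_measure_w[m]
    signal_var = float(sum(np.sum(w**2) for w in per_measure_w.values()))
    if spec.nonlinear:
        scale = np.sqrt(signal_var)
        signal = np.tanh(signal / scale) * scale
        signal_var = float(signal.var())  # closed form no longer applies; use the sample

    noise_sd = (
        spec.noise_sd
        if spec.noise_sd is not None
        else noise_sd_for_ceiling(signal_var, spec.target_ceiling)
    )
    r_max = float(np.sqrt(signal_var / (signal_var + noise_sd**2))) if signal_var > 0 else 0.0
    y = signal + noise_sd * rng.standard_normal(n)
    y = (y - y.mean()) / y.std()  # sample sd exactly 1; correlations unchanged

    tables = []
    for m in measures:
        loc, scale = _MEASURE_SCALES[m]
        observed = loc + scale * latent[m]
        if spec.zero_inflation_rate > 0:
            observed[rng.random((n, d)) < spec.zero_inflation_rate] = 0.0
        tables.append(
            FeatureTable(
                measure_name=m,
                subject_ids=subject_ids,
                feature_ids=feature_ids,
                values=observed,
                category_map=category_map,
            )
        )
    scores = ScoreVector(subject_ids=subject_ids, scores=y, score_name=spec.score_name)
    truth = GroundTruth(
        informative={m: feature_ids[per_measure_idx[m]].tolist() for m in measures},
        weights={m: per_measure_w[m].tolist() for m in measures},
        informative_ids=feature_ids[informative_idx].tolist(),
        signal_var=signal_var,
        noise_sd=float(noise_sd),
        r_max=r_max,
        signal=signal,
    )
    return tables, scores, truth


def write_fixture(
    tables: list[FeatureTable],
    scores: ScoreVector,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the dataset as plain CSV/JSON files; reload is exact.

    Emits one feature CSV per measure, a two-column label CSV, the
    cluster -> category map, and a ground-truth manifest. Byte-identical
    under a fixed generator seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for t in tables:
        p = out_dir / f"{t.measure_name.lower()}.csv"
        write_feature_table(t, p)
        paths[t.measure_name] = p
    paths["labels"] = out_dir / "labels.csv"
    write_scores(scores, paths["labels"])
    paths["categories"] = out_dir / "categories.csv"
    write_category_map(tables[0].category_map, paths["categories"])
    paths["ground_truth"] = out_dir / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth.to_json_dict(), indent=2))
    return paths


def load_fixture(out_dir: str | Path) -> tuple[list[FeatureTable], ScoreVector, dict]:
    """Reload a fixture directory written by :func:`write_fixture`."""
    out_dir = Path(out_dir)
    category_map = load_category_map(out_dir / "categories.csv")
    truth = json.loads((out_dir / "ground_truth.json").read_text())
    tables = []
    for m in _DEFAULT_MEASURES:
        p = out_dir / f"{m.lower()}.csv"
        if p.exists():
            tables.append(load_feature_table(p, m, category_map=category_map))
    scores = load_scores(out_dir / "labels.csv")
    return tables, scores, truth
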