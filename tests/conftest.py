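import numpy as np
import pytest

from scregress import FeatureTable, ScoreVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """A 12-subject, 5-feature table with realistic-ish FA values."""
    n, d = 12, 5
    return FeatureTable(
        measure_name="FA",
        subject_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"c{j}" for j in range(d)],
        values=0.5 + 0.1 * rng.standard_normal((n, d)),
    )


@pytest.fixture
def small_scores(small_table, rng):
    return ScoreVector(
        subject_ids=small_table.subject_ids,
        scores=rng.standard_normal(small_table.n_subjects),
        score_name="PC1",
    )
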