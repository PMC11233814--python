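import numpy as np
import pytest

from scregress import (
    FeatureTable,
    ImportanceConfig,
    ImportanceResult,
    ScoreVector,
    aggregate_by_category,
    make_split,
    pearson_r,
    run_permutation_importance,
    top_k,
)
from scregress.data import DataError

from _oracles import single_feature_permutation_importance


class LinearStub:
    """Fixed linear model with the TrainedRegressor prediction surface."""

    def __init__(self, weights):
        self.weights = np.asarray(weights, dtype=float)

    def predict_values(self, values):
        return values @ self.weights

    def predict(self, table):
        return self.predict_values(table.values)


def make_problem(rng, n=80, d=6, weights=None):
    values = rng.standard_normal((n, d))
    weights = np.zeros(d) if weights is None else np.asarray(weights, dtype=float)
    y = values @ weights + 0.1 * rng.standard_normal(n)
    table = FeatureTable("FA", [f"s{i}" for i in range(n)],
                         [f"c{j}" for j in range(d)], values)
    scores = ScoreVector(table.subject_ids, y, "PC1")
    return table, scores, make_split(n, seed=0)


class TestBookkeeping:
    def test_inclusion_count_conservation(self, rng):
        table, scores, split = make_problem(rng, weights=[1, 0, 0, 0, 0, 0])
        cfg = ImportanceConfig(group_size=3, n_permutations=50, mode="test_permute", seed=1)
        res = run_permutation_importance(table, scores, split, cfg,
                                         model=LinearStub([1, 0, 0, 0, 0, 0]))
        assert res.inclusion_counts.sum() == 3 * 50

    def test_full_group_includes_every_feature(self, rng):
        table, scores, split = make_problem(rng, weights=[1, 0, 0, 0, 0, 0])
        cfg = ImportanceConfig(group_size=6, n_permutations=9, mode="test_permute", seed=1)
        res = run_permutation_importance(table, scores, split, cfg,
                                         model=LinearStub([1, 0, 0, 0, 0, 0]))
        np.testing.assert_array_equal(res.inclusion_counts, np.full(6, 9))

    def test_undersampling_warns_and_flags(self, rng):
        table, scores, split = make_problem(rng, weights=[1, 0, 0, 0, 0, 0])
        cfg = ImportanceConfig(group_size=1, n_permutations=1, mode="test_permute", seed=1)
        with pytest.warns(UserWarning, match="never sampled"):
            res = run_permutation_importance(table, scores, split, cfg,
                                             model=LinearStub([1, 0, 0, 0, 0, 0]))
        assert res.undersampled
        assert np.isnan(res.scores).sum() == 5

    def test_group_size_exceeding_d_errors(self, rng):
        table, scores, split = make_problem(rng, weights=[1, 0, 0, 0, 0, 0])
        cfg = ImportanceConfig(group_size=7, n_permutations=5, mode="test_permute")
        with pytest.raises(ValueError, match="group_size"):
            run_permutation_importance(table, scores, split, cfg,
                                       model=LinearStub([1, 0, 0, 0, 0, 0]))


def test_constant_column_scores_zero(rng):
    """Shuffling a column that is constant across subjects changes nothing."""
    table, scores, split = make_problem(rng, weights=[1, 0, 0, 0, 0, 0])
    table.values[:, 3] = 4.2  # constant; model ignores it anyway
    cfg = ImportanceConfig(group_size=1, n_permutations=300, mode="test_permute", seed=2)
    res = run_permutation_importance(table, scores, split, cfg,
                                     model=LinearStub([1, 0, 0, 0.5, 0, 0]))
    assert res.scores[3] == 0.0


def test_single_feature_mode_matches_classical_importance(rng):
    """group_size=1 test-permute reduces to classical permutation importance."""
    weights = np.array([1.0, 0.7, 0.0, 0.3, 0.0])
    n, d = 300, 5
    values = rng.standard_normal((n, d))
    y = values @ weights
    table = FeatureTable("FA", [f"s{i}" for i in range(n)],
                         [f"c{j}" for j in range(d)], values)
    scores = ScoreVector(table.subject_ids, y, "PC1")
    split = make_split(n, seed=1)
    model = LinearStub(weights)
    cfg = ImportanceConfig(group_size=1, n_permutations=2000, mode="test_permute", seed=3)
    res = run_permutation_importance(table, scores, split, cfg, model=model)
    oracle = single_feature_permutation_importance(
        model.predict_values, values[split.test_idx], y[split.test_idx],
        pearson_r, n_rounds=400, rng=np.random.default_rng(99),
    )
    np.testing.assert_allclose(res.scores, oracle, atol=0.03)
    assert list(np.argsort(-res.scores)) == list(np.argsort(-oracle))


def test_retrain_mode_ranks_informative_feature(rng):
    """The literal protocol (shuffle training rows, refit, evaluate) ranks the
    signal-carrying feature first."""
    table, scores, split = make_problem(rng, n=100, weights=[2, 0, 0, 0, 0, 0])

    class RidgeFactory:
        def __call__(self, t, s, sp):
            x, y = t.values[sp.train_idx], s.scores[sp.train_idx]
            gram = x.T @ x + 1.0 * np.eye(x.shape[1])
            return LinearStub(np.linalg.solve(gram, x.T @ y))

    cfg = ImportanceConfig(group_size=2, n_permutations=60, mode="retrain", seed=4)
    res = run_permutation_importance(table, scores, split, cfg,
                                     model_factory=RidgeFactory())
    assert np.nanargmax(res.scores) == 0
    assert res.scores[0] > np.nanmean(res.scores[1:]) + 0.05


class TestTopK:
    def make_result(self, scores, ids=None):
        d = len(scores)
        return ImportanceResult(
            feature_ids=np.asarray(ids if ids is not None else [f"c{j}" for j in range(d)],
                                   dtype=object),
            scores=np.asarray(scores, dtype=float),
            inclusion_counts=np.ones(d, dtype=np.int64),
            baseline_r=0.5,
            config=ImportanceConfig(group_size=1, n_permutations=1, mode="test_permute"),
        )

    def test_full_ranking_is_permutation(self):
        res = self.make_result([0.3, 0.1, 0.5, 0.2])
        assert top_k(res, 4) == ["c2", "c0", "c3", "c1"]

    def test_ties_break_by_feature_id(self):
        res = self.make_result([0.2, 0.2, 0.5], ids=["b", "a", "z"])
        assert top_k(res, 3) == ["z", "a", "b"]

    def test_invalid_k_errors(self):
        res = self.make_result([0.1, 0.2])
        with pytest.raises(ValueError):
            top_k(res, 0)
        with pytest.raises(ValueError):
            top_k(res, 3)


class TestCategoryAggregation:
    def test_single_category_degenerate(self):
        cmap = {f"c{j}": "projection" for j in range(50)}
        agg = aggregate_by_category([f"c{j}" for j in range(50)], cmap)
        assert agg["projection"] == (50, 100.0)

    def test_percentage_arithmetic(self):
        cats = ["association", "projection", "commissural", "cerebellar", "superficial"]
        counts = [8, 15, 10, 5, 12]
        top, cmap = [], {}
        k = 0
        for cat, c in zip(cats, counts):
            for _ in range(c):
                cmap[f"c{k}"] = cat
                top.append(f"c{k}")
                k += 1
        agg = aggregate_by_category(top, cmap)
        assert agg["association"] == (8, 16.0)
        assert agg["projection"] == (15, 30.0)
        assert agg["commissural"] == (10, 20.0)
        assert agg["cerebellar"] == (5, 10.0)
        assert agg["superficial"] == (12, 24.0)
        assert sum(c for c, _ in agg.values()) == 50
        assert sum(p for _, p in agg.values()) == pytest.approx(100.0)

    def test_counts_conserved_for_random_maps(self, rng):
        from scregress import CATEGORIES
        top = [f"c{j}" for j in range(37)]
        cmap = {f: str(rng.choice(CATEGORIES)) for f in top}
        agg = aggregate_by_category(top, cmap)
        assert sum(c for c, _ in agg.values()) == 37

    def test_unmapped_feature_errors(self):
        with pytest.raises(DataError, match="unmapped"):
            aggregate_by_category(["c0", "c1"], {"c0": "projection"})
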