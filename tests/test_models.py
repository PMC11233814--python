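import numpy as np
import pytest

import scregress.nn as nn
from scregress import (
    EarlyStopper,
    NetworkConfig,
    SyntheticSpec,
    TrainConfig,
    TrainedRegressor,
    generate_dataset,
    make_split,
    pearson_r,
    pretrain_encoder,
    train_mlp_baseline,
    train_regressor,
)
from scregress.models import finetune_regressor


def small_task(seed=0, n=200, d=12, **spec_kw):
    spec = SyntheticSpec(
        n_subjects=n, n_features=d, n_informative=min(d, 6), n_measures=1,
        zero_inflation_rate=0.0, target_ceiling=0.9, seed=seed, **spec_kw,
    )
    tables, scores, _ = generate_dataset(spec)
    return tables[0], scores, make_split(n, seed=seed)


def small_cfg(seed=0, **kw):
    kw.setdefault("pretrain_batch", 64)
    kw.setdefault("max_epochs", 15)
    return TrainConfig(seed=seed, **kw)


class TestEarlyStopper:
    def test_patience_three_trajectory(self):
        """Losses (5.0, 4.0, 4.1, 4.2, 4.3): stop after the fifth epoch,
        best parameters from the second epoch."""
        stopper = EarlyStopper(patience=3)
        stops = [stopper.update(v, i) for i, v in enumerate([5.0, 4.0, 4.1, 4.2, 4.3])]
        assert stops == [False, False, False, False, True]
        assert stopper.best_epoch == 1  # 0-based: the second epoch

    def test_improvement_resets_patience(self):
        stopper = EarlyStopper(patience=2)
        for v in [3.0, 3.1, 2.9, 3.0]:
            assert not stopper.update(v, 0)


class TestPretraining:
    def test_deterministic_parameter_trajectories(self):
        table, scores, split = small_task(seed=1)
        std_x = table.values  # standardization not needed for determinism check
        tr, va = split.train_idx, split.val_idx
        runs = []
        for _ in range(2):
            res = pretrain_encoder(
                std_x[tr], scores.scores[tr], std_x[va], scores.scores[va],
                small_cfg(seed=5),
            )
            runs.append(res)
        for a, b in zip(runs[0].encoder + runs[0].projector,
                        runs[1].encoder + runs[1].projector):
            np.testing.assert_array_equal(a, b)
        assert runs[0].history == runs[1].history

    def test_contrastive_training_loss_decreases(self):
        """Over several seeds the recorded final training contrastive loss is
        below the first epoch's."""
        table, scores, split = small_task(seed=3, n=500, d=20)
        tr, va = split.train_idx, split.val_idx
        wins = 0
        for seed in range(5):
            cfg = small_cfg(seed=seed, pretrain_monitor="contrastive", max_epochs=10,
                            patience=10)
            res = pretrain_encoder(
                table.values[tr], scores.scores[tr],
                table.values[va], scores.scores[va], cfg,
            )
            hist = res.history["train_loss"]
            wins += hist[-1] < hist[0]
        assert wins == 5


class TestFinetuning:
    def test_encoder_parameters_bit_identical(self):
        table, scores, split = small_task(seed=2)
        model = train_regressor(table, scores, split, small_cfg(seed=2))
        # retrace: rerun the pretraining alone and compare against the
        # fine-tuned model's encoder
        from scregress.data import fit_standardizer
        std = fit_standardizer(table, split.train_idx)
        x = std.transform(table.values)
        tr, va = split.train_idx, split.val_idx
        pre = pretrain_encoder(x[tr], scores.scores[tr], x[va], scores.scores[va],
                               small_cfg(seed=2))
        for a, b in zip(pre.encoder, model.encoder):
            np.testing.assert_array_equal(a, b)

    def test_constant_labels_give_constant_predictions(self):
        table, scores, split = small_task(seed=4)
        scores.scores[:] = 1.5
        cfg = small_cfg(seed=4, max_epochs=300)
        model = train_regressor(table, scores, split, cfg)
        pred = model.predict(table)
        assert np.std(pred) < 0.15
        assert np.mean((pred - 1.5) ** 2) < 0.05


@pytest.fixture(scope="module")
def zero_noise_fitted():
    spec = SyntheticSpec(n_subjects=2000, n_features=50, n_informative=50,
                         n_measures=1, zero_inflation_rate=0.0, noise_sd=0.0,
                         seed=2)
    tables, scores, truth = generate_dataset(spec)
    split = make_split(2000, seed=2)
    model = train_regressor(tables[0], scores, split, TrainConfig(seed=2))
    return tables[0], scores, split, model


class TestZeroNoiseRecovery:
    def test_test_set_accuracy_near_ceiling(self, zero_noise_fitted):
        table, scores, split, model = zero_noise_fitted
        r = pearson_r(scores.scores[split.test_idx],
                      model.predict(table)[split.test_idx])
        assert r >= 0.95

    def test_training_set_fit(self, zero_noise_fitted):
        """Noise-free signal: the training rows are fit at least as well as
        the held-out rows (early stopping keeps the fit short of full
        interpolation)."""
        table, scores, split, model = zero_noise_fitted
        pred = model.predict(table)
        r_train = pearson_r(scores.scores[split.train_idx], pred[split.train_idx])
        r_test = pearson_r(scores.scores[split.test_idx], pred[split.test_idx])
        assert r_train >= 0.95
        assert r_train >= r_test - 0.01


@pytest.fixture(scope="module")
def predict_fitted():
    table, scores, split = small_task(seed=6)
    return table, train_regressor(table, scores, split, small_cfg(seed=6))


class TestPredict:
    @pytest.fixture
    def fitted(self, predict_fitted):
        return predict_fitted

    def test_deterministic(self, fitted):
        table, model = fitted
        np.testing.assert_array_equal(model.predict(table), model.predict(table))

    def test_row_permutation_permutes_predictions(self, fitted, rng):
        table, model = fitted
        perm = rng.permutation(table.n_subjects)
        base = model.predict_values(table.values)
        np.testing.assert_allclose(model.predict_values(table.values[perm]), base[perm],
                                   rtol=1e-5)

    def test_feature_id_mismatch_errors(self, fitted):
        table, model = fitted
        from scregress import FeatureTable
        other = FeatureTable("FA", table.subject_ids,
                             [f"x{j}" for j in range(table.n_features)], table.values)
        with pytest.raises(ValueError, match="feature ids"):
            model.predict(other)


class TestSerialization:
    def test_save_load_round_trip_bit_stable(self, tmp_path):
        table, scores, split = small_task(seed=8)
        model = train_regressor(table, scores, split, small_cfg(seed=8))
        model.save(tmp_path / "m")
        back = TrainedRegressor.load(tmp_path / "m")
        for a, b in zip(model.encoder + model.regressor, back.encoder + back.regressor):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(model.predict(table), back.predict(table))
        assert back.train_config == model.train_config
        assert back.measure_name == model.measure_name


def test_mlp_baseline_runs_and_beats_chance():
    table, scores, split = small_task(seed=9, n=600, d=10)
    model = train_mlp_baseline(table, scores, split, small_cfg(seed=9, max_epochs=40))
    r = pearson_r(scores.scores[split.test_idx], model.predict(table)[split.test_idx])
    assert model.model_kind == "mlp"
    assert r > 0.3
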