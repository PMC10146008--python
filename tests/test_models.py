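"""Neural estimators: architectures, training determinism, composite, LOO."""

import numpy as np
import pytest

import ppgbp as pb
from ppgbp.errors import (
    ConfigError,
    DataError,
    InsufficientDataError,
    LeakageError,
    SchemaError,
    StateError,
)
from ppgbp.models import (
    CANONICAL_SPECS,
    CompositeModel,
    NetworkSpec,
    NeuralEstimator,
    TrainingConfig,
)

FAST = TrainingConfig(max_epochs=300, early_stop_patience=30, seed=0)


def linear_fixture(n=120, seed=5, n_features=7):
    """Noiseless targets, linear in two of the features: recoverable."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = 120.0 + 10.0 * X[:, 0] - 5.0 * X[:, 1]
    return X, y


class TestArchitectures:
    @pytest.mark.parametrize("name, expected", [
        ("morph_ffnn", 21 * 35 + 35 + 35 * 20 + 20 + 20 * 2 + 2),   # 1532
        ("final_sbp", 8 * 10 + 10 + 10 * 1 + 1),                    # 101
    ])
    def test_dense_parameter_counts(self, name, expected):
        assert pb.build_network(name).n_params == expected

    def test_canonical_specs_dimensions(self):
        spec = CANONICAL_SPECS["morph_deep"]
        assert (spec.input_dim, spec.hidden, spec.output_dim) == (7, (70, 100, 150), 2)
        assert CANONICAL_SPECS["morph_lstm"].hidden == (64, 512)
        assert CANONICAL_SPECS["morph_gru"].hidden == (128, 256, 512)
        assert CANONICAL_SPECS["morph_lstm"].hidden_activation == "relu"

    def test_same_seed_same_initial_parameters(self):
        a = pb.build_network("final_sbp", seed=9)
        b = pb.build_network("final_sbp", seed=9)
        for pa, pc in zip(a.get_params(), b.get_params()):
            np.testing.assert_array_equal(pa, pc)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigError):
            NetworkSpec("bad", 7, (10, 0), "sigmoid", 1)


class TestGradients:
    @pytest.mark.parametrize("kind, hidden, act", [
        ("dense", (5, 4), "sigmoid"),
        ("lstm", (6,), "relu"),
        ("gru", (6,), "relu"),
    ])
    def test_backprop_matches_numerical_gradient(self, kind, hidden, act):
        spec = NetworkSpec("t", 3, hidden, act, 2, kind)
        est = NeuralEstimator(spec, seed=1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 3))
        y = rng.normal(size=(7, 2))
        pred, caches = est._forward(X)
        grads = est._backward(2 * (pred - y) / 7, caches)
        params = [p for layer in est.layers for p in layer.params]

        def loss():
            p, _ = est._forward(X)
            return float(np.mean(np.sum((p - y) ** 2, axis=1)))

        for p, g in zip(params, grads):
            flat_idx = np.unravel_index(
                np.argmax(np.abs(g)), p.shape)  # check the largest gradient
            for idx in [flat_idx, (0,) * p.ndim]:
                orig = p[idx]
                eps = 1e-6
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


class TestTraining:
    def test_recoverable_mapping_low_error(self):
        X, y = linear_fixture()
        spec = NetworkSpec("lin", 7, (10,), "sigmoid", 1)
        est = NeuralEstimator(spec, seed=3).fit(X[:100], y[:100],
                                                TrainingConfig(seed=3))
        held_out = est.predict(X[100:]).ravel()
        assert np.mean(np.abs(held_out - y[100:])) < 1.0
        re_pred = est.predict(X[:100]).ravel()
        assert np.mean(np.abs(re_pred - y[:100])) < 1.0

    def test_sklearn_oracle_agrees_on_fixture(self):
        """Independent cross-check: an established MLP fits the same
        recoverable fixture to comparable held-out error."""
        from sklearn.neural_network import MLPRegressor

        X, y = linear_fixture()
        ours = NeuralEstimator(NetworkSpec("lin", 7, (10,), "sigmoid", 1),
                               seed=3).fit(X[:100], y[:100],
                                           TrainingConfig(seed=3))
        ref = MLPRegressor(hidden_layer_sizes=(10,), activation="logistic",
                           solver="lbfgs", max_iter=5000, alpha=1e-4,
                           random_state=0).fit(X[:100], y[:100])
        mae_ours = np.mean(np.abs(ours.predict(X[100:]).ravel() - y[100:]))
        mae_ref = np.mean(np.abs(ref.predict(X[100:]) - y[100:]))
        assert mae_ours < 1.0 and mae_ref < 1.0

    def test_training_is_deterministic(self):
        X, y = linear_fixture(n=60)
        cfg = TrainingConfig(max_epochs=200, seed=7)
        a = NeuralEstimator(NetworkSpec("d", 7, (8,), "sigmoid", 1), seed=2).fit(X, y, cfg)
        b = NeuralEstimator(NetworkSpec("d", 7, (8,), "sigmoid", 1), seed=2).fit(X, y, cfg)
        for pa, pc in zip(a.get_params(), b.get_params()):
            np.testing.assert_array_equal(pa, pc)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_missing_value_names_row(self):
        X, y = linear_fixture(n=30)
        X[4, 2] = np.nan
        est = NeuralEstimator(NetworkSpec("d", 7, (5,), "sigmoid", 1), seed=0)
        with pytest.raises(DataError, match="4"):
            est.fit(X, y, FAST)

    def test_too_few_rows(self):
        X, y = linear_fixture(n=10)
        est = NeuralEstimator(NetworkSpec("d", 7, (5,), "sigmoid", 1), seed=0)
        with pytest.raises(InsufficientDataError):
            est.fit(X, y, FAST)

    def test_scaler_uses_training_split_only(self):
        X, y = linear_fixture(n=80)
        est = NeuralEstimator(NetworkSpec("d", 7, (5,), "sigmoid", 1), seed=0)
        est.fit(X, y, FAST)
        np.testing.assert_allclose(est.scaler_mean_,
                                   X[est.train_indices_].mean(axis=0))
        np.testing.assert_allclose(
            est.scaler_sd_, X[est.train_indices_].std(axis=0))
        assert np.intersect1d(est.train_indices_, est.val_indices_).size == 0

    def test_recurrent_nets_train_and_predict(self):
        X, y = linear_fixture(n=60)
        y2 = np.column_stack([y, y - 50.0])
        for arch in ("morph_lstm", "morph_gru"):
            est = pb.build_network(arch, seed=1)
            est.fit(X, y2, TrainingConfig(max_epochs=150,
                                          early_stop_patience=20, seed=1))
            pred = est.predict(X)
            assert pred.shape == (60, 2)
            assert np.all(np.isfinite(pred))

    def test_bayes_reg_trainer_fits_small_net(self):
        X, y = linear_fixture(n=80)
        Xb = np.column_stack([X, np.zeros(80)])  # pad to the 8-input final net
        est = pb.build_network("final_sbp", seed=4)
        est.fit(Xb, y, TrainingConfig(bayes_reg=True, seed=4))
        assert est.training_log["trainer"] == "bayes_reg"
        assert np.mean(np.abs(est.predict(Xb).ravel() - y)) < 2.0


class TestPredict:
    def test_untrained_predict_rejected(self):
        with pytest.raises(StateError):
            pb.build_network("final_sbp").predict(np.zeros((3, 8)))

    def test_schema_mismatch(self):
        X, y = linear_fixture(n=40)
        est = NeuralEstimator(NetworkSpec("d", 7, (5,), "sigmoid", 1), seed=0)
        est.fit(X, y, FAST)
        with pytest.raises(SchemaError):
            est.predict(np.zeros((3, 22)))

    def test_row_permutation_permutes_outputs(self):
        X, y = linear_fixture(n=40)
        est = NeuralEstimator(NetworkSpec("d", 7, (5,), "sigmoid", 1), seed=0)
        est.fit(X, y, FAST)
        perm = np.random.default_rng(0).permutation(40)
        np.testing.assert_allclose(est.predict(X)[perm], est.predict(X[perm]),
                                   atol=1e-12)


class TestComposite:
    def test_pass_through_construction(self):
        """With pure-noise dynamics features, the final nets can only learn
        to relay the stage-1 morphology estimate."""
        rng = np.random.default_rng(6)
        n = 150
        morph7 = rng.normal(size=(n, 7))
        y = np.column_stack([120 + 12 * morph7[:, 0] - 4 * morph7[:, 1],
                             70 + 6 * morph7[:, 2] + 3 * morph7[:, 3]])
        dyn7 = rng.normal(size=(n, 7)) * 0.01
        X = np.column_stack([morph7, dyn7])
        model = CompositeModel(seed=2, cfg=TrainingConfig(seed=2))
        model.fit(X, y)
        stage1 = model.nets["morph_deep"].predict(morph7)
        composite = model.predict(X)
        assert np.mean(np.abs(composite - stage1)) < 1.0

    def test_row_count_preserved(self, cohort_table_40):
        from ppgbp.pipeline import composite_design_matrix, targets_matrix

        table, _ = cohort_table_40
        X = composite_design_matrix(table)
        model = CompositeModel(seed=0, cfg=FAST)
        model.fit(X[:30], targets_matrix(table)[:30], FAST)
        assert model.predict(X).shape == (len(table), 2)

    def test_untrained_net_rejected(self):
        nets = {k: pb.build_network(k) for k in
                ("morph_deep", "final_sbp", "final_dbp")}
        with pytest.raises(StateError):
            pb.composite_estimate(np.zeros((2, 7)), np.zeros((2, 7)), nets)

    def test_constant_morphology_estimate_degrades_gracefully(self):
        rng = np.random.default_rng(13)
        n = 80
        dyn7 = rng.normal(size=(n, 7))
        y = 100 + 5 * dyn7[:, 0]
        X8 = np.column_stack([dyn7, np.full(n, 110.0)])  # constant 8th input
        est = pb.build_network("final_sbp", seed=1).fit(X8, y, FAST)
        assert np.all(np.isfinite(est.predict(X8)))


class TestLOO:
    def _builder(self, seed):
        return NeuralEstimator(NetworkSpec("d", 3, (5,), "sigmoid", 1),
                               seed=seed)

    def test_five_subjects_five_estimates(self):
        rng = np.random.default_rng(1)
        # LOO trains on n-1 = 24 rows, above the minimum-row rule
        X = rng.normal(size=(25, 3))
        y = 110 + 4 * X[:, 0]
        preds = pb.loo_evaluate(X, y, self._builder, FAST)
        assert preds.shape == (25,)

    def test_duplicated_subject_detected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        X[11] = X[3]
        y = 110 + 4 * X[:, 0]
        with pytest.raises(LeakageError):
            pb.loo_evaluate(X, y, self._builder, FAST)

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            pb.loo_evaluate(np.zeros((4, 3)), np.zeros(4), self._builder, FAST)

    def test_loo_never_trains_on_held_out_row(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 3))
        y = 110 + 4 * X[:, 0]
        seen: list[np.ndarray] = []
        outer = self

        class SpyModel:
            def __init__(self, seed):
                self.inner = outer._builder(seed)

            def fit(self, Xtr, ytr, cfg=None):
                seen.append(np.asarray(Xtr).copy())
                self.inner.fit(Xtr, ytr, cfg)
                return self

            def predict(self, Xte):
                return self.inner.predict(Xte)

        pb.loo_evaluate(X, y, SpyModel, FAST)
        for i, Xtr in enumerate(seen):
            assert not np.any(np.all(Xtr == X[i], axis=1))
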