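from __future__ import annotations

import numpy as np
import pytest

from actisleep import ModelSpec, SleepQualityClassifier, parameter_count
from actisleep import _nn


def _toy_problem(n=40, length=60, seed=0, gap=3.0):
    """Two classes with constant-mean activity shifted by `gap` standard errors."""
    rng = np.random.default_rng(seed)
    y = np.array(["poor", "good"] * (n // 2))
    X = rng.normal(200.0, 30.0, (n, length))
    X[y == "good"] += gap * 30.0
    return np.abs(X), y


class TestParameterCounts:
    @pytest.mark.parametrize(
        "spec,length,expected",
        [
            (ModelSpec("lr"), 960, 960 + 1),
            (ModelSpec("mlp"), 960, 960 * 15 + 15 + 15 + 1),
            (ModelSpec("rnn"), 960, 1 * 75 + 75 * 75 + 75 + 75 + 1),
            (ModelSpec("lstm"), 960, (1 + 100) * 400 + 400 + 100 + 1),
            (ModelSpec("tb_lstm"), 960, (15 + 100) * 400 + 400 + 100 + 1),
        ],
    )
    def test_count_is_pure_function_of_spec_and_shape(self, spec, length, expected):
        assert parameter_count(spec, length) == expected

    def test_cnn_count(self):
        # 25 filters of length 5 -> conv map 956, pooled 239, flat 5975
        expected = 5 * 25 + 25 + 239 * 25 * 1 + 1
        assert parameter_count(ModelSpec("cnn"), 960) == expected


class TestEquivalences:
    def test_mlp_without_hidden_layer_matches_logistic_regression(self):
        rng = np.random.default_rng(4)
        L = 30
        X = rng.normal(0, 1, (8, L))
        w, b = rng.normal(0, 1, (L, 1)), np.array([0.3])
        lr_net = _nn.LogisticNet(L)
        mlp0_net = _nn.MLPNet(L, hidden_size=0)
        p_lr, _ = lr_net.forward({"w": w, "b": b}, X, train=False, rng=None)
        p_mlp, _ = mlp0_net.forward({"w2": w, "b2": b}, X, train=False, rng=None)
        np.testing.assert_allclose(p_lr, p_mlp, rtol=0, atol=0)

    def test_all_zero_weights_give_half_confidence(self):
        net = _nn.LogisticNet(10)
        p, _ = net.forward({"w": np.zeros((10, 1)), "b": np.zeros(1)}, np.ones((3, 10)), False, None)
        np.testing.assert_allclose(p, 0.5)


class TestGradients:
    def test_five_parameter_lr_numeric_vs_analytic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (6, 4))
        y = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        net = _nn.LogisticNet(4, dropout=0.0)
        params = net.init_params(rng)
        p, cache = net.forward(params, X, train=False, rng=None)
        grads = net.backward(params, cache, (p - y) / len(y))

        def loss(ps):
            pp, _ = net.forward(ps, X, train=False, rng=None)
            return _nn.bce_loss(pp, y)

        num = _nn.numerical_gradient(loss, params)
        for name in params:
            np.testing.assert_allclose(grads[name], num[name], atol=1e-5)

    @pytest.mark.parametrize("arch", ["mlp", "cnn", "rnn", "lstm", "tb_lstm"])
    def test_backprop_matches_numerical_gradient(self, arch):
        rng = np.random.default_rng(2)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        if arch == "mlp":
            net, batch = _nn.MLPNet(12, 5, dropout=0.0), rng.normal(0, 1, (4, 12))
        elif arch == "cnn":
            net, batch = _nn.ConvNet(12, 3, 5, 4, dropout=0.0), rng.normal(0, 1, (4, 12))
        else:
            D = 3 if arch == "tb_lstm" else 1
            cls = _nn.ElmanNet if arch == "rnn" else _nn.LSTMNet
            net = cls(D, hidden_size=5, dropout=0.0)
            mask = np.ones((4, 6), dtype=bool)
            mask[0, :2] = mask[2, :4] = False  # left-padded rows
            batch = (rng.normal(0, 1, (4, 6, D)), mask)
        params = net.init_params(rng)
        p, cache = net.forward(params, batch, train=False, rng=None)
        grads = net.backward(params, cache, (p - y) / len(y))

        def loss(ps):
            pp, _ = net.forward(ps, batch, train=False, rng=None)
            return _nn.bce_loss(pp, y)

        num = _nn.numerical_gradient(loss, params)
        for name in params:
            np.testing.assert_allclose(grads[name], num[name], atol=1e-6)


class TestTraining:
    def test_separable_classes_reach_perfect_training_accuracy(self):
        X, y = _toy_problem(n=20, gap=8.0)
        model = SleepQualityClassifier("lr", fixed_length=60, random_state=0)
        model.fit(X, y, validation_data=(X, y))
        assert (model.predict(X) == y).all()
        assert model.n_epochs_ <= 50

    def test_max_epochs_one_runs_exactly_one_epoch(self):
        X, y = _toy_problem()
        model = SleepQualityClassifier("mlp", fixed_length=60, max_epochs=1, random_state=0)
        model.fit(X, y)
        assert [e["epoch"] for e in model.training_log_] == [1]

    @pytest.mark.parametrize("arch", ["lr", "cnn", "lstm"])
    def test_same_seed_gives_identical_fit_and_log(self, arch):
        X, y = _toy_problem(n=24)
        fits = []
        for _ in range(2):
            m = SleepQualityClassifier(arch, fixed_length=60, max_epochs=3, random_state=7)
            m.fit(X, y)
            fits.append(m)
        a, b = fits
        assert a.training_log_ == b.training_log_
        for k in a.params_:
            np.testing.assert_array_equal(a.params_[k], b.params_[k])

    def test_early_stopping_restores_best_validation_epoch(self):
        X, y = _toy_problem(n=40, gap=1.0, seed=3)
        Xv, yv = _toy_problem(n=20, gap=1.0, seed=4)
        model = SleepQualityClassifier("mlp", fixed_length=60, max_epochs=30, random_state=5)
        model.fit(X, y, validation_data=(Xv, yv))
        accs = [e["val_accuracy"] for e in model.training_log_]
        if model.training_log_[-1].get("early_stopped"):
            returned = accs[-2]  # previous epoch's parameters were restored
            assert returned >= max(accs[:-1]) - 1e-12
            assert accs[-1] < accs[-2]
        assert len(accs) <= 30

    def test_prediction_is_deterministic_and_bounded(self):
        X, y = _toy_problem(n=24)
        model = SleepQualityClassifier("tb_lstm", fixed_length=60, max_epochs=2, random_state=0)
        model.fit(X, y)
        p1 = model.predict_proba(X)[:, 1]
        p2 = model.predict_proba(X)[:, 1]
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_save_load_round_trip(self, tmp_path):
        X, y = _toy_problem(n=24)
        model = SleepQualityClassifier("cnn", fixed_length=60, max_epochs=2, random_state=0)
        model.fit(X, y)
        model.save(tmp_path / "cnn")
        back = SleepQualityClassifier.load(tmp_path / "cnn")
        np.testing.assert_allclose(
            model.predict_proba(X), back.predict_proba(X), atol=0
        )


class TestSklearnCompat:
    def test_get_set_params_round_trip(self):
        model = SleepQualityClassifier("cnn", conv_filters=10)
        params = model.get_params()
        assert params["architecture"] == "cnn"
        clone = SleepQualityClassifier(**params)
        assert clone.get_params() == params

    def test_works_in_sklearn_clone_and_pipeline(self):
        from sklearn.base import clone

        model = SleepQualityClassifier("mlp", max_epochs=2, fixed_length=60)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
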