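import numpy as np
import pytest

import pestcast as pc
from oracles import finite_difference_gradients
from pestcast.errors import (DegenerateLabelsError, InsufficientDataError,
                             InvalidArgumentError)
from pestcast.lstm import (CellState, LSTMParameters, TrainingConfig,
                           bce_loss, forward, init_rmsprop_state,
                           loss_and_gradients, lstm_cell_forward,
                           make_windows, predict, rmsprop_step, sgd_step,
                           train)

SIG1 = 1.0 / (1.0 + np.exp(-1.0))  # sigmoid(1)


def _unit_weights(value=1.0, units=1, feats=1):
    shape = (units, units + feats)
    return {f"{kind}_{g}": (np.full(shape, value) if kind == "W"
                            else np.zeros(units))
            for g in "ifoc" for kind in ("W", "b")}


def _awake_params(n_features, units=2, n_layers=1, fc_hidden=3, seed=5):
    """Random parameters with non-zero biases so no activation sits exactly
    on the ReLU kink (where finite differences are invalid)."""
    params = LSTMParameters.initialize(n_features, units=units,
                                       n_layers=n_layers,
                                       fc_hidden=fc_hidden, seed=seed,
                                       scale=0.6)
    rng = np.random.default_rng(seed + 1)
    for key, block in params.blocks.items():
        if block.ndim == 1:
            params.blocks[key] = rng.normal(0.3, 0.4, size=block.shape)
    return params


class TestCellForward:
    def test_zero_weights_give_half_gates_and_zero_state(self):
        weights = _unit_weights(0.0, units=3, feats=2)
        state = CellState(h=np.zeros(3), c=np.zeros(3))
        out = lstm_cell_forward(np.zeros(2), state, weights)
        assert np.allclose(out.i, 0.5) and np.allclose(out.f, 0.5)
        assert np.allclose(out.o, 0.5)
        assert np.allclose(out.c, 0.0) and np.allclose(out.h, 0.0)

    def test_hand_computed_single_unit_cell(self):
        # one unit, one feature, all weights 1, x=1, zero initial state:
        # gates sigmoid(1), candidate tanh(1), C = i*g, h = o*tanh(C)
        weights = _unit_weights(1.0)
        state = CellState(h=np.zeros(1), c=np.zeros(1))
        out = lstm_cell_forward(np.ones(1), state, weights)
        assert out.i[0] == pytest.approx(SIG1, abs=1e-4)
        assert out.g[0] == pytest.approx(np.tanh(1.0), abs=1e-4)
        assert out.c[0] == pytest.approx(SIG1 * np.tanh(1.0), abs=1e-4)
        assert out.h[0] == pytest.approx(
            SIG1 * np.tanh(SIG1 * np.tanh(1.0)), abs=1e-4)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        weights = {k: rng.normal(0, 0.8, size=v.shape)
                   for k, v in _unit_weights(0.0, units=4, feats=3).items()}
        state = CellState(h=rng.normal(size=4), c=rng.normal(size=4))
        out = lstm_cell_forward(rng.normal(size=3), state, weights)
        for gate in (out.i, out.f, out.o):
            assert np.all((gate > 0) & (gate < 1))
        assert np.all(np.abs(out.g) < 1)


class TestForward:
    def test_zero_parameters_output_half(self):
        params = LSTMParameters.initialize(9, seed=0, scale=0.0)
        window = np.random.default_rng(1).normal(size=(4, 9))
        assert forward(window, params) == pytest.approx(0.5)

    def test_output_bounded_and_hidden_bounded(self):
        rng = np.random.default_rng(2)
        for trial in range(50):
            params = _awake_params(5, units=3, seed=trial)
            batch = rng.normal(0, 3, size=(20, 4, 5))
            probs = forward(batch, params)
            assert np.all((probs > 0) & (probs < 1))

    def test_manual_two_step_unroll(self):
        # 1 unit, 1 feature, T=2: replay the cell equations by hand
        params = LSTMParameters.initialize(1, units=1, fc_hidden=1, seed=3,
                                           scale=0.0)
        for g in "ifoc":
            params.blocks[f"lstm0.W_{g}"][:] = 0.5
        params.blocks["lstm0.b_f"][:] = 0.0
        params.blocks["fc1.W"][:] = 1.0
        params.blocks["fc2.W"][:] = 1.0
        x = np.array([[1.0], [2.0]])
        h = c = 0.0
        for t in range(2):
            z = 0.5 * (h + x[t, 0])
            i = f = o = 1.0 / (1.0 + np.exp(-z))
            g_ = np.tanh(z)
            c = f * c + i * g_
            h = o * np.tanh(c)
        expected = 1.0 / (1.0 + np.exp(-max(h, 0.0)))
        assert forward(x, params) == pytest.approx(expected, abs=1e-12)

    def test_feature_mismatch_rejected(self):
        params = LSTMParameters.initialize(9, seed=0)
        with pytest.raises(InvalidArgumentError):
            forward(np.zeros((4, 8)), params)


class TestLoss:
    def test_confident_correct_prediction_has_tiny_loss(self):
        assert bce_loss([1.0], [1.0 - 1e-9]) < 1e-6

    def test_uninformative_prediction_is_ln_two(self):
        assert bce_loss([0.0], [0.5]) == pytest.approx(np.log(2.0))

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 64).astype(float)
        p = rng.uniform(0.01, 0.99, 64)
        direct = -sum(yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                      for yi, pi in zip(y, p)) / 64
        assert bce_loss(y, p) == pytest.approx(direct, abs=1e-12)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        rng = np.random.default_rng(10)
        params = _awake_params(3, units=2, n_layers=1)
        x = rng.normal(size=(4, 4, 3))
        y = np.array([0, 1, 1, 0])
        _, grads = loss_and_gradients(x, y, params)
        fd = finite_difference_gradients(
            lambda: loss_and_gradients(x, y, params)[0], params)
        for key in grads:
            num = np.linalg.norm(fd[key] - grads[key])
            den = np.linalg.norm(fd[key]) + np.linalg.norm(grads[key]) + 1e-12
            assert num / den < 1e-5, key

    def test_bptt_matches_finite_differences_stacked_with_dropout(self):
        rng = np.random.default_rng(11)
        params = _awake_params(3, units=2, n_layers=2)
        x = rng.normal(size=(3, 4, 3))
        y = np.array([1, 0, 1])
        mask = (rng.random((3, 2)) >= 0.1) / 0.9
        _, grads = loss_and_gradients(x, y, params, mask)
        fd = finite_difference_gradients(
            lambda: loss_and_gradients(x, y, params, mask)[0], params)
        for key in grads:
            num = np.linalg.norm(fd[key] - grads[key])
            den = np.linalg.norm(fd[key]) + np.linalg.norm(grads[key]) + 1e-12
            assert num / den < 1e-5, key

    def test_duplicated_batch_leaves_mean_gradient_unchanged(self):
        rng = np.random.default_rng(12)
        params = _awake_params(3)
        x = rng.normal(size=(5, 4, 3))
        y = np.array([0, 1, 0, 1, 1])
        _, g1 = loss_and_gradients(x, y, params)
        _, g2 = loss_and_gradients(np.tile(x, (2, 1, 1)), np.tile(y, 2),
                                   params)
        for key in g1:
            assert np.allclose(g1[key], g2[key], atol=1e-12)

    def test_zero_gradient_at_symmetric_stationary_point(self):
        # all-zero weights, balanced labels: output is exactly 1/2 and the
        # per-sample logit gradients cancel pairwise
        params = LSTMParameters.initialize(3, seed=0, scale=0.0)
        params.blocks["lstm0.b_f"][:] = 0.0
        x = np.random.default_rng(13).normal(size=(6, 4, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        _, grads = loss_and_gradients(x, y, params)
        for key, g in grads.items():
            assert np.allclose(g, 0.0, atol=1e-15), key


class TestOptimizers:
    def test_sgd_zero_gradient_is_identity(self):
        p = {"w": np.array([1.0, -2.0])}
        out = sgd_step(p, {"w": np.zeros(2)}, 0.1)
        assert np.array_equal(out["w"], p["w"])

    def test_sgd_arithmetic_and_linearity(self):
        p = {"w": np.array([1.0])}
        g = {"w": np.array([2.0])}
        assert sgd_step(p, g, 0.1)["w"][0] == pytest.approx(0.8)
        twice = sgd_step(sgd_step(p, g, 0.1), g, 0.1)
        assert twice["w"][0] == pytest.approx(sgd_step(p, g, 0.2)["w"][0])

    def test_rmsprop_single_step_hand_value(self):
        p = {"w": np.array([0.0])}
        g = {"w": np.array([1.0])}
        v = init_rmsprop_state(p)
        new, state = rmsprop_step(p, g, v, lr=0.001, gamma=0.9, eps=0.0)
        assert state["w"][0] == pytest.approx(0.1)
        assert new["w"][0] == pytest.approx(-0.001 / np.sqrt(0.1))

    def test_rmsprop_zero_gradient_decays_v_only(self):
        p = {"w": np.array([3.0])}
        state = {"w": np.array([0.4])}
        new, state = rmsprop_step(p, {"w": np.zeros(1)}, state, gamma=0.9)
        assert new["w"][0] == pytest.approx(3.0)
        assert state["w"][0] == pytest.approx(0.36)

    def test_rmsprop_v_converges_to_squared_gradient(self):
        p = {"w": np.array([0.0])}
        g = {"w": np.array([2.0])}
        state = init_rmsprop_state(p)
        for _ in range(300):
            p, state = rmsprop_step(p, g, state, lr=1e-6, gamma=0.9)
        assert state["w"][0] == pytest.approx(4.0, rel=1e-8)


class TestWindows:
    def _series(self, n, seed=0):
        ds = pc.generate_weather_series(n, seed=seed)
        rng = np.random.default_rng(seed + 1)
        return ds.with_pest(rng.integers(0, 3, n).astype(float))

    def test_window_count_and_future_labels(self):
        ds = self._series(10)
        w = make_windows(ds, timesteps=4, standardize_fraction=None)
        assert len(w) == 6
        assert np.array_equal(w.labels, ds.occurrence[4:])
        assert np.array_equal(w.windows[0][:, -1], ds.pest_value[:4])

    def test_excluding_pest_history_drops_to_eight_features(self):
        w = make_windows(self._series(30), include_pest_history=False)
        assert w.n_features == 8

    def test_series_no_longer_than_window_rejected(self):
        with pytest.raises(InsufficientDataError):
            make_windows(self._series(4), timesteps=4)

    def test_standardization_uses_training_rows_only(self):
        ds = self._series(100)
        w = make_windows(ds, timesteps=4, standardize_fraction=0.75)
        n_train = int(0.75 * len(w))
        train_rows = w.windows[:n_train]
        # rows feeding the training windows are standardized to ~N(0,1)
        flat = train_rows.reshape(-1, w.n_features)
        assert np.all(np.abs(flat.mean(axis=0)) < 0.2)


class TestTraining:
    @staticmethod
    def _toy_windows(n=120, seed=6):
        """Linearly separable toy: window mean decides the label."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 0.3, size=(n, 4, 3)) + (2.0 * y - 1.0)[:, None, None]
        return pc.WindowedDataset(x, y, ("f1", "f2", "f3"))

    def test_rmsprop_halves_training_loss_on_strong_signal(self):
        data = self._toy_windows()
        cfg = TrainingConfig(seed=1, epochs=200, dropout=0.0)
        _, history = train(data, cfg)
        assert history[-1] < history[0] / 2

    def test_sgd_also_converges_on_separable_toy(self):
        data = self._toy_windows()
        cfg = TrainingConfig(optimizer="sgd", learning_rate=0.5, seed=1,
                             epochs=80, dropout=0.0)
        _, history = train(data, cfg)
        assert history[-1] < history[0] / 2

    def test_fixed_seed_reproduces_parameters_exactly(self):
        data = self._toy_windows()
        cfg = TrainingConfig(seed=9, epochs=10)
        p1, h1 = train(data, cfg)
        p2, h2 = train(data, cfg)
        assert h1 == h2
        for key in p1.keys():
            assert np.array_equal(p1[key], p2[key])

    def test_single_class_labels_rejected(self):
        data = self._toy_windows()
        bad = pc.WindowedDataset(data.windows, np.ones(len(data), int),
                                 data.feature_names)
        with pytest.raises(DegenerateLabelsError):
            train(bad, TrainingConfig(seed=0))


class TestEndToEndRecovery:
    def test_high_auc_on_clean_planted_signal(self, tmp_path):
        """With planted rule confidence 0.9 and persistence 0.8 (no label
        noise) the trained network separates the held-out weeks almost
        perfectly."""
        cfg = pc.PipelineConfig.from_dict(
            {"seed": 5, "synthetic": {"n_weeks": 1200, "label_noise": 0.0}})
        report = pc.run_forecast_experiment(cfg, tmp_path)
        assert report.auc >= 0.95


class TestPredict:
    def test_zero_params_all_labels_one_at_half_threshold(self):
        params = LSTMParameters.initialize(3, seed=0, scale=0.0)
        x = np.random.default_rng(0).normal(size=(5, 4, 3))
        labels, scores = predict(params, x)
        assert np.allclose(scores, 0.5)
        assert labels.all()  # >= convention at threshold 0.5

    def test_scores_match_forward_exactly(self):
        params = _awake_params(3)
        x = np.random.default_rng(1).normal(size=(7, 4, 3))
        _, scores = predict(params, x)
        assert np.allclose(scores, forward(x, params), atol=0)

    def test_checkpoint_round_trip(self, tmp_path):
        params = _awake_params(4, units=3)
        path = tmp_path / "ckpt.json"
        params.save(path)
        restored = LSTMParameters.load(path)
        x = np.random.default_rng(2).normal(size=(3, 4, 4))
        assert np.allclose(forward(x, params), forward(x, restored),
                           atol=1e-15)
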