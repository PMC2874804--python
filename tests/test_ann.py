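"""The 4-H-1 logistic network: forward pass, gradients, training, scaling."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import driftnet as dn
from driftnet.ann import loss_and_gradients, logistic, _forward_batch


def finite_difference_grads(model, X, y, h=1e-6):
    """Central-difference gradients of the MSE loss, parameter by parameter."""
    grads = {}
    for name in ("w_hidden", "b_hidden", "w_out", "b_out"):
        arr = getattr(model, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            lp, _ = loss_and_gradients(model, X, y)
            arr[idx] = orig - h
            lm, _ = loss_and_gradients(model, X, y)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2 * h)
        grads[name] = g
    return grads


def random_model_and_batch(rng, h=None, n=None):
    h = h or int(rng.integers(1, 5))
    n = n or int(rng.integers(1, 12))
    model = dn.init_network(h, dn.TrainingConfig(seed=int(rng.integers(2**31)), init_range=1.0))
    X = rng.uniform(-1, 1, size=(4, n))
    y = rng.uniform(0.1, 0.9, size=n)
    return model, X, y


class TestInit:
    def test_same_seed_is_bitwise_identical(self):
        cfg = dn.TrainingConfig(seed=99)
        a, b = dn.init_network(3, cfg), dn.init_network(3, cfg)
        for name in ("w_hidden", "b_hidden", "w_out", "b_out"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_shapes_for_three_hidden_nodes(self):
        m = dn.init_network(3)
        assert m.w_hidden.shape == (3, 4)
        assert m.w_out.shape == (1, 3)
        assert m.b_hidden.shape == (3,) and m.b_out.shape == (1,)
        assert m.layer_sizes == (4, 3, 1)

    def test_zero_init_range_gives_zero_weights(self):
        m = dn.init_network(2, dn.TrainingConfig(init_range=0.0))
        assert not m.w_hidden.any() and not m.w_out.any()

    def test_hidden_below_one_rejected(self):
        with pytest.raises(dn.ValidationError):
            dn.init_network(0)


class TestForward:
    def test_all_zero_parameters_give_half_activations(self):
        m = dn.init_network(3, dn.TrainingConfig(init_range=0.0))
        out, hidden = dn.forward(m, np.zeros(4))
        assert out == 0.5
        assert np.all(hidden == 0.5)

    @given(x=st.floats(-30, 30))
    def test_logistic_symmetry(self, x):
        assert logistic(np.array(x)) + logistic(np.array(-x)) == pytest.approx(1.0)

    def test_hand_computed_single_hidden_node(self):
        """Pencil-and-paper two-layer composition for H=1."""
        m = dn.init_network(1, dn.TrainingConfig(init_range=0.0))
        m.w_hidden[:] = [[0.2, -0.4, 0.6, 0.1]]
        m.b_hidden[:] = [0.05]
        m.w_out[:] = [[1.5]]
        m.b_out[:] = [-0.3]
        x = np.array([0.5, -1.0, 0.25, 2.0])
        net_h = 0.2 * 0.5 - 0.4 * -1.0 + 0.6 * 0.25 + 0.1 * 2.0 + 0.05
        a_h = 1 / (1 + math.exp(-net_h))
        expected = 1 / (1 + math.exp(-(1.5 * a_h - 0.3)))
        out, hidden = dn.forward(m, x)
        assert out == pytest.approx(expected, abs=1e-12)
        assert hidden[0] == pytest.approx(a_h, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(dn.ValidationError):
            dn.forward(dn.init_network(3), np.zeros(5))

    def test_output_always_in_open_unit_interval(self, rng):
        for _ in range(20):
            m, X, _ = random_model_and_batch(rng)
            A2, _ = _forward_batch(m, X)
            assert np.all(A2 > 0) and np.all(A2 < 1)


class TestTargetScaler:
    def test_endpoints_map_to_margins(self):
        s = dn.TargetScaler(t_min=1.0, t_max=19.0, margin=0.1)
        assert s.scale(1.0) == pytest.approx(0.1)
        assert s.scale(19.0) == pytest.approx(0.9)

    def test_midpoint(self):
        s = dn.TargetScaler(t_min=1.0, t_max=19.0, margin=0.1)
        assert s.scale(10.0) == pytest.approx(0.5)

    @given(t=st.floats(0.1, 50))
    def test_round_trip_identity(self, t):
        s = dn.TargetScaler(t_min=0.5, t_max=20.0)
        assert s.unscale(s.scale(t)) == pytest.approx(t, rel=1e-12)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(dn.ConfigurationError):
            dn.TargetScaler(t_min=5.0, t_max=5.0)

    def test_fit_spans_data(self):
        s = dn.TargetScaler.fit([3.0, 7.0, 5.0])
        assert (s.t_min, s.t_max) == (3.0, 7.0)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients agree with central differences to 1e-6 relative."""
        for _ in range(20):
            model, X, y = random_model_and_batch(rng)
            _, analytic = loss_and_gradients(model, X, y)
            numeric = finite_difference_grads(model, X, y)
            for name in analytic:
                scale = max(np.abs(numeric[name]).max(), 1e-8)
                err = np.abs(analytic[name] - numeric[name]).max() / scale
                assert err < 1e-6, f"{name}: relative error {err}"


class TestTraining:
    def test_single_example_fits_below_tolerance(self):
        cfg = dn.TrainingConfig(seed=1)
        m = dn.init_network(3, cfg)
        m.target_scaler = dn.TargetScaler(t_min=1.0, t_max=10.0)
        X = np.array([[0.2], [-0.4], [0.6], [0.1]])
        _, trace = dn.train_backprop(m, X, [5.0], cfg)
        assert trace[-1] < cfg.loss_tolerance

    def test_empty_training_set_rejected(self):
        with pytest.raises(dn.ValidationError):
            dn.train_backprop(dn.init_network(3), np.zeros((4, 0)), [])

    def test_target_count_mismatch_rejected(self):
        with pytest.raises(dn.ValidationError):
            dn.train_backprop(dn.init_network(3), np.zeros((4, 3)), [1.0, 2.0])

    def test_teacher_student_recovery_noiseless(self, rng):
        """A student of the same class fits noiseless teacher targets."""
        teacher = dn.init_network(3, dn.TrainingConfig(seed=5, init_range=2.0))
        X = rng.uniform(-1, 1, size=(4, 50))
        A2, _ = _forward_batch(teacher, X)
        t = 1.0 + 10.0 * A2[0]  # map teacher output into a drift-time-like range
        cfg = dn.TrainingConfig(seed=6, max_epochs=20000)
        student = dn.init_network(3, cfg)
        student, trace = dn.train_backprop(student, X, t, cfg)
        assert trace[-1] < 1e-3
        # held-out points from the same teacher are predicted closely
        X_new = rng.uniform(-1, 1, size=(4, 30))
        t_new = 1.0 + 10.0 * _forward_batch(teacher, X_new)[0][0]
        pred = student.target_scaler.unscale(_forward_batch(student, X_new)[0][0])
        assert np.abs(pred - t_new) / t_new == pytest.approx(np.zeros(30), abs=0.05)

    def test_training_is_deterministic(self, rng):
        X = rng.uniform(-1, 1, size=(4, 20))
        t = rng.uniform(2, 12, size=20)
        cfg = dn.TrainingConfig(seed=3, max_epochs=500)
        runs = []
        for _ in range(2):
            m, _ = dn.train_backprop(dn.init_network(3, cfg), X, t, cfg)
            runs.append(m)
        for name in ("w_hidden", "b_hidden", "w_out", "b_out"):
            assert np.array_equal(getattr(runs[0], name), getattr(runs[1], name))

    def test_online_mode_also_converges_and_is_deterministic(self, rng):
        X = rng.uniform(-1, 1, size=(4, 15))
        t = rng.uniform(2, 12, size=15)
        cfg = dn.TrainingConfig(seed=4, max_epochs=300, online=True, learning_rate=0.1)
        m1, tr1 = dn.train_backprop(dn.init_network(3, cfg), X, t, cfg)
        m2, tr2 = dn.train_backprop(dn.init_network(3, cfg), X, t, cfg)
        assert tr1 == tr2
        assert tr1[-1] < tr1[0]
        assert np.array_equal(m1.w_hidden, m2.w_hidden)

    def test_loss_trace_non_increasing_and_learns_learnable_target(self, rng):
        X = rng.uniform(-1, 1, size=(4, 30))
        t = 7.0 + 3.0 * X[0] - 2.0 * X[2]  # a learnable affine slice
        cfg = dn.TrainingConfig(seed=8, max_epochs=2000)
        _, trace = dn.train_backprop(dn.init_network(3, cfg), X, t, cfg)
        assert all(b <= a for a, b in zip(trace, trace[1:]))  # rejected steps are undone
        assert trace[-1] < 0.1 * trace[0]


class TestPrediction:
    def _trained_model(self, dataset, charge, seed=17):
        peps = [p for p in dataset if p.charge == charge]
        M = dn.featurize_dataset(peps)
        params = dn.fit_normalization(M)
        t = np.array([p.drift_time_ms for p in peps])
        cfg = dn.TrainingConfig(seed=seed, max_epochs=2000)
        m = dn.init_network(3, cfg)
        m.feature_params = params
        m.target_scaler = dn.TargetScaler.fit(t)
        m.metadata["charge"] = charge
        m, _ = dn.train_backprop(m, dn.apply_normalization(M, params), t, cfg)
        return m, peps, t

    def test_predictions_bounded_by_scaler_range(self, small_dataset):
        m, peps, _ = self._trained_model(small_dataset, 2)
        pred = dn.predict_drift_time(m, peps)
        s = m.target_scaler
        slack = (s.t_max - s.t_min) * s.margin / (1 - 2 * s.margin)
        assert np.all(pred > s.t_min - slack - 1e-9)
        assert np.all(pred < s.t_max + slack + 1e-9)

    def test_charge_mismatch_warns(self, small_dataset):
        m, _, _ = self._trained_model(small_dataset, 2)
        other = [p for p in small_dataset if p.charge == 1][:3]
        with pytest.warns(UserWarning, match="charge"):
            dn.predict_drift_time(m, other)

    def test_serialization_round_trip_preserves_predictions_bitwise(self, small_dataset, tmp_path):
        m, peps, _ = self._trained_model(small_dataset, 2)
        before = dn.predict_drift_time(m, peps)
        path = tmp_path / "model.json"
        dn.save_model(m, path, seed=17)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # same charge: must not warn
            after = dn.predict_drift_time(dn.load_model(path), peps)
        assert np.array_equal(before, after)

    def test_untrained_model_without_scaling_rejected(self, small_dataset):
        with pytest.raises(dn.ConfigurationError):
            dn.predict_drift_time(dn.init_network(3), small_dataset[:2])
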