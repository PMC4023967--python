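"""Network core: normalization, forward/Jacobian, LM training, importance."""

import numpy as np
import pytest

from gaitbalance.errors import NormalizationError, TrainingError
from gaitbalance.network import (
    MinMaxNormalizer,
    NetworkConfig,
    NetworkModel,
    forward,
    init_weights,
    input_importance,
    jacobian,
    load_model,
    make_teacher,
    n_parameters,
    predict,
    save_model,
    train_lm,
)
from gaitbalance.network import _pack, _unpack


class TestNormalizer:
    def test_maps_extrema_to_unit_interval(self):
        norm = MinMaxNormalizer.fit(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(
            norm.apply(np.array([[0.0], [5.0], [10.0]])).ravel(), [-1.0, 0.0, 1.0]
        )

    def test_invert_apply_round_trip(self, rng):
        X = rng.normal(size=(40, 6)) * rng.uniform(0.5, 50, 6)
        norm = MinMaxNormalizer.fit(X)
        np.testing.assert_allclose(norm.invert(norm.apply(X)), X, rtol=1e-12)

    def test_constant_column_error_names_column(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(NormalizationError, match="bmi"):
            MinMaxNormalizer.fit(X, columns=["age", "bmi"])


class TestForwardAndJacobian:
    def test_zero_network_outputs_zero(self, rng):
        m = NetworkModel(W1=np.zeros((4, 3)), b1=np.zeros(4),
                         W2=np.zeros((2, 4)), b2=np.zeros(2))
        np.testing.assert_array_equal(forward(m, rng.normal(size=(7, 3))), 0.0)

    def test_parameter_count_formula(self):
        assert n_parameters(16, 20, 3) == 20 * 17 + 3 * 21
        m = init_weights(NetworkConfig(n_inputs=16, n_hidden=20), np.random.default_rng(0))
        assert _pack(m).size == n_parameters(16, 20, 3)

    def test_jacobian_matches_finite_differences(self, rng):
        cfg = NetworkConfig(n_inputs=4, n_hidden=6, n_outputs=3, seed=2)
        m = init_weights(cfg, np.random.default_rng(2))
        X = rng.normal(size=(5, 4))
        J = jacobian(m, X)
        p0 = _pack(m)
        eps = 1e-6
        for j in range(p0.size):
            for sign, store in ((+1, "hi"), (-1, "lo")):
                p = p0.copy()
                p[j] += sign * eps
                m.W1, m.b1, m.W2, m.b2 = _unpack(p, 4, 6, 3)
                if sign > 0:
                    hi = forward(m, X)
                else:
                    lo = forward(m, X)
            fd = ((hi - lo) / (2 * eps)).ravel()
            assert np.max(np.abs(fd - J[:, j])) < 1e-4
        m.W1, m.b1, m.W2, m.b2 = _unpack(p0, 4, 6, 3)

    def test_output_weight_columns_equal_hidden_activations(self, rng):
        """Chain rule: dy_o/dW2[o,h] is the hidden activation a_h."""
        cfg = NetworkConfig(n_inputs=3, n_hidden=4, n_outputs=2, seed=1)
        m = init_weights(cfg, np.random.default_rng(1))
        X = rng.normal(size=(6, 3))
        A = np.tanh(X @ m.W1.T + m.b1)
        J = jacobian(m, X)
        H, I, O = 4, 3, 2
        off = H * I + H
        block = J[:, off: off + O * H].reshape(6, O, O, H)
        for o in range(O):
            np.testing.assert_allclose(block[:, o, o, :], A, atol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        m = init_weights(NetworkConfig(n_inputs=4, n_hidden=3), np.random.default_rng(0))
        with pytest.raises(TrainingError, match="columns"):
            forward(m, rng.normal(size=(5, 7)))


class TestTrainLM:
    def test_linear_data_reaches_least_squares_optimum(self, rng):
        """On exactly linear data the net matches the normal-equations fit."""
        X = rng.normal(size=(60, 3))
        B = rng.normal(size=(3, 3))
        Y = X @ B + 0.5
        cfg = NetworkConfig(n_inputs=3, n_hidden=5, n_outputs=3,
                            error_goal=1e-10, max_epochs=500, seed=3)
        model, trace = train_lm(cfg, X, Y)
        Xn, Yn = model.x_norm.apply(X), model.y_norm.apply(Y)
        A = np.column_stack([Xn, np.ones(60)])
        beta, *_ = np.linalg.lstsq(A, Yn, rcond=None)
        ols_mse = float(np.mean((A @ beta - Yn) ** 2))
        assert trace.mse[-1] <= ols_mse + 1e-6

    def test_accepted_step_mse_is_monotone(self, study_cohort):
        X = study_cohort[["bbs", "tug", "abc"]].to_numpy(float)
        Y = study_cohort[["com_bos", "comv_bos", "bos_area"]].to_numpy(float)
        cfg = NetworkConfig(n_inputs=3, n_hidden=10, error_goal=1e-6,
                            max_epochs=60, seed=0)
        _, trace = train_lm(cfg, X, Y)
        assert all(b <= a for a, b in zip(trace.mse, trace.mse[1:]))
        assert trace.epochs_used <= 60

    def test_xor_is_learnable_for_most_seeds(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        Y = np.array([[0.0], [1], [1], [0]])
        reached = 0
        for seed in range(10):
            cfg = NetworkConfig(n_inputs=2, n_hidden=5, n_outputs=1,
                                error_goal=0.001, seed=seed)
            _, trace = train_lm(cfg, X, Y)
            reached += trace.stop_reason == "goal"
        assert reached >= 9

    def test_seed_determinism(self, study_cohort):
        X = study_cohort[["bbs", "tug", "abc"]].to_numpy(float)
        Y = study_cohort[["com_bos", "comv_bos", "bos_area"]].to_numpy(float)
        cfg = NetworkConfig(n_inputs=3, n_hidden=5, error_goal=0.01, seed=11)
        m1, t1 = train_lm(cfg, X, Y)
        m2, t2 = train_lm(cfg, X, Y)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        assert t1.mse == t2.mse

    def test_teacher_student_recovery(self):
        teacher = make_teacher(6, 8, 3, seed=7)
        X = np.random.default_rng(8).uniform(-1, 1, size=(200, 6))
        Y = forward(teacher, X)
        cfg = NetworkConfig(n_inputs=6, n_hidden=8, n_outputs=3,
                            error_goal=1e-8, max_epochs=300, seed=1)
        model, _ = train_lm(cfg, X[:150], Y[:150])
        pred = predict(model, X[150:])
        for o in range(3):
            assert np.corrcoef(pred[:, o], Y[150:, o])[0, 1] > 0.99

    def test_non_finite_data_rejected(self):
        cfg = NetworkConfig(n_inputs=2, n_hidden=3, n_outputs=1)
        with pytest.raises(TrainingError):
            train_lm(cfg, np.array([[1.0, np.nan]]), np.array([[1.0]]))


class TestPredictAndSerialization:
    def test_training_sample_consistency(self, study_cohort):
        X = study_cohort[["bbs", "tug", "abc"]].to_numpy(float)
        Y = study_cohort[["com_bos", "comv_bos", "bos_area"]].to_numpy(float)
        cfg = NetworkConfig(n_inputs=3, n_hidden=20, error_goal=0.001, seed=4)
        model, trace = train_lm(cfg, X, Y)
        resid_n = model.y_norm.apply(predict(model, X)) - model.y_norm.apply(Y)
        assert float(np.mean(resid_n**2)) <= max(trace.mse[-1] * 1.01, 0.001)

    def test_json_round_trip_is_bit_exact(self, tmp_path, study_cohort):
        X = study_cohort[["bbs", "tug", "abc"]].to_numpy(float)
        Y = study_cohort[["com_bos", "comv_bos", "bos_area"]].to_numpy(float)
        cfg = NetworkConfig(n_inputs=3, n_hidden=5, error_goal=0.01, seed=2)
        model, _ = train_lm(cfg, X, Y)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        for attr in ("W1", "b1", "W2", "b2"):
            np.testing.assert_array_equal(getattr(back, attr), getattr(model, attr))
        np.testing.assert_array_equal(back.x_norm.col_min, model.x_norm.col_min)
        np.testing.assert_array_equal(predict(back, X), predict(model, X))


class TestInputImportance:
    def test_single_active_input_ranked_first(self):
        W1 = np.zeros((6, 5))
        W1[:, 3] = 2.0
        m = NetworkModel(W1=W1, b1=np.zeros(6), W2=np.ones((3, 6)), b2=np.zeros(3))
        _, order = input_importance(m, input_names=list("abcde"))
        assert order[0] == "d"

    def test_ties_are_stable_by_index(self):
        m = NetworkModel(W1=np.ones((4, 3)), b1=np.zeros(4),
                         W2=np.ones((1, 4)), b2=np.zeros(1))
        scores, order = input_importance(m)
        assert np.ptp(scores) == 0.0
        assert order == [0, 1, 2]

    def test_informative_inputs_dominate_noise_inputs(self):
        """A student trained on a 3-relevant-of-16-input teacher ranks the
        informative inputs at the top for most seeds."""
        relevant = [2, 7, 11]
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.uniform(-1, 1, size=(400, 16))
            teacher = make_teacher(3, 6, 3, seed=seed, weight_scale=1.0)
            Y = forward(teacher, X[:, relevant])
            cfg = NetworkConfig(n_inputs=16, n_hidden=6, n_outputs=3,
                                error_goal=1e-4, max_epochs=150, seed=seed)
            model, _ = train_lm(cfg, X, Y)
            _, order = input_importance(model)
            hits += set(order[:3]) == set(relevant)
        assert hits >= 8
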