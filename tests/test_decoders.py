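"""Decoder correctness: Kalman recursion against hand computation,
least-squares model recovery, gradient training, and the cross-validation
audit."""

import numpy as np
import pytest

from neuroscribe import synthetic
from neuroscribe.decoders import (
    KalmanModel,
    LossSpec,
    LSTMDecoder,
    TrainConfig,
    WindowedLinearDecoder,
    crossval_loco,
    decode,
    fit_kalman,
    kalman_decode,
    loss_value_and_grad,
    pearson_cc,
    train_decoder,
)


def stable_system(rng, n_obs=5):
    A = np.array([[0.92, 0.05, 0.01], [-0.04, 0.9, 0.02], [0.0, 0.0, 1.0]])
    H = rng.normal(size=(n_obs, 3))
    return A, H


def rollout(A, H, x0, T):
    xs = [x0]
    for _ in range(T - 1):
        xs.append(A @ xs[-1])
    X = np.asarray(xs)
    return X, X @ H.T


class TestKalman:
    def test_one_step_update_matches_hand_recursion(self):
        # A=H=Q=R=P0=1, x0=0, z=2: P- = 2, K = 2/3, xhat = 4/3.
        m = KalmanModel(
            A=np.eye(1), H=np.eye(1), Q=np.eye(1), R=np.eye(1),
            x0=np.zeros(1), P0=np.eye(1), bias=False,
        )
        out = kalman_decode(m, np.array([[2.0]]))
        assert out.velocity[0, 0] == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_huge_R_follows_pure_prediction(self):
        m = KalmanModel(
            A=np.eye(1) * 0.5, H=np.eye(1), Q=np.eye(1) * 1e-6,
            R=np.eye(1) * 1e12, x0=np.ones(1), P0=np.eye(1), bias=False,
        )
        out = kalman_decode(m, np.full((4, 1), 100.0))
        assert out.velocity[:, 0] == pytest.approx(
            [0.5, 0.25, 0.125, 0.0625], rel=1e-3
        )

    def test_refit_recovers_generating_system(self, rng):
        A, H = stable_system(rng)
        trials_x, trials_z = [], []
        for _ in range(4):
            x0 = np.array([*rng.normal(size=2), 1.0])
            X, Z = rollout(A, H, x0, 60)
            trials_x.append(X[:, :2])
            trials_z.append(Z)
        model = fit_kalman(trials_x, trials_z)
        assert model.A == pytest.approx(A, abs=1e-6)
        assert model.H == pytest.approx(H, abs=1e-6)

    def test_white_noise_states_give_no_dynamics(self, rng):
        xs = [rng.normal(size=(500, 2)) for _ in range(3)]
        zs = [x @ rng.normal(size=(2, 4)) for x in xs]
        model = fit_kalman(xs, zs)
        assert np.abs(model.A[:2, :2]).max() < 0.15

    def test_covariances_positive_semidefinite(self, rng):
        xs = [rng.normal(size=(80, 2))]
        zs = [rng.normal(size=(80, 6))]
        model = fit_kalman(xs, zs)
        for M in (model.Q, model.R):
            assert np.allclose(M, M.T)
            assert np.linalg.eigvalsh(M).min() >= -1e-9

    def test_noiseless_system_decoded_exactly(self, rng):
        A, H = stable_system(rng, n_obs=6)
        x0 = np.array([1.0, -0.5, 1.0])
        X, Z = rollout(A, H, x0, 50)
        model = fit_kalman([X[:, :2]], [Z])
        model.x0 = x0
        model.P0 = np.eye(3) * 1e-6
        out = kalman_decode(model, Z)
        assert out.velocity == pytest.approx(X[:, :2], abs=1e-6)


class TestTraining:
    def test_single_trial_mse_loss_decreases(self, rng):
        X = rng.normal(size=(25, 4))
        Y = rng.normal(size=(25, 2))
        model = LSTMDecoder(4, hidden=16, seed=0)
        fit = train_decoder(
            [X], [Y], LossSpec("mse"),
            TrainConfig(epochs=200, seed=0, hidden_size=16, patience=200),
            model=model,
        )
        hist = fit.loss_history
        smoothed = np.convolve(hist, np.ones(10) / 10, mode="valid")
        assert smoothed[-1] < smoothed[0]
        assert np.all(np.diff(smoothed) < 1e-3)  # monotone after smoothing

    def test_recoverable_linear_map_reaches_high_cc(self, rng):
        W = rng.normal(size=(6, 2))
        feats, targs = [], []
        for _ in range(8):
            v = np.cumsum(rng.normal(size=(40, 2)), axis=0) / 5
            feats.append(v @ W.T + 0.01 * rng.normal(size=(40, 6)))
            targs.append(v)
        model = WindowedLinearDecoder(6, taps=0, seed=1)
        fit = train_decoder(
            feats, targs, LossSpec("mse"),
            TrainConfig(epochs=300, seed=1, patience=300), model=model,
        )
        ccs = [pearson_cc(fit.model.forward(f), t) for f, t in zip(feats, targs)]
        assert np.mean(ccs) >= 0.95

    def test_training_reproducible_given_seed(self, rng):
        X = [rng.normal(size=(20, 3))]
        Y = [rng.normal(size=(20, 2))]
        hists = []
        for _ in range(2):
            model = LSTMDecoder(3, hidden=8, seed=5)
            fit = train_decoder(
                X, Y, LossSpec("dilate"),
                TrainConfig(epochs=5, seed=5, hidden_size=8), model=model,
            )
            hists.append(fit.loss_history)
        assert np.array_equal(hists[0], hists[1])

    def test_nan_loss_aborts_with_diagnostic(self, rng):
        X = [rng.normal(size=(10, 3)) * 1e200]
        Y = [rng.normal(size=(10, 2))]
        model = LSTMDecoder(3, hidden=4, seed=0)
        model.params["Wo"] *= 1e200
        with pytest.raises(RuntimeError, match="non-finite"):
            train_decoder(X, Y, LossSpec("mse"),
                          TrainConfig(epochs=2, seed=0, hidden_size=4), model=model)

    def test_decode_is_deterministic_and_length_preserving(self, rng):
        model = LSTMDecoder(4, hidden=8, seed=2)
        X = rng.normal(size=(33, 4))
        a = decode(model, X)
        b = decode(model, X)
        assert np.array_equal(a.velocity, b.velocity)
        assert len(a) == 33
        assert a.position.shape == (33, 2)

    def test_zero_weight_model_outputs_constant(self):
        model = WindowedLinearDecoder(3, taps=1, seed=0)
        model.params["W"][:] = 0.0
        model.params["b"][:] = 1.5
        out = decode(model, np.random.default_rng(0).normal(size=(10, 3)))
        assert out.velocity == pytest.approx(np.full((10, 2), 1.5))


@pytest.fixture(scope="module")
def session30(corpus):
    # 30 characters x 3 repetitions -> 90 trials, train folds of 87.
    templates = corpus.templates + [
        synthetic.random_glyph(100 + k, 2, glyph_id=f"rand{k}") for k in range(4)
    ]
    big = synthetic.GlyphCorpus(templates=templates)
    spec = synthetic.SessionSpec(repetitions=3, n_channels=6, seed=8,
                                 misalignment=False, noise_sd=0.5)
    return synthetic.simulate_session(big, spec)


class TestCrossvalLoco:
    def _factory(self, n_in, seed):
        return WindowedLinearDecoder(n_in, taps=0, seed=seed)

    def test_fold_structure_87_train_samples(self, session30):
        res = crossval_loco(
            session30.trials, LossSpec("mse"),
            TrainConfig(epochs=1, seed=0), model_factory=self._factory,
        )
        assert len(res) == 30
        assert all(f.train_size == 87 for f in res)

    def test_no_leakage_of_held_out_character(self, session30):
        res = crossval_loco(
            session30.trials, LossSpec("mse"),
            TrainConfig(epochs=1, seed=0), model_factory=self._factory,
        )
        for fold in res:
            assert all(cid != fold.held_out for cid, _ in fold.train_ids)

    def test_fold_assignment_deterministic(self, session30):
        r1 = crossval_loco(session30.trials, LossSpec("mse"),
                           TrainConfig(epochs=1, seed=3), model_factory=self._factory)
        r2 = crossval_loco(session30.trials, LossSpec("mse"),
                           TrainConfig(epochs=1, seed=3), model_factory=self._factory)
        assert [f.held_out for f in r1] == [f.held_out for f in r2]
        for a, b in zip(r1, r2):
            assert a.metrics["cc"] == pytest.approx(b.metrics["cc"])


class TestLossInterface:
    def test_mse_matches_definition(self, rng):
        p, y = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        v, g = loss_value_and_grad(p, y, LossSpec("mse"))
        assert v == pytest.approx(np.mean((p - y) ** 2))
        assert g == pytest.approx(2 * (p - y) / p.size)

    def test_dilate_on_aligned_pair_smaller_than_on_shifted(self, rng):
        t = np.linspace(0, 2 * np.pi, 40)
        y = np.column_stack([np.sin(t), np.cos(t)])
        shifted = np.roll(y, 6, axis=0)
        spec = LossSpec("dilate")
        v_same, _ = loss_value_and_grad(y, y, spec)
        v_shift, _ = loss_value_and_grad(shifted, y, spec)
        assert v_same < v_shift
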