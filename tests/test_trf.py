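import numpy as np
import pytest

from envtrack import synthdata as sd
from envtrack import trf
from envtrack.envelope import MultibandEnvelope
from envtrack.preprocess import EEGEpochs
from envtrack.trf import (
    LagWindow,
    build_lagged_design,
    crossval_tracking,
    fit_ridge,
    fit_subject_trf,
    permutation_chance_level,
    predict_eeg,
)


def _env(features, fs=128.0):
    nb = features.shape[0]
    return MultibandEnvelope(
        features=features, fs=fs, band_centers=np.arange(1.0, nb + 1.0)
    )


class TestLagWindow:
    def test_default_lag_count(self):
        # round(-0.1*128) = -13 ... round(0.45*128) = 58 inclusive -> 72 lags
        w = LagWindow(-100.0, 450.0, 128.0)
        assert w.lags[0] == -13
        assert w.lags[-1] == 58
        assert w.n_lags == 72

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            LagWindow(100.0, -100.0, 128.0)


class TestBuildLaggedDesign:
    def test_single_lag_identity(self, rng):
        f = rng.standard_normal((1, 50))
        X = build_lagged_design(_env(f), LagWindow(0.0, 1.0, 128.0))
        # lag 0 column equals the feature itself
        np.testing.assert_allclose(X[:, 0], 1.0)
        np.testing.assert_allclose(X[:, 1], f[0])

    def test_column_count_16_bands(self, rng):
        f = rng.standard_normal((16, 300))
        X = build_lagged_design(_env(f), LagWindow(-100.0, 450.0, 128.0))
        assert X.shape == (300, 16 * 72 + 1)

    def test_shift_property(self, rng):
        f = rng.standard_normal((2, 80))
        w = LagWindow(-50.0, 100.0, 128.0)
        X = build_lagged_design(_env(f), w)
        fs_shift = np.zeros_like(f)
        fs_shift[:, 1:] = f[:, :-1]
        Xs = build_lagged_design(_env(fs_shift), w)
        # interior rows (outside the zero-padded lag edges) shift by +1
        hi, lo = w.lags[-1], -w.lags[0]
        np.testing.assert_allclose(
            Xs[hi + 1 : -lo - 1, 1:], X[hi : -lo - 2, 1:]
        )

    def test_zero_padding_at_edges(self, rng):
        f = rng.standard_normal((1, 30))
        w = LagWindow(0.0, 1000.0 * 5 / 128.0, 128.0)  # lags 0..5
        X = build_lagged_design(_env(f), w)
        assert np.all(X[0, 2:] == 0)  # lags >= 1 see no past at t=0

    def test_rate_mismatch(self, rng):
        with pytest.raises(ValueError):
            build_lagged_design(_env(rng.standard_normal((1, 10)), fs=64.0),
                                LagWindow(0.0, 10.0, 128.0))


def _ridge_oracle(X, Y, lam):
    """Independent normal-equations solve with explicit inversion."""
    ncols = X.shape[1]
    P = np.eye(ncols)
    P[0, 0] = 0.0
    m = np.trace(X.T @ X) / ncols
    return np.linalg.inv(X.T @ X + lam * m * P) @ (X.T @ Y)


class TestFitRidge:
    def test_exact_recovery_lambda_zero(self, rng):
        X = np.c_[np.ones(40), rng.standard_normal((40, 5))]
        w_true = rng.standard_normal((6, 2))
        Y = X @ w_true
        model = fit_ridge(X, Y, 0.0)
        np.testing.assert_allclose(
            np.r_[model.intercept[None, :], model.flat_weights()], w_true, rtol=1e-6
        )

    def test_monotone_shrinkage(self, rng):
        X = np.c_[np.ones(60), rng.standard_normal((60, 8))]
        Y = rng.standard_normal((60, 1))
        norms = [
            np.linalg.norm(fit_ridge(X, Y, lam).flat_weights())
            for lam in (0.0, 1.0, 10.0, 100.0, 1e4, 1e8)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_small_system_oracle(self, rng):
        X = np.c_[np.ones(5), rng.standard_normal((5, 1))]
        Y = rng.standard_normal((5, 1))
        for lam in (0.0, 1.0, 100.0):
            model = fit_ridge(X, Y, lam)
            W = np.r_[model.intercept[None, :], model.flat_weights()]
            np.testing.assert_allclose(W, _ridge_oracle(X, Y, lam), rtol=1e-8)

    def test_oracle_equivalence_random_systems(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 51))
            p = int(rng.integers(2, 11))
            X = np.c_[np.ones(n), rng.standard_normal((n, p - 1))]
            Y = rng.standard_normal((n, 3))
            for lam in (0.0, 1.0, 100.0):
                model = fit_ridge(X, Y, lam)
                W = np.r_[model.intercept[None, :], model.flat_weights()]
                oracle = _ridge_oracle(X, Y, lam)
                assert np.linalg.norm(W - oracle) / np.linalg.norm(oracle) < 1e-8

    def test_rank_deficient_advises_regularization(self):
        X = np.c_[np.ones(10), np.ones((10, 3))]  # collinear
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            fit_ridge(X, np.random.default_rng(0).standard_normal((10, 1)), 0.0)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ridge(np.ones((5, 2)), rng.standard_normal((5, 1)), -1.0)


class TestPredict:
    def test_zero_weights_predict_intercept(self, rng):
        w = LagWindow(0.0, 50.0, 128.0)
        env = _env(rng.standard_normal((2, 100)))
        model = trf.TRFModel(
            weights=np.zeros((w.n_lags, 2, 3)),
            intercept=np.array([1.0, -2.0, 0.5]),
            lam=0.0,
            lag_axis_ms=w.lags_ms,
        )
        pred = predict_eeg(model, env, w)
        np.testing.assert_allclose(pred, np.tile([1.0, -2.0, 0.5], (100, 1)))

    def test_training_correlation_one_noiseless(self, rng):
        w = LagWindow(0.0, 100.0, 128.0)
        env = _env(rng.standard_normal((2, 400)))
        X = build_lagged_design(env, w)
        w_true = rng.standard_normal((X.shape[1], 2))
        Y = X @ w_true
        model = fit_ridge(X, Y, 0.0, window=w, n_bands=2)
        pred = predict_eeg(model, env, w)
        for c in range(2):
            assert np.corrcoef(pred[:, c], Y[:, c])[0, 1] > 1 - 1e-9

    def test_linearity_in_features(self, rng):
        w = LagWindow(0.0, 50.0, 128.0)
        f = rng.standard_normal((2, 100))
        model = trf.TRFModel(
            weights=rng.standard_normal((w.n_lags, 2, 2)),
            intercept=np.array([0.3, -0.7]),
            lam=0.0,
            lag_axis_ms=w.lags_ms,
        )
        p1 = predict_eeg(model, _env(f), w) - model.intercept
        p2 = predict_eeg(model, _env(2.0 * f), w) - model.intercept
        np.testing.assert_allclose(p2, 2.0 * p1, atol=1e-10)

    def test_band_mismatch(self, rng):
        w = LagWindow(0.0, 50.0, 128.0)
        model = trf.TRFModel(
            weights=rng.standard_normal((w.n_lags, 3, 2)),
            intercept=np.zeros(2),
            lam=0.0,
            lag_axis_ms=w.lags_ms,
        )
        with pytest.raises(ValueError):
            predict_eeg(model, _env(rng.standard_normal((2, 100))), w)


def _noise_tracks(rng, gram, n_channels):
    return [rng.standard_normal((n, n_channels)) for n in gram.nsamp]


class TestCrossvalTracking:
    def test_high_snr_recovers(self, small_config, small_window, small_envs, small_gram):
        stimuli, envs = small_envs
        cfg = sd.SimulationConfig(**{**small_config.__dict__, "snr_db": 60.0})
        rng = np.random.default_rng(5)
        kern = sd.default_kernel(small_window, cfg.n_bands, cfg.n_channels, seed=rng)
        ep = sd.simulate_subject_eeg([], kern, cfg, seed=rng, envelopes=envs,
                                     window=small_window)
        res = crossval_tracking(envs, ep, small_window, [1e-4], gram=small_gram)
        assert res.r_mean > 0.9

    def test_white_noise_centered_at_zero(self, small_gram, small_window, rng):
        Y = _noise_tracks(rng, small_gram, 4)
        res = crossval_tracking(None, Y, small_window, [100.0], gram=small_gram)
        n_total = sum(small_gram.nsamp) * 4
        assert abs(res.r_mean) < 2.0 / np.sqrt(n_total) * 10

    def test_pairing_invariance(self, small_gram, small_window, small_envs, rng):
        _, envs = small_envs
        Y = _noise_tracks(rng, small_gram, 3)
        res1 = crossval_tracking(envs, Y, small_window, [10.0])
        perm = [2, 0, 3, 1]
        res2 = crossval_tracking([envs[i] for i in perm],
                                 [Y[i] for i in perm], small_window, [10.0])
        np.testing.assert_allclose(
            sorted(res1.r_per_track_channel.ravel()),
            sorted(res2.r_per_track_channel.ravel()),
            atol=1e-10,
        )
        assert np.isclose(res1.r_mean, res2.r_mean)

    def test_too_few_tracks(self, small_window, rng):
        f = [rng.standard_normal((2, 100)) for _ in range(2)]
        envs = [_env(x) for x in f]
        Y = [rng.standard_normal((100, 2)) for _ in range(2)]
        with pytest.raises(ValueError, match="3 tracks"):
            crossval_tracking(envs, Y, small_window, [1.0])

    def test_lambda_selection_reported(self, small_gram, small_window, rng):
        Y = _noise_tracks(rng, small_gram, 2)
        grid = [1.0, 100.0, 1e4]
        res = crossval_tracking(None, Y, small_window, grid, gram=small_gram)
        assert res.lambda_selected in grid
        assert len(res.grid_scores) == 3
        assert res.r_mean == res.grid_scores.max()


class TestPermutationChanceLevel:
    def test_determinism(self, small_gram, small_window, rng):
        Y = _noise_tracks(rng, small_gram, 2)
        a = permutation_chance_level(None, Y, small_window, 10.0, 150, seed=42,
                                     gram=small_gram)
        b = permutation_chance_level(None, Y, small_window, 10.0, 150, seed=42,
                                     gram=small_gram)
        assert a == b

    def test_high_snr_exceeds_chance(self, small_config, small_window, small_envs, small_gram):
        stimuli, envs = small_envs
        cfg = sd.SimulationConfig(**{**small_config.__dict__, "snr_db": 20.0})
        rng = np.random.default_rng(11)
        kern = sd.default_kernel(small_window, cfg.n_bands, cfg.n_channels, seed=rng)
        ep = sd.simulate_subject_eeg([], kern, cfg, seed=rng, envelopes=envs,
                                     window=small_window)
        res = crossval_tracking(envs, ep, small_window, [1.0], gram=small_gram)
        chance = permutation_chance_level(envs, ep, small_window, 1.0, 150,
                                          seed=1, gram=small_gram)
        assert res.r_mean > chance

    def test_n_perm_minimum(self, small_gram, small_window, rng):
        Y = _noise_tracks(rng, small_gram, 2)
        with pytest.raises(ValueError):
            permutation_chance_level(None, Y, small_window, 1.0, 50, gram=small_gram)

    def test_derangements_have_no_fixed_points(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = trf._sample_derangement(rng, 5)
            assert not np.any(p == np.arange(5))


class TestParameterRecovery:
    def test_nrmse_decreases_with_snr(self, small_config, small_window, small_envs, small_gram):
        _, envs = small_envs
        errs = []
        for snr in (-10.0, 10.0, 60.0):
            vals = []
            for seed in range(3):
                cfg = sd.SimulationConfig(**{**small_config.__dict__, "snr_db": snr})
                rng = np.random.default_rng(100 + seed)
                kern = sd.default_kernel(small_window, cfg.n_bands, cfg.n_channels,
                                         seed=rng)
                ep = sd.simulate_subject_eeg([], kern, cfg, seed=rng, envelopes=envs,
                                             window=small_window)
                model = fit_subject_trf(envs, ep, small_window, 1e-6, gram=small_gram)
                vals.append(
                    np.linalg.norm(model.weights - kern.weights)
                    / np.linalg.norm(kern.weights)
                )
            errs.append(np.mean(vals))
        assert errs[0] > errs[1] > errs[2]
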