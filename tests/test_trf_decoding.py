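import warnings
from dataclasses import dataclass, field

import numpy as np
import pytest

from actisense._utils import apply_lag_kernel
from actisense.dataset import EEGTrace
from actisense.trf_decoding import (LagSpec, build_lagged_design, fit_ridge,
                                    predict_velocity, score_single_trials,
                                    score_train_test, select_lambda_cv,
                                    to_forward_model, train_decoder)


@dataclass
class FakeTrial:
    eeg: EEGTrace
    velocity: np.ndarray
    trial: int = 0


def _coupled_trials(n_trials, n_samples, n_ch, snr, fs, seed, lags=None,
                    pattern=None):
    """Trials where EEG is a lagged mixture of a smoothed-noise velocity."""
    rng = np.random.default_rng(seed)
    if lags is None:
        lags = np.arange(-2, 6)
    if pattern is None:
        spatial = rng.standard_normal(n_ch)
        temporal = np.exp(-0.5 * ((np.arange(lags.size) - 3) / 1.5) ** 2)
        pattern = np.outer(spatial, temporal)
    labels = [f"ch{i}" for i in range(n_ch)]
    trials = []
    for k in range(n_trials):
        v = np.convolve(rng.standard_normal(n_samples), np.ones(3) / 3, "same")
        sig = apply_lag_kernel(v, pattern, lags)
        if snr == 0:
            data = rng.standard_normal(sig.shape)
        else:
            noise_sd = np.sqrt(np.maximum(sig.var(axis=0), 1e-12) / snr)
            data = sig + rng.standard_normal(sig.shape) * noise_sd
        trials.append(FakeTrial(eeg=EEGTrace(data=data, fs=fs, labels=labels),
                                velocity=v, trial=k))
    return trials, pattern, lags


class TestLaggedDesign:
    def test_single_channel_zero_lag_column_is_identity(self, rng):
        data = rng.standard_normal((50, 1))
        eeg = EEGTrace(data=data, fs=100.0, labels=["Cz"])
        spec = LagSpec(fs=100.0, lag_min_ms=-10.0, lag_max_ms=0.0)  # lags {-1, 0}
        X = build_lagged_design(eeg, spec)
        assert X.shape == (50, 2)
        assert np.array_equal(X[:, 1], data[:, 0])  # lag-0 column = EEG itself

    def test_column_count(self, rng):
        eeg = EEGTrace(data=rng.standard_normal((40, 2)), fs=100.0,
                       labels=["a", "b"])
        spec = LagSpec(fs=100.0, lag_min_ms=0.0, lag_max_ms=20.0)  # 3 lags
        assert build_lagged_design(eeg, spec).shape == (40, 6)

    def test_positive_lag_shifts_forward(self):
        # delta function input: lag +10 ms at 100 Hz = exactly 1 sample
        data = np.zeros((30, 1))
        data[10, 0] = 1.0
        eeg = EEGTrace(data=data, fs=100.0, labels=["x"])
        spec = LagSpec(fs=100.0, lag_min_ms=0.0, lag_max_ms=10.0)
        X = build_lagged_design(eeg, spec)
        # column for lag +1: X[t] = m[t+1] -> delta appears at t = 9
        assert X[9, 1] == 1.0 and X[10, 1] == 0.0
        assert X[10, 0] == 1.0  # lag 0 column unchanged

    def test_trial_shorter_than_lag_span_errors(self, rng):
        eeg = EEGTrace(data=rng.standard_normal((5, 1)), fs=100.0, labels=["x"])
        spec = LagSpec(fs=100.0, lag_min_ms=-200.0, lag_max_ms=400.0)
        with pytest.raises(ValueError, match="shorter"):
            build_lagged_design(eeg, spec)


class TestRidge:
    def test_matches_normal_equation_oracle_on_random_instances(self):
        # independent oracle: ordinary least squares with an intercept column
        # solved by explicit normal equations
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(10, 51))
            p = int(rng.integers(1, 9))
            X = rng.standard_normal((n, p)) * rng.uniform(0.5, 3.0, p)
            y = rng.standard_normal(n)
            w, b = fit_ridge(X, y, lam=0.0)
            A = np.column_stack([np.ones(n), X])
            coef = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.max(np.abs(w - coef[1:])) < 1e-8
            assert abs(b - coef[0]) < 1e-8

    def test_huge_lambda_shrinks_to_zero(self, rng):
        X = rng.standard_normal((100, 5))
        y = rng.standard_normal(100)
        w, _ = fit_ridge(X, y, lam=1e9)
        assert np.max(np.abs(w)) < 1e-5

    def test_perfect_fit_at_lambda_zero(self, rng):
        X = rng.standard_normal((60, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 4.0
        w, b = fit_ridge(X, y, lam=0.0)
        pred = X @ w + b
        assert np.corrcoef(pred, y)[0, 1] ** 2 == pytest.approx(1.0)

    def test_collinear_at_lambda_zero_raises(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x])
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            fit_ridge(X, x + rng.standard_normal(50), lam=0.0)


class TestLambdaSelection:
    def test_null_data_flat_warning(self):
        trials, _, _ = _coupled_trials(6, 80, 2, snr=0.0, fs=100.0, seed=3)
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=50.0)
        with pytest.warns(UserWarning, match="flat"):
            lam, curve = select_lambda_cv(trials, spec,
                                          grid=[1.0, 4.0, 16.0], seed=1)
        assert lam in curve

    def test_duplicated_trial_gives_identical_fold_scores(self):
        trials, _, _ = _coupled_trials(1, 100, 2, snr=2.0, fs=100.0, seed=4)
        clones = [FakeTrial(eeg=trials[0].eeg, velocity=trials[0].velocity,
                            trial=k) for k in range(5)]
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=50.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, curve = select_lambda_cv(clones, spec, grid=[4.0], seed=2)
        assert np.isfinite(curve[4.0])

    def test_empty_grid_errors(self):
        trials, _, _ = _coupled_trials(5, 60, 1, snr=1.0, fs=100.0, seed=5)
        spec = LagSpec(fs=100.0, lag_min_ms=0.0, lag_max_ms=30.0)
        with pytest.raises(ValueError):
            select_lambda_cv(trials, spec, grid=[])

    def test_flat_curve_on_coupled_data(self):
        trials, _, _ = _coupled_trials(10, 200, 3, snr=4.0, fs=100.0, seed=6)
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        _, curve = select_lambda_cv(trials, spec, grid=[1.0, 2.0, 4.0, 8.0, 16.0],
                                    seed=3)
        vals = np.array(list(curve.values()))
        assert vals.max() - vals.min() < 0.05 * vals.max()


class TestScoring:
    def test_noiseless_coupling_gives_r2_near_one(self):
        # noiseless single-lag copies are exactly invertible; long trials so
        # zero-padded edges are a negligible fraction
        lags = np.arange(-2, 6)
        pattern = np.zeros((3, lags.size))
        pattern[:, 3] = [1.0, -0.5, 2.0]  # every channel a lagged copy
        trials, _, _ = _coupled_trials(10, 600, 3, snr=1e9, fs=100.0, seed=7,
                                       lags=lags, pattern=pattern)
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        score = score_single_trials(trials, spec, lam=1e-6, seed=0)
        assert np.nanmin(score.r2) > 0.97

    def test_independent_eeg_scores_low(self):
        trials, _, _ = _coupled_trials(10, 150, 3, snr=0.0, fs=100.0, seed=8)
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        score = score_single_trials(trials, spec, lam=4.0, seed=0)
        assert np.nanmean(score.r2) < 0.2

    def test_scale_invariance(self):
        trials, _, _ = _coupled_trials(8, 120, 2, snr=2.0, fs=100.0, seed=9)
        scaled = [FakeTrial(eeg=EEGTrace(data=2.0 * t.eeg.data, fs=100.0,
                                         labels=t.eeg.labels),
                            velocity=t.velocity, trial=t.trial)
                  for t in trials]
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        a = score_single_trials(trials, spec, lam=4.0, seed=0)
        b = score_single_trials(scaled, spec, lam=4.0, seed=0)
        assert np.allclose(a.r2, b.r2, atol=1e-6)

    def test_r2_bounded(self):
        trials, _, _ = _coupled_trials(8, 120, 2, snr=1.0, fs=100.0, seed=10)
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        score = score_single_trials(trials, spec, lam=4.0, seed=0)
        ok = score.r2[~np.isnan(score.r2)]
        assert np.all((ok >= 0) & (ok <= 1))

    def test_fold_permutation_preserves_distribution(self):
        trials, _, _ = _coupled_trials(15, 150, 3, snr=2.0, fs=100.0, seed=11)
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        a = score_single_trials(trials, spec, lam=4.0, seed=0)
        b = score_single_trials(trials, spec, lam=4.0, seed=99)
        assert not np.allclose(a.r2, b.r2)  # folds differ
        assert abs(np.nanmean(a.r2) - np.nanmean(b.r2)) < 0.1

    def test_snr_monotonicity_two_points(self):
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        means = []
        for snr in (0.25, 4.0):
            trials, _, _ = _coupled_trials(10, 150, 3, snr=snr, fs=100.0,
                                           seed=12)
            score = score_single_trials(trials, spec, lam=4.0, seed=0)
            means.append(np.nanmean(score.r2))
        assert means[1] > means[0]

    def test_train_test_split_scores(self):
        trials, _, _ = _coupled_trials(10, 150, 2, snr=4.0, fs=100.0, seed=13)
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        model, test_idx, scores = score_train_test(trials, spec, lam=4.0, seed=0)
        assert len(test_idx) == 2 and len(scores) == 2
        assert np.nanmean(scores) > 0.4


class TestForwardModel:
    def test_single_source_recovers_spatial_pattern(self):
        # instantaneous rank-one mixing: recovered pattern at lag 0 ~ a
        rng = np.random.default_rng(14)
        a = rng.standard_normal(5)
        labels = [f"c{i}" for i in range(5)]
        trials = []
        for k in range(6):
            v = np.convolve(rng.standard_normal(200), np.ones(3) / 3, "same")
            data = np.outer(v, a)
            trials.append(FakeTrial(eeg=EEGTrace(data=data, fs=100.0,
                                                 labels=labels),
                                    velocity=v, trial=k))
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=20.0)
        dec = train_decoder(trials, spec, lam=1.0)
        fwd = to_forward_model(dec, trials)
        lag0 = list(spec.lags).index(0)
        pat = fwd.f[:, lag0]
        cos = abs(pat @ a) / (np.linalg.norm(pat) * np.linalg.norm(a))
        assert cos > 0.99

    def test_whitened_data_forward_proportional_to_weights(self, rng):
        # uncorrelated standardized design: f ~ g up to scale
        n, n_ch = 6000, 4
        labels = [f"c{i}" for i in range(n_ch)]
        data = rng.standard_normal((n, n_ch))
        w_true = np.array([1.0, -0.5, 0.25, 2.0])
        v = data @ w_true + 0.1 * rng.standard_normal(n)
        # lags {-1, 0}: white data keeps the Gram ~identity across lags too
        trial = FakeTrial(eeg=EEGTrace(data=data, fs=100.0, labels=labels),
                          velocity=v)
        spec = LagSpec(fs=100.0, lag_min_ms=-10.0, lag_max_ms=0.0)
        dec = train_decoder([trial], spec, lam=1e-6)
        fwd = to_forward_model(dec, [trial])
        g = dec.weights_flat
        f = fwd.f.reshape(-1)
        cos = (f @ g) / (np.linalg.norm(f) * np.linalg.norm(g))
        assert cos > 0.99

    def test_scale_invariance_up_to_convention(self):
        trials, _, _ = _coupled_trials(6, 150, 3, snr=4.0, fs=100.0, seed=15)
        scaled = [FakeTrial(eeg=EEGTrace(data=3.0 * t.eeg.data, fs=100.0,
                                         labels=t.eeg.labels),
                            velocity=t.velocity, trial=t.trial)
                  for t in trials]
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        f1 = to_forward_model(train_decoder(trials, spec, 4.0), trials).f
        f2 = to_forward_model(train_decoder(scaled, spec, 4.0), scaled).f
        c = np.corrcoef(f1.reshape(-1), f2.reshape(-1))[0, 1]
        assert abs(c) > 0.999

    def test_zero_variance_reconstruction_errors(self, rng):
        labels = ["a"]
        trial = FakeTrial(eeg=EEGTrace(data=rng.standard_normal((100, 1)),
                                       fs=100.0, labels=labels),
                          velocity=rng.standard_normal(100))
        spec = LagSpec(fs=100.0, lag_min_ms=0.0, lag_max_ms=10.0)
        dec = train_decoder([trial], spec, lam=4.0)
        dec.g[:] = 0.0
        with pytest.raises(ValueError, match="zero variance"):
            to_forward_model(dec, [trial])

    def test_prediction_roundtrip(self):
        lags = np.arange(-2, 6)
        pattern = np.zeros((2, lags.size))
        pattern[:, 2] = [1.0, 0.7]
        trials, _, _ = _coupled_trials(5, 600, 2, snr=1e6, fs=100.0, seed=16,
                                       lags=lags, pattern=pattern)
        spec = LagSpec(fs=100.0, lag_min_ms=-20.0, lag_max_ms=60.0)
        dec = train_decoder(trials, spec, lam=1e-3)
        pred = predict_velocity(dec, trials[0].eeg)
        assert np.corrcoef(pred, trials[0].velocity)[0, 1] ** 2 > 0.97
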