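"""Linear-Gaussian SSM: Kalman smoother oracle, EM behavior, demixing."""

import numpy as np
import pytest
import scipy.linalg as sla
from scipy.signal import resample_poly
from scipy.stats import multivariate_normal

import bedvitals as bv
from bedvitals import separation as sep
from bedvitals.core import bandpass


def _sim_ssm(params: sep.SSMParams, T, rng):
    k = params.transition.shape[0]
    d = params.mixing.shape[0]
    x = np.zeros((T, k))
    y = np.zeros((T, d))
    x[0] = rng.multivariate_normal(params.init_mean, params.init_cov)
    for t in range(T):
        if t > 0:
            x[t] = params.transition @ x[t - 1] + rng.multivariate_normal(
                np.zeros(k), params.process_cov)
        y[t] = params.mixing @ x[t] + rng.normal(0, np.sqrt(params.obs_cov))
    return x, y


def _dense_posterior(params: sep.SSMParams, y):
    """Brute-force batch oracle: condition the joint Gaussian directly."""
    T, d = y.shape
    k = params.transition.shape[0]
    A, H = params.transition, params.mixing
    Pm = [params.init_cov]
    for _ in range(1, T):
        Pm.append(A @ Pm[-1] @ A.T + params.process_cov)
    Sig = np.zeros((T * k, T * k))
    for t in range(T):
        for s in range(T):
            if t >= s:
                M = np.linalg.matrix_power(A, t - s) @ Pm[s]
            else:
                M = (np.linalg.matrix_power(A, s - t) @ Pm[t]).T
            Sig[t * k:(t + 1) * k, s * k:(s + 1) * k] = M
    Hb = np.kron(np.eye(T), H)
    S = Hb @ Sig @ Hb.T + np.kron(np.eye(T), np.diag(params.obs_cov))
    K = Sig @ Hb.T @ np.linalg.inv(S)
    mean = (K @ y.reshape(-1)).reshape(T, k)
    return mean, S


def _toy_params(rng):
    A = 0.95 * np.array([[np.cos(0.3), np.sin(0.3)],
                         [-np.sin(0.3), np.cos(0.3)]])
    H = rng.normal(size=(3, 2))
    return sep.SSMParams(A, H, 0.1 * np.eye(2), np.array([0.2, 0.3, 0.25]),
                         np.zeros(2), np.eye(2))


class TestKalmanSmoother:
    def test_identity_model_zero_noise_passthrough(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(50, 2))
        params = sep.SSMParams(np.zeros((2, 2)), np.eye(2), np.eye(2),
                               np.full(2, 1e-12), np.zeros(2), np.eye(2))
        xs, Ps, _ = sep.kalman_smooth(y, params)
        np.testing.assert_allclose(xs, y, atol=1e-4)

    @pytest.mark.parametrize("T", [20, 50])
    def test_matches_dense_joint_gaussian(self, T):
        rng = np.random.default_rng(1)
        params = _toy_params(rng)
        _, y = _sim_ssm(params, T, rng)
        xs, _, ll = sep.kalman_smooth(y, params)
        dense_mean, S = _dense_posterior(params, y)
        assert np.abs(xs - dense_mean).max() < 1e-8

    def test_loglik_matches_analytic_gaussian(self):
        rng = np.random.default_rng(2)
        params = _toy_params(rng)
        _, y = _sim_ssm(params, 20, rng)
        _, _, ll = sep.kalman_smooth(y, params)
        _, S = _dense_posterior(params, y)
        ll_oracle = multivariate_normal(np.zeros(S.shape[0]), S).logpdf(
            y.reshape(-1))
        assert ll == pytest.approx(ll_oracle, abs=1e-8)

    def test_white_noise_model_closed_form(self):
        # pure observation noise: loglik is the iid Gaussian log-density sum
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1.0, size=(200, 2))
        params = sep.SSMParams(np.zeros((2, 2)), 1e-9 * np.eye(2),
                               1e-18 * np.eye(2), np.array([1.0, 1.0]),
                               np.zeros(2), 1e-12 * np.eye(2))
        _, _, ll = sep.kalman_smooth(y, params)
        closed = -0.5 * (y.size * np.log(2 * np.pi) + np.sum(y ** 2))
        assert ll == pytest.approx(closed, rel=1e-6)

    def test_missing_rows_skipped(self):
        rng = np.random.default_rng(4)
        params = _toy_params(rng)
        _, y = _sim_ssm(params, 60, rng)
        y_gap = y.copy()
        y_gap[20:25] = np.nan
        xs, Ps, ll = sep.kalman_smooth(y_gap, params)
        assert np.isfinite(xs).all() and np.isfinite(ll)
        # posterior variance grows inside the gap
        assert Ps[22, 0, 0] > Ps[10, 0, 0]

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            sep.SSMParams(np.eye(2) * 0.5, np.eye(2),
                          np.array([[1.0, 2.0], [2.0, 1.0]]),
                          np.ones(2), np.zeros(2), np.eye(2))


class TestEM:
    def test_loglik_monotone_on_seeded_runs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            A = np.zeros((4, 4))
            for i, f in enumerate((0.2, 0.3)):
                A[2 * i:2 * i + 2, 2 * i:2 * i + 2] = sep._rotation(
                    2 * np.pi * f / 8.0, rho=0.99)
            true = sep.SSMParams(A, rng.normal(size=(4, 4)), 0.05 * np.eye(4),
                                 0.1 * np.ones(4), np.zeros(4), np.eye(4))
            _, y = _sim_ssm(true, 600, rng)
            params, trace = sep.fit_em(y, 8.0, seed=seed, max_iter=30,
                                       n_restarts=1, return_trace=True)
            diffs = np.diff(trace)
            assert np.all(diffs > -1e-8 * np.maximum(1.0, np.abs(trace[1:])))

    def test_final_loglik_at_least_truth(self):
        rng = np.random.default_rng(7)
        A = np.zeros((4, 4))
        for i, f in enumerate((0.2, 0.3)):
            A[2 * i:2 * i + 2, 2 * i:2 * i + 2] = sep._rotation(
                2 * np.pi * f / 8.0, rho=0.995)
        true = sep.SSMParams(A, rng.normal(size=(4, 4)), 0.02 * np.eye(4),
                             0.01 * np.ones(4), np.zeros(4), np.eye(4))
        _, y = _sim_ssm(true, 2400, rng)
        params, trace = sep.fit_em(y, 8.0, seed=0, max_iter=100,
                                   n_restarts=1, return_trace=True)
        _, _, ll_truth = sep.kalman_smooth(y, true)
        assert trace[-1] >= ll_truth - 1e-3 * y.shape[0]

    def test_mixing_recovery_subspace_angle(self):
        rng = np.random.default_rng(1)
        A = np.zeros((4, 4))
        for i, f in enumerate((0.2, 0.3)):
            A[2 * i:2 * i + 2, 2 * i:2 * i + 2] = sep._rotation(
                2 * np.pi * f / 8.0, rho=0.995)
        Htrue = np.array([[0.8, 0, 0.1, 0], [0.5, 0, 0.3, 0],
                          [0.2, 0, 0.6, 0], [0.1, 0, 0.9, 0]])
        true = sep.SSMParams(A, Htrue, 0.02 * np.eye(4), 0.01 * np.ones(4),
                             np.zeros(4), np.eye(4))
        _, y = _sim_ssm(true, 4800, rng)
        params = sep.fit_em(y, 8.0, seed=0, max_iter=150, n_restarts=1)
        for s in (0, 1):
            ang = min(
                np.rad2deg(sla.subspace_angles(
                    params.mixing[:, [2 * s]], Htrue[:, [c]]))[0]
                for c in (0, 2))
            assert ang < 5.0

    def test_duplicated_channels_get_equal_mixing(self):
        rng = np.random.default_rng(5)
        params0 = _toy_params(rng)
        _, y = _sim_ssm(params0, 600, rng)
        y_dup = np.column_stack([y[:, 0], y[:, 0], y[:, 1], y[:, 2]])
        fit = sep.fit_em(y_dup, 8.0, n_sources=1, seed=0, max_iter=40,
                         n_restarts=1)
        np.testing.assert_allclose(fit.mixing[0], fit.mixing[1], atol=1e-5)

    def test_single_source_data_second_source_small(self, quiet_night):
        frame, truth = quiet_night
        obs = bandpass(frame.channels, frame.fs, 0.167, 1.5)
        res = sep.demix(obs, frame.fs, seed=0, max_iter=60, n_restarts=1)
        dim = res.params.state_dim_per_source
        var = []
        for s in (0, 1):
            sl = slice(s * dim, (s + 1) * dim)
            xs, _, _ = sep.kalman_smooth(
                resample_poly(obs, 1, 10, axis=0), res.params)
            contrib = xs[:, sl] @ res.params.mixing[:, sl].T
            var.append(contrib.var())
        assert min(var) / sum(var) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sep.fit_em(np.zeros((100, 4)), 8.0)


class TestDemix:
    def _two_sleeper_obs(self, seed):
        p1 = bv.PersonSpec(weight=160, resp_rate=12,
                           projection=(0.4, 0.3, 0.2, 0.1), label="P1")
        p2 = bv.PersonSpec(weight=125, resp_rate=17,
                           projection=(0.1, 0.2, 0.3, 0.4), label="P2")
        frame, truth = bv.simulate_session([p1, p2], noise_sd=0.02,
                                           duration_s=600.0, seed=seed)
        obs = bandpass(frame.channels * truth.calibration.channel_gains,
                       frame.fs, 0.167, 1.5)
        return obs, truth, frame.fs

    @staticmethod
    def _corr_matrix(res, truth, fs):
        corr = np.zeros((2, 2))
        for i in range(2):
            for j, lbl in enumerate(["P1", "P2"]):
                tb = bandpass(truth.resp_sources[lbl], fs, 0.167, 1.5)
                tb = resample_poly(tb, 1, int(round(fs / res.fs)))
                n = min(len(res.sources[i]), len(tb))
                corr[i, j] = abs(np.corrcoef(res.sources[i][:n], tb[:n])[0, 1])
        return corr

    def test_source_recovery_12_17_bpm(self):
        obs, truth, fs = self._two_sleeper_obs(0)
        res = sep.demix(obs, fs, seed=0, max_iter=100, n_restarts=1)
        corr = self._corr_matrix(res, truth, fs)
        best = max(min(corr[0, 0], corr[1, 1]), min(corr[0, 1], corr[1, 0]))
        assert best >= 0.9
        assert np.all(np.diff(res.loglik_trace)
                      > -1e-8 * np.abs(res.loglik_trace[1:]))

    def test_peak_timing_correct_below_wrong(self):
        obs, truth, fs = self._two_sleeper_obs(1)
        res = sep.demix(obs, fs, seed=1, max_iter=100, n_restarts=1)
        corr = self._corr_matrix(res, truth, fs)
        assign = ["P1", "P2"] if corr[0, 0] > corr[0, 1] else ["P2", "P1"]
        for i, own in enumerate(assign):
            other = "P2" if own == "P1" else "P1"
            e_own, *_ = sep.peak_timing_error(res.sources[i], res.fs,
                                              truth.breath_peaks[own])
            e_other, *_ = sep.peak_timing_error(res.sources[i], res.fs,
                                                truth.breath_peaks[other])
            assert e_own < e_other

    def test_identical_inphase_sources_warn(self):
        p = dict(weight=150, resp_rate=15, projection=(0.25, 0.25, 0.25, 0.25))
        p1 = bv.PersonSpec(label="P1", **p)
        p2 = bv.PersonSpec(label="P2", **p)
        frame, truth = bv.simulate_session([p1, p2], noise_sd=0.02,
                                           duration_s=300.0, seed=2)
        obs = bandpass(frame.channels, frame.fs, 0.167, 1.5)
        with pytest.warns(RuntimeWarning, match="identifiable"):
            sep.demix(obs, frame.fs, seed=0, max_iter=30, n_restarts=1)

    def test_channel_reordering_gauge_invariance(self):
        obs, truth, fs = self._two_sleeper_obs(3)
        res_a = sep.demix(obs, fs, seed=3, max_iter=60, n_restarts=1)
        res_b = sep.demix(obs[:, ::-1], fs, seed=3, max_iter=60, n_restarts=1)
        # sources agree up to permutation and sign
        c = np.abs(np.corrcoef(np.vstack([res_a.sources,
                                          res_b.sources]))[:2, 2:])
        best = max(min(c[0, 0], c[1, 1]), min(c[0, 1], c[1, 0]))
        assert best > 0.95


class TestPeakTiming:
    def test_identical_signals_zero_error(self):
        t = np.arange(0, 300, 1 / 8.0)
        x = np.sin(2 * np.pi * 0.25 * t)
        ref = 1.0 + np.arange(74) * 4.0
        m, sd, nm, nu = sep.peak_timing_error(x, 8.0, ref)
        assert m < 0.13  # one sample at 8 Hz
        assert nu == 0

    def test_pure_shift_measured(self):
        t = np.arange(0, 300, 1 / 8.0)
        x = np.sin(2 * np.pi * 0.25 * (t - 0.25))
        ref = 1.0 + np.arange(74) * 4.0
        m, sd, *_ = sep.peak_timing_error(x, 8.0, ref)
        assert m == pytest.approx(0.25, abs=0.13)
        assert sd < 0.1

    def test_too_few_matches_not_evaluable(self):
        with pytest.raises(ValueError):
            sep.peak_timing_error(np.zeros(100), 8.0, [1.0, 2.0])
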