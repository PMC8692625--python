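"""Core data model, I/O, calibration and signal-utility tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bedvitals as bv
from bedvitals import core


def _frame(n=800, fs=80.0, n_ch=4, rng=None):
    rng = rng or np.random.default_rng(0)
    t = np.arange(n) / fs
    ch = rng.normal(100.0, 1.0, size=(n, n_ch))
    return core.SensorFrame(t, ch, nominal_rate=fs)


class TestSensorFrame:
    def test_csv_roundtrip(self, tmp_path):
        f = _frame()
        p = tmp_path / "rec.csv"
        core.write_frame(f, p)
        g = core.read_frame(p)
        assert g.n_samples == 800
        assert g.nominal_rate == 80
        np.testing.assert_allclose(g.channels, f.channels)

    def test_hdf5_roundtrip_bit_exact(self, tmp_path):
        f = _frame()
        p = tmp_path / "rec.h5"
        core.write_frame(f, p)
        g = core.read_frame(p)
        assert np.array_equal(g.timestamps, f.timestamps)
        assert np.array_equal(g.channels, f.channels)
        assert g.units == f.units and g.nominal_rate == f.nominal_rate

    def test_repeated_timestamps_rejected_with_index(self, tmp_path):
        f = _frame(n=50)
        t = f.timestamps.copy()
        t[7] = t[6]  # repeat
        p = tmp_path / "bad.csv"
        import pandas as pd
        pd.DataFrame({"t": t, "ch0": f.channels[:, 0]}).to_csv(p, index=False)
        with pytest.raises(core.FormatError, match="7"):
            core.read_frame(p)

    def test_missing_time_column(self, tmp_path):
        p = tmp_path / "no_t.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(core.FormatError, match="'t'"):
            core.read_frame(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,ch0\n0.0,1.0\n0.0125,oops\n")
        with pytest.raises(core.ParseError, match="row 1"):
            core.read_frame(p)

    def test_rate_bounds_enforced(self):
        t = np.arange(100) / 30.0
        with pytest.raises(core.FormatError):
            core.SensorFrame(t, np.zeros((100, 1)), nominal_rate=30.0)


class TestCalibration:
    def test_two_point_interpolation_and_extrapolation(self):
        cal = core.two_point_calibrate(1000.0, 2000.0, 100.0)
        assert cal.au_to_lbs(1500.0) == pytest.approx(50.0)
        assert cal.au_to_lbs(1000.0) == pytest.approx(0.0)
        assert cal.au_to_lbs(2500.0) == pytest.approx(150.0)

    def test_two_point_equal_readings_guarded(self):
        with pytest.raises(core.CalibrationError):
            core.two_point_calibrate(1000.0, 1000.0, 100.0)

    def test_two_point_roundtrip_precision(self):
        cal = core.two_point_calibrate(812.3, 4567.9, 137.4)
        assert abs(cal.au_to_lbs(812.3)) < 1e-9 * 137.4
        assert abs(cal.au_to_lbs(4567.9) - 137.4) < 1e-9 * 137.4

    @staticmethod
    def _placement_frames(gains_true, load=25.0, n_pos=5, seed=0):
        """A known load moved across bed positions, read through unequal
        channel sensitivities (the inverse of the target gains)."""
        rng = np.random.default_rng(seed)
        sens = gains_true[0] / np.asarray(gains_true)
        frames = []
        for pos in range(n_pos):
            proj = rng.dirichlet(np.ones(4))
            f, _ = bv.simulate_session(
                [bv.PersonSpec(weight=load, projection=tuple(proj),
                               resp_amplitude=0.0, bcg_amplitude=0.0)],
                noise_sd=0.001, duration_s=10.0, seed=pos, tare_lbs=0.0,
                sensitivities=sens)
            frames.append(f)
        return frames

    def test_joint_gain_recovery_within_1pct(self):
        gains_true = np.array([1.0, 0.9, 1.1, 1.05])
        frames = self._placement_frames(gains_true)
        cal = core.fit_joint_calibration(frames)
        np.testing.assert_allclose(cal.channel_gains, gains_true, rtol=0.01)

    def test_identical_channels_give_unit_gains(self):
        frames = self._placement_frames(np.ones(4))
        cal = core.fit_joint_calibration(frames)
        np.testing.assert_allclose(cal.channel_gains, np.ones(4), atol=0.01)

    def test_matches_normal_equations_oracle(self):
        gains_true = np.array([1.0, 0.8, 1.3, 0.95])
        frames = self._placement_frames(gains_true, seed=3)
        cal = core.fit_joint_calibration(frames)
        # independent oracle: explicit normal equations on centered means
        M = np.vstack([f.channels.mean(axis=0) for f in frames])
        Mc = M - M.mean(axis=0)
        A, b = Mc[:, 1:], -Mc[:, 0]
        g_free = np.linalg.solve(A.T @ A, A.T @ b)
        np.testing.assert_allclose(cal.channel_gains[1:], g_free, rtol=1e-8)

    def test_fitted_gains_reduce_variance_at_least_as_much_as_truth(self):
        gains_true = np.array([1.0, 0.9, 1.1, 1.05])
        frames = self._placement_frames(gains_true, seed=5)
        cal = core.fit_joint_calibration(frames)
        M = np.vstack([f.channels.mean(axis=0) for f in frames])
        assert (np.var(M @ cal.channel_gains)
                <= np.var(M @ gains_true) + 1e-6)

    def test_too_few_placements(self):
        frames = self._placement_frames(np.ones(4))[:1]
        with pytest.raises(core.CalibrationError):
            core.fit_joint_calibration(frames)

    def test_constant_channel_degenerate(self):
        t = np.arange(100) / 80.0
        fs = []
        for load in (1.0, 2.0):
            ch = np.column_stack([np.full(100, load), np.full(100, 5.0),
                                  np.full(100, load), np.full(100, load)])
            fs.append(core.SensorFrame(t, ch))
        with pytest.raises(core.CalibrationError, match="degenerate"):
            core.fit_joint_calibration(fs)


class TestBandpass:
    fs = 80.0

    def _tone(self, f_hz, dur=120.0):
        t = np.arange(int(dur * self.fs)) / self.fs
        return np.sin(2 * np.pi * f_hz * t)

    def test_inband_tone_preserved(self):
        x = self._tone(0.3)
        y = core.bandpass(x, self.fs, 0.167, 1.5)
        mid = slice(2000, -2000)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_below_band_attenuated(self):
        x = self._tone(0.05, dur=400.0)
        y = core.bandpass(x, self.fs, 0.167, 1.5)
        mid = slice(8000, -8000)
        # oracle: the designed filter's own frequency response, applied
        # twice (forward-backward), evaluated at the tone frequency
        from scipy import signal as sps
        sos = sps.butter(4, [0.167, 1.5], btype="bandpass", fs=self.fs,
                         output="sos")
        _, h = sps.sosfreqz(sos, worN=[0.05], fs=self.fs)
        expected = np.abs(h[0]) ** 2
        assert np.abs(y[mid]).max() < 0.1  # > 90% attenuation
        assert np.abs(y[mid]).max() == pytest.approx(expected, rel=0.2)

    def test_dc_removed(self):
        y = core.bandpass(np.full(4000, 7.0), self.fs, 0.167, 1.5)
        assert np.abs(y).max() < 1e-6

    def test_zero_phase_no_lag(self):
        t = np.arange(8000) / self.fs
        x = np.sin(2 * np.pi * 0.3 * t)
        y = core.bandpass(x, self.fs, 0.167, 1.5)
        mid = slice(2000, 6000)
        lags = np.arange(-50, 51)
        xc = [np.dot(x[mid], np.roll(y, int(l))[mid]) for l in lags]
        assert abs(int(lags[int(np.argmax(xc))])) <= 1

    def test_passband_idempotence(self):
        x = self._tone(0.5)
        y1 = core.bandpass(x, self.fs, 0.167, 1.5)
        y2 = core.bandpass(y1, self.fs, 0.167, 1.5)
        mid = slice(2000, -2000)
        assert np.abs(y2[mid] - y1[mid]).max() < 0.05

    def test_nyquist_clipping_logged(self, caplog):
        x = self._tone(5.0, dur=30.0)
        with caplog.at_level("WARNING"):
            core.bandpass(x, self.fs, 5.0, 50.0)
        assert any("clipping" in r.message for r in caplog.records)

    def test_bad_band_rejected(self):
        with pytest.raises(ValueError):
            core.bandpass(np.zeros(100), self.fs, 1.5, 0.167)


class TestMovingStat:
    def test_constant_variance_zero(self):
        v = core.moving_stat(np.full(800, 3.0), 80.0, 1.0, "variance")
        assert np.abs(v).max() < 1e-20

    def test_white_noise_variance_near_unity(self, rng):
        x = rng.normal(size=80 * 600)
        v = core.moving_stat(x, 80.0, 10.0, "variance")
        # sampling-theory oracle: var of the estimate ~ 2/(n_eff-1)
        assert abs(np.mean(v) - 1.0) < 3 * np.sqrt(2.0 / 799)

    def test_moving_mean_of_ramp_is_ramp(self):
        x = np.arange(800, dtype=float)
        m = core.moving_stat(x, 80.0, 1.0, "mean")
        interior = slice(40, -40)
        np.testing.assert_allclose(m[interior], x[interior])

    def test_output_length_equals_input(self):
        assert core.moving_stat(np.zeros(321), 80.0, 0.5, "mean").size == 321

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            core.moving_stat(np.zeros(10), 80.0, 10.0, "mean")


class TestSteadyRegions:
    fs = 80.0

    def _var(self, quiet_spans, dur=60.0, hi=10.0, lo=0.1):
        v = np.full(int(dur * self.fs), hi)
        for (a, b) in quiet_spans:
            v[int(a * self.fs):int(b * self.fs)] = lo
        return v

    def test_short_run_rejected(self):
        v = self._var([(10, 18)])  # 8 s < 10 s minimum
        assert core.steady_regions(v, self.fs, 1.0, 10.0) == []

    def test_single_run_duration(self):
        v = self._var([(10, 25)])
        regs = core.steady_regions(v, self.fs, 1.0, 10.0)
        assert len(regs) == 1
        assert regs[0].duration_s == pytest.approx(15.0, abs=1.0 / self.fs)

    def test_spike_splits_runs(self):
        v = self._var([(5, 20), (21, 36)])
        regs = core.steady_regions(v, self.fs, 1.0, 10.0)
        assert len(regs) == 2
        assert regs[0].end_s <= regs[1].start_s

    def test_padding_invariance(self):
        v = self._var([(10, 25)])
        regs = core.steady_regions(v, self.fs, 1.0, 10.0)
        padded = np.concatenate([np.full(400, 50.0), v, np.full(400, 50.0)])
        regs_p = core.steady_regions(padded, self.fs, 1.0, 10.0, t0=-5.0)
        assert len(regs) == len(regs_p) == 1
        assert regs_p[0].start_s == pytest.approx(regs[0].start_s, abs=0.02)
        assert regs_p[0].duration_s == pytest.approx(regs[0].duration_s, abs=0.02)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.floats(0, 40), st.floats(1, 15)), max_size=4))
    def test_regions_disjoint_ordered_and_long_enough(self, spans):
        quiet = [(a, min(a + d, 60.0)) for a, d in spans]
        v = self._var(quiet)
        regs = core.steady_regions(v, self.fs, 1.0, 10.0)
        for r in regs:
            assert r.duration_s >= 10.0
        for r1, r2 in zip(regs, regs[1:]):
            assert r1.end_s <= r2.start_s
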