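"""Ballistocardiogram processing: single-peak BCG, beats, heart rate, analytics.

Each heartbeat's mechanical recoil appears on the leg sensors as a short
(5-50 Hz) transient. The single-peak BCG converts it into one dominant peak
per beat: per-channel bandpass (5, 50) Hz -> moving mean (50 ms) -> moving
variance (150 ms) -> channel sum -> bandpass (1, 50) Hz. Because the moving
variance is quadratic in the input, the summed energy peak scales with the
squared beat amplitude; beat *magnitude* (the linear scale used by the
respirophasic-coupling and post-ectopy analytics) is the square root of the
baseline-corrected energy at the detected peak.

Heart rate reuses the median-interval epoch machinery of the respiration
module (5-min centered window, 30 s shift, 45 s unsteady-time validity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import (CalibrationModel, SensorFrame, bandpass, moving_stat,
                   resample_uniform)
from .respiration import CompositeSignal, rate_epochs_from_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "BeatSeries",
    "BCG_BAND_HZ",
    "single_peak_bcg",
    "find_beats",
    "heart_rate",
    "respirophasic_coupling",
    "ectopy_amplitude_ratio",
    "find_ectopy_candidates",
]

BCG_BAND_HZ = (5.0, 50.0)
BCG_AMPLITUDE_BAND_HZ = (1.0, 50.0)
COMPOSITE_BAND_HZ = (1.0, 50.0)
MEAN_WINDOW_S = 0.05
VAR_WINDOW_S = 0.15
STEADY_MIN_S = 5.0
MAX_HR_BPM = 180.0


@dataclass(frozen=True)
class BeatSeries:
    """Detected heartbeats with energy and magnitude amplitudes."""

    beat_times_s: np.ndarray
    beat_amplitudes: np.ndarray        # single-peak-BCG energy peak heights
    beat_magnitudes: np.ndarray        # sqrt(energy): linear amplitude scale
    resp_phase_at_beat: np.ndarray | None = None  # "inspiration"/"expiration"/"unknown"

    def __post_init__(self):
        t = np.asarray(self.beat_times_s, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(np.asarray(self.beat_amplitudes) < 0):
            raise ValueError("beat amplitudes are an energy measure, >= 0")

    @property
    def n_beats(self) -> int:
        return len(self.beat_times_s)


def single_peak_bcg(frame: SensorFrame, cal: CalibrationModel | None = None,
                    amplitude_mode: bool = False, return_energy: bool = False):
    """One-peak-per-beat BCG series from the raw multi-channel recording.

    ``amplitude_mode`` lowers the per-channel cutoff from 5 Hz to 1 Hz for
    beat-amplitude analytics. With ``return_energy`` the summed (pre-final-
    bandpass) nonnegative energy series is returned alongside, which the
    beat detector uses for baseline-corrected amplitudes.
    """
    frame = resample_uniform(frame)
    if cal is not None and frame.units != "lbs":
        frame = cal.calibrate_channels(frame)
    fs = frame.fs
    band = BCG_AMPLITUDE_BAND_HZ if amplitude_mode else BCG_BAND_HZ
    ch = bandpass(frame.channels, fs, *band)
    ch = moving_stat(ch, fs, MEAN_WINDOW_S, "mean")
    energy = moving_stat(ch, fs, VAR_WINDOW_S, "variance").sum(axis=1)
    out = bandpass(energy, fs, *COMPOSITE_BAND_HZ)
    if return_energy:
        return out, energy
    return out


def find_beats(single_peak, fs: float, steady=None, energy=None,
               prominence_frac: float = 0.2, t0: float = 0.0,
               baseline_window_s: float = 1.0) -> BeatSeries:
    """Detect beats on the single-peak BCG inside steady (>= 5 s) regions.

    Peak spacing is at least one period at 180 bpm; prominence must reach
    20% of the local amplitude scale. Amplitude is the summed-energy value at
    the peak minus a rolling-minimum baseline; magnitude is its square root.
    """
    x = np.asarray(single_peak, dtype=float)
    n = x.size
    if energy is None:
        energy = np.maximum(x, 0.0)
    base = (pd.Series(energy)
            .rolling(int(round(baseline_window_s * fs)), center=True, min_periods=1)
            .min().to_numpy())
    min_dist = max(int(round(60.0 / MAX_HR_BPM * fs)), 1)
    regions = ([(reg.start_s, reg.end_s) for reg in steady]
               if steady is not None else [(t0, t0 + n / fs)])
    times, amps = [], []
    for (s0, s1) in regions:
        i0 = max(int(round((s0 - t0) * fs)), 0)
        i1 = min(int(round((s1 - t0) * fs)), n)
        seg = x[i0:i1]
        if seg.size < min_dist:
            continue
        # beats occupy a small duty cycle, so a high percentile of the
        # single-peak series tracks beat height rather than the noise floor
        scale = float(np.percentile(seg, 95) - np.median(seg))
        if scale <= 0:
            continue
        # strict first pass estimates the beat period; the second pass
        # enforces spacing at 60% of it. Beats are positive energy
        # excursions; the high-pass rebound between beats sits far below
        # beat height and is excluded by the height gate.
        strict, _ = sps.find_peaks(seg, distance=min_dist,
                                   height=0.6 * np.percentile(seg, 98),
                                   prominence=prominence_frac * scale)
        dist = min_dist
        if strict.size >= 3:
            period = float(np.median(np.diff(strict)))
            dist = max(min_dist, int(0.6 * period))
        pk, _ = sps.find_peaks(seg, distance=dist,
                               height=0.35 * scale,
                               prominence=prominence_frac * scale)
        for p in pk:
            times.append(t0 + (i0 + p) / fs)
            amps.append(max(energy[i0 + p] - base[i0 + p], 0.0))
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    amps = np.asarray(amps, dtype=float)[order]
    return BeatSeries(times, amps, np.sqrt(amps))


def heart_rate(beats: BeatSeries, duration_s: float, steady=None,
               t0: float = 0.0, **kw):
    """Heart-rate epochs: same contract as the respiratory-rate estimator."""
    return rate_epochs_from_peaks(beats.beat_times_s, duration_s,
                                  steady=steady, t0=t0, **kw)


def steady_from_bcg(single_peak, fs: float, var_window_s: float = 2.0,
                    min_duration_s: float = STEADY_MIN_S,
                    threshold: float | None = None, t0: float = 0.0):
    """Steady regions from the BCG-scale moving variance (>= 5 s minimum)."""
    from .core import adaptive_steady_threshold, steady_regions
    var = moving_stat(np.asarray(single_peak, dtype=float), fs,
                      var_window_s, "variance")
    if threshold is None:
        threshold = adaptive_steady_threshold(var)
    return steady_regions(var, fs, threshold, min_duration_s, t0=t0,
                          channel_scope="single_peak_bcg")


def bcg_pipeline(frame: SensorFrame, cal: CalibrationModel | None = None,
                 steady_threshold: float | None = None,
                 amplitude_mode: bool = False):
    """Frame -> single-peak BCG, steady regions, beats and heart-rate epochs."""
    sp, energy = single_peak_bcg(frame, cal, amplitude_mode=amplitude_mode,
                                 return_energy=True)
    fs = frame.nominal_rate
    t0 = float(frame.timestamps[0])
    steady = steady_from_bcg(sp, fs, threshold=steady_threshold, t0=t0)
    beats = find_beats(sp, fs, steady=steady, energy=energy, t0=t0)
    dur = frame.timestamps[-1] - frame.timestamps[0]
    epochs = heart_rate(beats, dur, steady=steady, t0=t0)
    return {"single_peak": sp, "energy": energy, "steady": steady,
            "beats": beats, "epochs": epochs}


def label_resp_phase(beats: BeatSeries, composite: CompositeSignal,
                     boundary_margin_s: float = 0.25) -> BeatSeries:
    """Label each beat inspiration/expiration from the respiratory composite.

    A beat on the rising limb (after the last trough, before the next peak)
    is inspiratory; on the falling limb expiratory. Beats closer than
    ``boundary_margin_s`` to a peak or trough straddle the phase transition
    (the filtered composite's extrema are slightly displaced from the true
    chest-wall turning points) and are labeled unknown.
    """
    fs = composite.fs
    x = composite.values
    min_dist = max(int(round(1.5 * fs)), 1)
    scale = np.percentile(np.abs(x - np.median(x)), 90)
    pk, _ = sps.find_peaks(x, distance=min_dist, prominence=0.25 * scale)
    tr, _ = sps.find_peaks(-x, distance=min_dist, prominence=0.25 * scale)
    pk_t = composite.t0 + pk / fs
    tr_t = composite.t0 + tr / fs
    ext_t = np.sort(np.concatenate([pk_t, tr_t])) if pk_t.size + tr_t.size else np.array([])
    phases = []
    for bt in beats.beat_times_s:
        if ext_t.size and np.min(np.abs(ext_t - bt)) < boundary_margin_s:
            phases.append("unknown")
            continue
        last_pk = pk_t[pk_t <= bt]
        last_tr = tr_t[tr_t <= bt]
        if last_pk.size == 0 and last_tr.size == 0:
            phases.append("unknown")
        elif last_tr.size and (last_pk.size == 0 or last_tr[-1] > last_pk[-1]):
            phases.append("inspiration")
        else:
            phases.append("expiration")
    return BeatSeries(beats.beat_times_s, beats.beat_amplitudes,
                      beats.beat_magnitudes, np.asarray(phases))


def respirophasic_coupling(beats: BeatSeries, composite: CompositeSignal | None = None,
                           min_beats_per_phase: int = 10):
    """Inspiratory vs expiratory beat magnitudes (cardiopulmonary coupling).

    Returns a dict with the two magnitude samples, their means, the
    inspiratory/expiratory mean ratio, and a two-sided Mann-Whitney p-value;
    ``None`` when either phase has fewer than ``min_beats_per_phase`` beats.
    """
    if beats.resp_phase_at_beat is None:
        if composite is None:
            raise ValueError("beats lack phase labels and no composite given")
        beats = label_resp_phase(beats, composite)
    ph = np.asarray(beats.resp_phase_at_beat)
    insp = beats.beat_magnitudes[ph == "inspiration"]
    expi = beats.beat_magnitudes[ph == "expiration"]
    if insp.size < min_beats_per_phase or expi.size < min_beats_per_phase:
        return None
    u = stats.mannwhitneyu(insp, expi, alternative="two-sided")
    return {
        "inspiratory": insp,
        "expiratory": expi,
        "mean_inspiratory": float(insp.mean()),
        "mean_expiratory": float(expi.mean()),
        "ratio": float(insp.mean() / expi.mean()),
        "p_value": float(u.pvalue),
    }


def ectopy_amplitude_ratio(beats: BeatSeries, ectopy_intervals,
                           n_preceding: int = 3):
    """Post-ectopy / pre-ectopy beat-magnitude ratios.

    For each ectopic interval: ratio = magnitude of the first beat after the
    interval over the mean magnitude of the ``n_preceding`` beats before it.
    Events with too few preceding beats are skipped with a log entry.
    """
    ratios = []
    bt = beats.beat_times_s
    mag = beats.beat_magnitudes
    for (e0, e1) in ectopy_intervals:
        pre_idx = np.flatnonzero(bt < e0)
        post_idx = np.flatnonzero(bt > e1)
        if pre_idx.size < n_preceding or post_idx.size == 0:
            logger.info("ectopy event (%.1f, %.1f) skipped: insufficient beats",
                        e0, e1)
            continue
        pre = mag[pre_idx[-n_preceding:]]
        post = mag[post_idx[0]]
        ratios.append(float(post / pre.mean()))
    ratios = np.asarray(ratios)
    summary = {
        "ratios": ratios,
        "mean_ratio": float(ratios.mean()) if ratios.size else float("nan"),
        "n_events": int(ratios.size),
    }
    return summary


def find_ectopy_candidates(beats: BeatSeries, short_frac: float = 0.7,
                           long_frac: float = 1.2, window: int = 9):
    """Heuristic ectopy localization from inter-beat intervals.

    An interval below 70% of the local median followed by one above 120%
    flags a candidate ectopic run; a lone interval near twice the local
    median flags a run whose low-amplitude ectopic beat escaped detection
    entirely. A fallback when no annotation exists — not a diagnostic.
    """
    bt = beats.beat_times_s
    if bt.size < window + 2:
        return []
    iv = np.diff(bt)
    med = pd.Series(iv).rolling(window, center=True, min_periods=3).median().to_numpy()
    out = []
    for i in range(iv.size):
        if (i + 1 < iv.size and iv[i] < short_frac * med[i]
                and iv[i + 1] > long_frac * med[i]):
            end = bt[i + 2] - 0.01 if i + 2 < bt.size else bt[i + 1]
            out.append((bt[i] + 0.01, end))
        elif iv[i] > 1.7 * med[i]:
            out.append((bt[i] + 0.01, bt[i + 1] - 0.01))
    return out
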