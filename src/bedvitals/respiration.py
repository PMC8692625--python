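"""Respiratory waveform extraction, rates, apneas and periodic breathing.

The chest wall redistributes load across the bed legs with every breath. Each
channel is bandpassed to the respiratory band (0.167-1.5 Hz), and a single
composite respiratory signal is formed by projecting the channels onto the
leading principal component computed in 12.5 s windows. Breath peaks are
found only inside movement-free (steady) regions of at least 10 s; the
respiratory rate per 30 s epoch is 60 / median inter-peak interval within a
centered 5-min window, with epochs holding more than 45 s of unsteady
physiology marked invalid. Apneas are sustained (>10 s) collapses of the
respiratory envelope below half of the flanking baseline, classified central
vs obstructive by the residual effort fraction; periodic (Cheyne-Stokes
spectrum) breathing is flagged from the envelope autocorrelation at
periodicities above 30 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (CalibrationModel, SensorFrame, SteadyRegion, bandpass,
                   moving_stat, resample_uniform)

__all__ = [
    "CompositeSignal",
    "RateEpoch",
    "ApneaEvent",
    "RESP_BAND_HZ",
    "resp_channels",
    "pca_composite",
    "find_breath_peaks",
    "respiratory_rate",
    "rate_epochs_from_peaks",
    "detect_apneas",
    "periodic_breathing",
]

RESP_BAND_HZ = (0.167, 1.5)
PCA_WINDOW_S = 12.5
STEADY_MIN_S = 10.0
RATE_WINDOW_S = 300.0
RATE_STEP_S = 30.0
MAX_UNSTEADY_S = 45.0
APNEA_MIN_S = 10.0


@dataclass(frozen=True)
class CompositeSignal:
    """Single respiratory waveform composited from the channel signals."""

    values: np.ndarray
    window_weights: np.ndarray  # (n_windows, n_channels), unit-norm loadings
    window_s: float
    fs: float
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass(frozen=True)
class RateEpoch:
    epoch_start_s: float
    rate_bpm: float
    n_peaks_used: int
    valid: bool
    reason_invalid: str = ""


@dataclass(frozen=True)
class ApneaEvent:
    start_s: float
    duration_s: float
    kind: str  # {"central", "obstructive", "unclassified"}
    effort_amplitude_fraction: float = float("nan")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


def resp_channels(frame: SensorFrame, cal: CalibrationModel | None = None) -> np.ndarray:
    """Per-channel zero-phase bandpass to the respiratory band."""
    frame = resample_uniform(frame)
    if cal is not None and frame.units != "lbs":
        frame = cal.calibrate_channels(frame)
    return bandpass(frame.channels, frame.fs, *RESP_BAND_HZ)


def pca_composite(channels, fs: float, window_s: float = PCA_WINDOW_S,
                  crossfade_s: float = 0.5, t0: float = 0.0) -> CompositeSignal:
    """Composite the channels via leading-PC loadings per 12.5 s window.

    Per non-overlapping window the channel covariance's leading eigenvector
    supplies the loadings; the channels are projected onto it and windows are
    stitched with a short crossfade so loading changes do not produce steps.
    The eigenvector sign is chosen so the loading of the highest-variance
    channel is positive; a zero-variance window carries the previous loading
    forward.
    """
    x = np.asarray(channels, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("pca_composite needs >= 2 channels")
    n, n_ch = x.shape
    w = int(round(window_s * fs))
    if w < 4:
        raise ValueError("window too short")
    n_win = max(1, int(np.ceil(n / w)))
    cf = int(round(crossfade_s * fs))
    loadings = np.zeros((n_win, n_ch))
    prev = np.full(n_ch, 1.0 / np.sqrt(n_ch))
    out = np.zeros(n)
    weight_acc = np.zeros(n)
    for wi in range(n_win):
        i0, i1 = wi * w, min((wi + 1) * w, n)
        seg = x[i0:i1]
        if seg.shape[0] < 2 or np.allclose(seg.var(axis=0), 0):
            v = prev
        else:
            c = np.cov(seg, rowvar=False)
            evals, evecs = np.linalg.eigh(c)
            v = evecs[:, -1]
            top = int(np.argmax(np.diag(c)))
            if v[top] < 0:
                v = -v
        loadings[wi] = v
        prev = v
        # project over an extended window for the crossfade overlap
        e0, e1 = max(i0 - cf // 2, 0), min(i1 + cf // 2, n)
        proj = x[e0:e1] @ v
        ramp = np.ones(e1 - e0)
        if e0 > 0:
            m = i0 + cf // 2 - e0
            ramp[:m] = np.linspace(0, 1, m, endpoint=False)
        if e1 < n:
            m = e1 - (i1 - cf // 2)
            ramp[-m:] = np.linspace(1, 0, m, endpoint=False)
        out[e0:e1] += proj * ramp
        weight_acc[e0:e1] += ramp
    out /= np.maximum(weight_acc, 1e-12)
    return CompositeSignal(out, loadings, window_s, fs, t0=t0)


def steady_from_composite(composite: CompositeSignal,
                          var_window_s: float = 5.0,
                          min_duration_s: float = STEADY_MIN_S,
                          threshold: float | None = None):
    """Steady (movement-free) regions of the respiratory composite.

    Moving variance over a window spanning at least one breath cycle, with
    the adaptive default threshold (4 x the 10th variance percentile);
    regions shorter than 10 s are rejected.
    """
    from .core import adaptive_steady_threshold, steady_regions
    var = moving_stat(composite.values, composite.fs, var_window_s, "variance")
    if threshold is None:
        threshold = adaptive_steady_threshold(var)
    return steady_regions(var, composite.fs, threshold, min_duration_s,
                          t0=composite.t0, channel_scope="resp_composite")


def respiratory_pipeline(frame: SensorFrame, cal: CalibrationModel | None = None,
                         steady_threshold: float | None = None):
    """Frame -> composite, steady regions, breath peaks and rate epochs."""
    ch = resp_channels(frame, cal)
    comp = pca_composite(ch, frame.nominal_rate, t0=float(frame.timestamps[0]))
    steady = steady_from_composite(comp, threshold=steady_threshold)
    peaks = find_breath_peaks(comp, steady)
    dur = frame.timestamps[-1] - frame.timestamps[0]
    epochs = respiratory_rate(peaks, dur, steady=steady,
                              t0=float(frame.timestamps[0]))
    return {"composite": comp, "steady": steady, "peaks": peaks,
            "epochs": epochs}


def _amplitude_scale(x) -> float:
    """Robust half peak-to-peak amplitude (98th-2nd percentile range / 2).

    Wide percentiles so the scale tracks breath-peak height even for slow,
    low-duty-cycle contours where most samples sit near the baseline.
    """
    lo, hi = np.percentile(x, [2, 98])
    return float((hi - lo) / 2.0)


def _adaptive_peaks(seg, fs, min_dist_s, prominence_frac):
    """Two-pass peak finding with period-adaptive minimum spacing.

    A strict first pass (height at half the top-percentile level) estimates
    the dominant period; the second pass enforces spacing at 60% of it (never
    below the physiologic floor), rejecting between-event noise maxima.
    """
    scale = _amplitude_scale(seg)
    if scale <= 0:
        return np.array([], dtype=int)
    strict, _ = sps.find_peaks(seg, distance=int(min_dist_s * fs),
                               height=0.5 * np.percentile(seg, 98),
                               prominence=prominence_frac * scale)
    dist_s = min_dist_s
    if strict.size >= 3:
        period = float(np.median(np.diff(strict))) / fs
        dist_s = max(min_dist_s, 0.6 * period)
    pk, _ = sps.find_peaks(seg, distance=max(int(dist_s * fs), 1),
                           prominence=prominence_frac * scale)
    return pk


def find_breath_peaks(composite: CompositeSignal, steady,
                      max_rate_bpm: float = 40.0,
                      prominence_frac: float = 0.25,
                      smooth_s: float = 0.5) -> np.ndarray:
    """Breath-peak times, searched only inside steady regions.

    The composite gets an additional 0.5 s moving-mean smoothing before peak
    finding; minimum spacing is one period at the fastest plausible rate
    (40 bpm), adaptively widened toward the region's own dominant period, and
    prominence must reach 25% of the region's amplitude scale.
    """
    fs = composite.fs
    x = moving_stat(composite.values, fs, smooth_s, "mean")
    min_dist_s = 60.0 / max_rate_bpm
    times = []
    for reg in steady:
        i0 = max(int(round((reg.start_s - composite.t0) * fs)), 0)
        i1 = min(int(round((reg.end_s - composite.t0) * fs)), x.size)
        seg = x[i0:i1]
        if seg.size < int(min_dist_s * fs):
            continue
        pk = _adaptive_peaks(seg, fs, min_dist_s, prominence_frac)
        times.append(composite.t0 + (i0 + pk) / fs)
    if not times:
        return np.array([])
    return np.sort(np.concatenate(times))


def _unsteady_seconds(window_lo, window_hi, steady, session_lo, session_hi):
    lo = max(window_lo, session_lo)
    hi = min(window_hi, session_hi)
    if hi <= lo:
        return 0.0
    covered = 0.0
    for reg in steady:
        covered += max(0.0, min(reg.end_s, hi) - max(reg.start_s, lo))
    return (hi - lo) - covered


def rate_epochs_from_peaks(
    peaks,
    duration_s: float,
    steady=None,
    window_s: float = RATE_WINDOW_S,
    step_s: float = RATE_STEP_S,
    max_unsteady_s: float = MAX_UNSTEADY_S,
    t0: float = 0.0,
):
    """Median-interval rate per 30 s epoch from a train of peak times.

    Shared by the respiratory-rate and heart-rate estimators: per epoch the
    rate is 60 / median inter-peak interval inside the centered 5-min window.
    Epochs with fewer than 2 peaks, or more than ``max_unsteady_s`` of
    unsteady physiology in the window, are invalid.
    """
    peaks = np.asarray(peaks, dtype=float)
    epochs = []
    n_epochs = int(np.ceil(duration_s / step_s))
    for e in range(n_epochs):
        start = t0 + e * step_s
        center = start + step_s / 2.0
        lo, hi = center - window_s / 2.0, center + window_s / 2.0
        in_win = peaks[(peaks >= lo) & (peaks <= hi)]
        reason = ""
        rate = float("nan")
        valid = True
        if in_win.size < 2:
            valid, reason = False, "fewer than 2 peaks in window"
        else:
            intervals = np.diff(in_win)
            med = float(np.median(intervals))
            if med <= 0:
                valid, reason = False, "degenerate intervals"
            else:
                rate = 60.0 / med
        if valid and steady is not None:
            uns = _unsteady_seconds(lo, hi, steady, t0, t0 + duration_s)
            if uns > max_unsteady_s:
                valid, reason = False, f"{uns:.0f} s unsteady physiology"
                rate = float("nan")
        epochs.append(RateEpoch(start, rate, int(in_win.size), valid, reason))
    return epochs


def respiratory_rate(peaks, duration_s, steady=None, t0: float = 0.0, **kw):
    """Respiratory-rate epochs (30 s grid, centered 5-min median window)."""
    return rate_epochs_from_peaks(peaks, duration_s, steady=steady, t0=t0, **kw)


def _fundamental_amplitude(seg, fs, f0):
    """Hann-windowed Fourier amplitude of ``seg`` at frequency ``f0``."""
    n = seg.size
    t = np.arange(n) / fs
    w = np.hanning(n)
    return float(np.abs(np.sum(seg * w * np.exp(-2j * np.pi * f0 * t)))
                 / np.sum(w) * 2.0)


def detect_apneas(
    composite: CompositeSignal,
    envelope_window_s: float = 4.0,
    event_threshold: float = 0.5,
    central_max_effort: float = 0.075,
    min_duration_s: float = APNEA_MIN_S,
    baseline_flank_s: float = 60.0,
    baseline_amplitude: float | None = None,
):
    """Low-variance respiratory collapses lasting > 10 s, typed by effort.

    Candidate events are maximal runs where the moving-RMS envelope stays
    below ``event_threshold`` x the flanking-breathing baseline. Because
    breaths are discrete, envelope crossings blur the edges by up to a
    breath period, so each candidate's boundaries are refined from the
    flanking full-size breath peaks: the apnea spans from one breath period
    after the last pre-gap peak's upstroke start to the first post-gap
    upstroke, making the duration (peak gap minus one breath period) exact
    to peak-timing accuracy.

    The residual effort fraction compares the Fourier amplitude at the
    flanking breath frequency inside the event with the same amplitude in
    the flanks (both detrended identically, so the slow transient the
    high-pass band edge produces at the cessation step does not register as
    effort). Kind is central below 7.5% of baseline — the split sits just
    above the estimator's noise floor at the 10 s duration minimum —
    obstructive in [7.5%, 50%), and unclassified without a usable flank.
    """
    fs = composite.fs
    x = composite.values
    env = np.sqrt(np.maximum(
        moving_stat(x ** 2, fs, envelope_window_s, "mean"), 0.0))
    n = env.size
    if baseline_amplitude is not None:
        provisional = np.full(n, float(baseline_amplitude))
    else:
        w = int(round(2 * baseline_flank_s * fs))
        if w >= n:
            provisional = np.full(n, np.median(env))
        else:
            provisional = (pd.Series(env)
                           .rolling(w, center=True, min_periods=1)
                           .quantile(0.75).to_numpy())
    low = env < event_threshold * provisional
    edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
    events = []
    for i0, i1 in zip(edges[::2], edges[1::2]):
        # coarse pre-filter: candidate must be at least half the final rule
        if (i1 - i0) / fs + envelope_window_s / 2.0 < min_duration_s / 2.0:
            continue
        f0 = max(int(i0 - baseline_flank_s * fs), 0)
        f1 = min(int(i1 + baseline_flank_s * fs), n)
        flank_mask = np.zeros(n, dtype=bool)
        flank_mask[f0:i0] = True
        flank_mask[i1:f1] = True
        flank_mask &= ~low
        if baseline_amplitude is not None:
            base = float(baseline_amplitude)
        elif flank_mask.any():
            base = float(np.median(env[flank_mask]))
        else:
            base = float("nan")

        # edge refinement from full-size breath peaks around the candidate
        seg = x[f0:f1]
        sm = moving_stat(seg, fs, 0.5, "mean")
        # full-size breaths only: effort breaths inside the event are below
        # the height gate relative to the flanking baseline
        height = event_threshold * base * np.sqrt(2.0) if np.isfinite(base) else None
        pk, _ = sps.find_peaks(sm, distance=max(int(1.5 * fs), 1), height=height)
        pk_t = (f0 + pk) / fs
        gap_lo, gap_hi = i0 / fs, i1 / fs
        pre = pk_t[pk_t <= gap_lo + envelope_window_s / 2.0]
        post = pk_t[pk_t >= gap_hi - envelope_window_s / 2.0]
        start = composite.t0 + gap_lo - envelope_window_s / 4.0
        dur = (i1 - i0) / fs + envelope_window_s / 2.0
        period = float("nan")
        if pre.size >= 3 and post.size >= 1:
            period = float(np.median(np.diff(pre)))
            tp_last, tp_first = pre[-1], post[0]
            dur = (tp_first - tp_last) - period
            # upstroke length from the trough preceding the last pre-gap peak
            j = int(tp_last * fs)
            j0 = max(j - int(period * fs), 0)
            t_insp = (j - (j0 + int(np.argmin(sm[max(j0 - f0, 0):j - f0]) if j > f0 else 0))) / fs
            start = composite.t0 + tp_last - t_insp + period
        if dur <= min_duration_s:
            continue
        effort = float("nan")
        if np.isfinite(base) and np.isfinite(period) and period > 0:
            # detrend core and flank identically; the fundamental-amplitude
            # attenuation of the detrend cancels in the ratio
            xd = x - moving_stat(x, fs, 3.0, "mean")
            s_rel = start - composite.t0
            c0 = max(int((s_rel + 1.5) * fs), 0)
            c1 = min(int((s_rel + dur - 1.5) * fs), n)
            fl0 = max(int((s_rel - 45.0) * fs), 0)
            fl1 = max(int((s_rel - 2.0) * fs), fl0 + 1)
            if c1 > c0 + int(2 * fs) and fl1 > fl0 + int(10 * fs):
                a_core = _fundamental_amplitude(xd[c0:c1], fs, 1.0 / period)
                a_flank = _fundamental_amplitude(xd[fl0:fl1], fs, 1.0 / period)
                if a_flank > 0:
                    effort = a_core / a_flank
        if not np.isfinite(effort):
            kind = "unclassified"
        elif effort < central_max_effort:
            kind = "central"
        else:
            kind = "obstructive"
        events.append(ApneaEvent(start, dur, kind, effort))
    return events


def periodic_breathing(
    composite: CompositeSignal,
    min_period_s: float = 30.0,
    min_duration_s: float = 600.0,
    envelope_window_s: float = 2.0,
    peak_threshold: float = 0.5,
    search_from_s: float = 10.0,
):
    """Flag periodic (Cheyne-Stokes spectrum) breathing from the envelope.

    The respiratory-envelope autocorrelation is scanned for its first
    secondary peak at lag >= ``search_from_s``; periodic breathing is flagged
    when that dominant peak reaches ``peak_threshold`` at a lag above
    ``min_period_s``. Returns ``(flag, period_s)`` with ``period_s = None``
    when no qualifying peak exists; raises on insufficient duration.
    """
    fs = composite.fs
    x = composite.values
    if x.size / fs < min_duration_s:
        raise ValueError(
            f"periodic-breathing analysis needs >= {min_duration_s:.0f} s of signal"
        )
    env = np.sqrt(np.maximum(moving_stat(x ** 2, fs, envelope_window_s, "mean"), 0.0))
    # smooth over a couple of breath cycles so within-cycle envelope ripple
    # (periods of a few seconds) cannot masquerade as slow periodicity
    env = moving_stat(env, fs, 8.0, "mean")
    e = env - env.mean()
    denom = float(np.dot(e, e))
    if denom <= 0:
        return False, None
    max_lag = int(min(x.size // 2, 3 * min_period_s * fs * 2))
    ac = np.array([np.dot(e[: e.size - L], e[L:]) / denom
                   for L in range(0, max_lag)])
    lag0 = int(search_from_s * fs)
    pk, props = sps.find_peaks(ac[lag0:], height=peak_threshold)
    if pk.size == 0:
        return False, None
    period = (lag0 + pk[0]) / fs
    return bool(period > min_period_s), float(period)
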