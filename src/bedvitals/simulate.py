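"""Seeded generator of 4-channel bed-sensor recordings with full ground truth.

The simulator emulates everything the analysis pipeline has to detect:

* static bed tare and per-person weight projected onto the four legs,
* a respiratory chest-wall waveform (brisk linear inspiratory upstroke,
  exponential expiratory decay), amplitude-modulated by apneas and, when
  requested, by a slow periodic-breathing envelope,
* a ballistocardiogram beat train (damped ~8 Hz kernel, one per heartbeat)
  with respirophasic amplitude coupling and ectopic-beat perturbations,
* bed entry/exit steps, episodic movement artifacts with load
  redistribution, slow sensor drift and white sensor noise.

Every recording comes with a :class:`SessionTruth` carrying the exact breath
peaks, beat times/amplitudes, entry/exit events, apnea intervals, movement
intervals and mixing matrix used, so downstream estimators can be scored
against ground truth. Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RAW_AU, CalibrationModel, SensorFrame

__all__ = [
    "PersonSpec",
    "ApneaSpec",
    "SessionTruth",
    "simulate_session",
    "simulate_aliquot_test",
    "simulate_simultaneity",
    "SimulationError",
]

KG_PER_ML_WATER = 0.001
LBS_PER_KG = 2.20462262185

#: BCG beat kernel parameters: a damped sinusoid with energy in the 5-50 Hz
#: band, ~0.3 s long — any kernel in that band exercises the pipeline.
_BCG_FREQ_HZ = 8.0
_BCG_DECAY_S = 0.08
_BCG_LEN_S = 0.3


class SimulationError(ValueError):
    pass


@dataclass
class PersonSpec:
    """One sleeper: weight, leg-load projection, respiration and heartbeat."""

    weight: float = 150.0                      # lbs
    projection: tuple = (0.35, 0.3, 0.2, 0.15)  # leg-load fractions, sum 1
    resp_rate: float = 15.0                    # breaths / min
    resp_amplitude: float = 0.5                # lbs, chest-wall load swing
    inspiration_fraction: float = 0.3          # fraction of cycle rising
    expiry_tau: float = 1.2                    # s, expiratory decay constant
    heart_rate: float = 65.0                   # beats / min
    bcg_amplitude: float = 0.3                 # lbs-scale beat kernel height
    coupling_gain: float = 1.0                 # inspiratory beat multiplier
    entry_s: float = 0.0
    exit_s: float | None = None                # None -> end of session
    periodic_depth: float = 0.0                # 0..1 periodic-breathing depth
    periodic_period_s: float = 60.0
    label: str = "P1"

    def validate(self, duration_s: float) -> None:
        p = np.asarray(self.projection, dtype=float)
        if self.weight <= 0:
            raise SimulationError("weight must be > 0")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise SimulationError("projection must be nonnegative and sum to 1")
        if not (6 < self.resp_rate < 40):
            raise SimulationError("resp_rate outside (6, 40) bpm")
        if not (40 < self.heart_rate < 180):
            raise SimulationError("heart_rate outside (40, 180) bpm")
        if not (0 < self.inspiration_fraction < 1):
            raise SimulationError("inspiration_fraction outside (0, 1)")
        exit_s = duration_s if self.exit_s is None else self.exit_s
        if not (0 <= self.entry_s < exit_s <= duration_s):
            raise SimulationError("entry/exit must satisfy 0 <= entry < exit <= duration")


@dataclass
class ApneaSpec:
    """A central (no effort) or obstructive (residual effort) apnea episode."""

    start_s: float
    duration_s: float
    kind: str = "central"          # {"central", "obstructive"}
    effort_fraction: float = 0.0   # 0 for central, ~0.05-0.5 for obstructive
    person: str | None = None      # defaults to the first person

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise SimulationError("apnea duration must be > 0")
        if self.kind not in ("central", "obstructive"):
            raise SimulationError(f"unknown apnea kind {self.kind!r}")
        if self.kind == "central" and self.effort_fraction != 0.0:
            raise SimulationError("central apnea must have effort_fraction 0")
        if self.kind == "obstructive" and not (0 < self.effort_fraction < 1):
            raise SimulationError("obstructive apnea needs effort_fraction in (0, 1)")


@dataclass
class SessionTruth:
    """Ground truth for one simulated session."""

    duration_s: float = 0.0
    fs: float = 80.0
    tare_lbs: float = 0.0
    breath_peaks: dict = field(default_factory=dict)     # label -> times (s)
    beat_times: dict = field(default_factory=dict)       # label -> times (s)
    beat_amplitudes: dict = field(default_factory=dict)  # label -> lbs-scale
    beat_resp_phase: dict = field(default_factory=dict)  # label -> str array
    resp_sources: dict = field(default_factory=dict)     # label -> waveform
    events: list = field(default_factory=list)           # (time, delta_lbs, label)
    apneas: list = field(default_factory=list)           # (start, dur, kind, label)
    ectopy_intervals: list = field(default_factory=list)  # (start, end) s
    movement_intervals: list = field(default_factory=list)
    mixing_matrix: np.ndarray | None = None              # n_channels x n_persons
    calibration: CalibrationModel | None = None
    steps: list = field(default_factory=list)            # (time, delta_lbs)
    person_weights: dict = field(default_factory=dict)   # label -> lbs


def _resp_waveform(t, period, insp_frac, tau):
    """Periodic breath contour: linear rise then exponential decay, peak 1."""
    phase = np.mod(t, period)
    t_insp = insp_frac * period
    base = np.exp(-(period - t_insp) / tau)
    rising = phase < t_insp
    out = np.where(
        rising,
        base + (1.0 - base) * phase / t_insp,
        np.exp(-(phase - t_insp) / tau),
    )
    return out


def _smooth(x, fs, window_s):
    w = int(round(window_s * fs)) | 1
    k = np.hanning(w + 2)[1:-1]
    k /= k.sum()
    return np.convolve(x, k, mode="same")


def _bcg_kernel(fs):
    t = np.arange(0, _BCG_LEN_S, 1.0 / fs)
    k = np.sin(2 * np.pi * _BCG_FREQ_HZ * t) * np.exp(-t / _BCG_DECAY_S)
    # zero the kernel's 0th and 1st moments (net impulse and displacement
    # return to baseline over a beat), so the beat train radiates essentially
    # nothing at its repetition fundamental and its low harmonics; the
    # tapered basis keeps the kernel endpoints at zero
    h = np.hanning(k.size)
    tc = t - t.mean()
    k = k - (k.sum() / h.sum()) * h                       # zero 0th moment
    k = k - ((k @ tc) / ((h * tc) @ tc)) * (h * tc)       # zero 1st moment
    return k / np.abs(k).max()


def simulate_session(
    persons,
    apneas=(),
    ectopy_times=(),
    noise_sd: float = 0.01,
    drift_per_hour: float = 0.0,
    duration_s: float = 600.0,
    seed: int = 0,
    fs: float = 80.0,
    tare_lbs: float = 100.0,
    sensitivities=None,
    movement_intervals=(),
    post_ectopic_gain: float = 1.4,
    movement_amplitude: float = 5.0,
):
    """Simulate a 4-channel bed recording; returns ``(frame, truth)``.

    ``sensitivities`` are per-channel AU-per-lb factors emulating unequal
    digitizer response; the truth calibration carries the correcting gains
    (channel 0 as reference). Ectopic beats get a 50%-shortened preceding
    interval, 50% amplitude, and a ``post_ectopic_gain``-amplified successor.
    """
    rng = np.random.default_rng(seed)
    persons = list(persons)
    if sensitivities is None:
        sensitivities = np.ones(4)
    sens = np.asarray(sensitivities, dtype=float)
    n_ch = sens.size

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    truth = SessionTruth(duration_s=duration_s, fs=fs, tare_lbs=tare_lbs)

    labels = []
    for p in persons:
        p.validate(duration_s)
        labels.append(p.label)

    apneas = list(apneas)
    by_person: dict = {}
    for a in apneas:
        a.validate()
        lbl = a.person if a.person is not None else (labels[0] if labels else None)
        if lbl is None:
            raise SimulationError("apnea specified without any person")
        ivs = by_person.setdefault(lbl, [])
        for (s0, s1) in ivs:
            if a.start_s < s1 and s0 < a.start_s + a.duration_s:
                raise SimulationError(f"overlapping apneas for person {lbl}")
        ivs.append((a.start_s, a.start_s + a.duration_s))
        truth.apneas.append((a.start_s, a.duration_s, a.kind, lbl))

    chan = np.full((n, n_ch), tare_lbs / n_ch)
    kernel = _bcg_kernel(fs)
    mixing = np.zeros((n_ch, len(persons)))

    for pi, p in enumerate(persons):
        exit_s = duration_s if p.exit_s is None else p.exit_s
        proj = np.asarray(p.projection, dtype=float)[:n_ch]
        in_bed = (t >= p.entry_s) & (t < exit_s)
        mixing[:, pi] = proj
        truth.person_weights[p.label] = p.weight
        if p.entry_s > 0:
            truth.events.append((p.entry_s, +p.weight, p.label))
        if exit_s < duration_s:
            truth.events.append((exit_s, -p.weight, p.label))

        # --- respiratory source --------------------------------------------
        # Breaths are discrete events: apnea onsets snap to the next breath-
        # cycle boundary and breathing resumes with a fresh (recovery-breath)
        # upstroke at apnea end, so truth apnea intervals are well defined.
        period = 60.0 / p.resp_rate
        t_insp = p.inspiration_fraction * period
        person_apneas = [a for a in apneas
                         if (a.person if a.person is not None else labels[0]) == p.label]
        person_apneas.sort(key=lambda a: a.start_s)
        segments = []  # (seg_start, seg_end, multiplier, record_peaks)
        cursor = p.entry_s
        for a in person_apneas:
            n_cycles = int(np.ceil(max(a.start_s - cursor, 0.0) / period))
            s0 = cursor + n_cycles * period
            s1 = min(s0 + a.duration_s, exit_s)
            if s0 > cursor:
                segments.append((cursor, s0, 1.0, True))
            segments.append((s0, s1, a.effort_fraction, False))
            # replace the requested interval with the snapped one in truth
            truth.apneas = [(ts, td, tk, tl) if tl != p.label or ts != a.start_s
                            else (s0, s1 - s0, tk, tl)
                            for (ts, td, tk, tl) in truth.apneas]
            cursor = s1
        if cursor < exit_s:
            segments.append((cursor, exit_s, 1.0, True))

        resp = np.zeros(n)
        peaks = []
        for (s0, s1, mult, record) in segments:
            i0, i1 = int(round(s0 * fs)), int(round(s1 * fs))
            if i1 <= i0 or mult == 0.0:
                continue
            seg_t = t[i0:i1] - s0
            resp[i0:i1] = mult * _resp_waveform(
                seg_t, period, p.inspiration_fraction, p.expiry_tau)
            if record:
                pk = s0 + np.arange(int(np.ceil((s1 - s0) / period))) * period + t_insp
                peaks.extend(pk[pk < s1])
        env = np.ones(n)
        if p.periodic_depth > 0:
            env = (1.0 - p.periodic_depth) + p.periodic_depth * 0.5 * (
                1.0 + np.sin(2 * np.pi * (t - p.entry_s) / p.periodic_period_s)
            )
        resp = p.resp_amplitude * resp * env * in_bed
        # chest-wall motion is band-limited: smooth the piecewise contour's
        # corners (symmetric kernel, so peak timing is unshifted) so no
        # artificial broadband energy leaks into the BCG band
        resp = _smooth(resp, fs, 0.2)
        truth.resp_sources[p.label] = resp.copy()
        pk = np.asarray(sorted(peaks))
        truth.breath_peaks[p.label] = pk[(pk >= p.entry_s) & (pk < exit_s)]

        # --- BCG beat train -------------------------------------------------
        beat_iv = 60.0 / p.heart_rate
        nb = int(np.floor((exit_s - p.entry_s - _BCG_LEN_S) / beat_iv))
        bt = p.entry_s + beat_iv * (1 + np.arange(max(nb, 0)))
        amps = np.full(bt.size, p.bcg_amplitude)
        phase_in_cycle = np.mod(bt - p.entry_s, period)
        inspir = phase_in_cycle < t_insp
        if p.coupling_gain != 1.0:
            amps[inspir] *= p.coupling_gain
        phases = np.where(inspir, "inspiration", "expiration")

        if pi == 0 and len(ectopy_times):
            bt = bt.copy()
            for te in ectopy_times:
                i = int(np.argmin(np.abs(bt - te)))
                if i < 1 or i >= bt.size - 1:
                    continue
                pre_t = bt[i - 1]
                bt[i] = pre_t + 0.5 * beat_iv
                amps[i] *= 0.5
                amps[i + 1] *= post_ectopic_gain
                truth.ectopy_intervals.append((pre_t + 0.01, bt[i + 1] - 0.01))

        bcg = np.zeros(n)
        for bti, a in zip(bt, amps):
            i0 = int(round((bti) * fs))
            seg = kernel * a
            i1 = min(i0 + seg.size, n)
            if i0 < n:
                bcg[i0:i1] += seg[: i1 - i0]
        truth.beat_times[p.label] = bt
        truth.beat_amplitudes[p.label] = amps
        truth.beat_resp_phase[p.label] = phases

        static = p.weight * in_bed
        chan += np.outer(static + resp + bcg, proj)

    # --- movement artifacts: low-frequency bursts + load redistribution ----
    for (m0, mdur) in movement_intervals:
        i0, i1 = int(m0 * fs), min(int((m0 + mdur) * fs), n)
        if i1 <= i0:
            continue
        burst = rng.normal(0, movement_amplitude, size=(i1 - i0, n_ch))
        # crude low-pass: cumulative smoothing keeps energy below ~2 Hz
        w = max(int(0.25 * fs), 1)
        c = np.cumsum(burst, axis=0)
        burst = (c - np.vstack([np.zeros((w, n_ch)), c[:-w]])) / w
        chan[i0:i1] += burst
        truth.movement_intervals.append((m0, m0 + mdur))
        for pi, p in enumerate(persons):
            exit_s = duration_s if p.exit_s is None else p.exit_s
            if p.entry_s <= m0 < exit_s:
                proj = np.asarray(p.projection, dtype=float)[:n_ch]
                newp = proj * (1.0 + 0.3 * rng.uniform(-1, 1, size=n_ch))
                newp = np.clip(newp, 1e-3, None)
                newp /= newp.sum()
                delta = (newp - proj) * p.weight
                chan[i1:] += delta[None, :]

    if drift_per_hour != 0.0:
        slopes = drift_per_hour * rng.uniform(-1, 1, size=n_ch)
        chan += np.outer(t / 3600.0, slopes)

    chan = chan * sens[None, :]
    if noise_sd > 0:
        chan = chan + rng.normal(0.0, noise_sd, size=chan.shape)

    gains = sens[0] / sens
    truth.calibration = CalibrationModel(gains, affine_offset=0.0,
                                         affine_scale=1.0 / sens[0])
    truth.mixing_matrix = mixing * sens[:, None]
    truth.events.sort(key=lambda e: e[0])
    frame = SensorFrame(t, chan, units=RAW_AU, nominal_rate=fs)
    return frame, truth


def simulate_aliquot_test(
    base_load: float = 10.0,
    aliquot_lbs: float = 15.0 * KG_PER_ML_WATER * LBS_PER_KG,
    n_aliquots: int = 5,
    interval_s: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = 80.0,
    lead_s: float = 20.0,
):
    """Sensitivity-limit staircase: small equal load steps at fixed intervals.

    Default step is 15 mL of water (~0.033 lbs). Truth records each step
    time and size.
    """
    if aliquot_lbs <= 0:
        raise SimulationError("aliquot_lbs must be > 0")
    rng = np.random.default_rng(seed)
    duration = lead_s + n_aliquots * interval_s + lead_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    total = np.full(n, base_load)
    truth = SessionTruth(duration_s=duration, fs=fs, tare_lbs=base_load)
    for k in range(n_aliquots):
        tk = lead_s + k * interval_s
        total[t >= tk] += aliquot_lbs
        truth.steps.append((tk, aliquot_lbs))
    chan = np.outer(total, np.full(4, 0.25))
    if noise_sd > 0:
        chan = chan + rng.normal(0.0, noise_sd, size=chan.shape)
    truth.calibration = CalibrationModel(np.ones(4))
    return SensorFrame(t, chan, units=RAW_AU, nominal_rate=fs), truth


def simulate_simultaneity(p1: PersonSpec, p2: PersonSpec, interval_s: float,
                          seed: int = 0, fs: float = 80.0, lead_s: float = 30.0,
                          noise_sd: float = 0.05, **session_kwargs):
    """Two-person entry/exit protocol at a fixed event spacing.

    Event sequence: P1 in, P2 in, P1 out, P2 out, then repeated with the
    order of the two persons exchanged — 8 step events ``interval_s`` apart.
    """
    if interval_s <= 0:
        raise SimulationError("interval_s must be > 0")
    I = float(interval_s)
    t0 = lead_s
    duration = 2 * lead_s + 7 * I

    def mk(p, entry, exit, tag):
        q = PersonSpec(**{**p.__dict__})
        q.entry_s, q.exit_s, q.label = entry, exit, p.label
        return q

    specs = [
        mk(p1, t0 + 0 * I, t0 + 2 * I, "a"),
        mk(p2, t0 + 1 * I, t0 + 3 * I, "a"),
        mk(p2, t0 + 4 * I, t0 + 6 * I, "b"),
        mk(p1, t0 + 5 * I, t0 + 7 * I, "b"),
    ]
    frame, truth = simulate_session(
        specs, duration_s=duration, seed=seed, fs=fs, noise_sd=noise_sd,
        **session_kwargs,
    )
    truth.person_weights = {p1.label: p1.weight, p2.label: p2.weight}
    return frame, truth
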