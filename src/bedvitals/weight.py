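"""Continuous total-weight estimation, step events, occupancy and daily weights.

Total body weight is the calibrated sum of the four leg sensors; persons and
objects are told apart by the *times* at which load steps occur, so weighing
needs no adherence from the patient. Step events are extracted from the total
signal as differences between robust pre/post plateaus, attributed to up to
two persons by clustering step magnitudes, and aggregated into daily weights
on a noon-to-noon day grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .core import CalibrationModel, SensorFrame

__all__ = [
    "WeightEvent",
    "OccupancyInterval",
    "total_weight",
    "detect_weight_events",
    "attribute_persons",
    "occupancy",
    "daily_weight",
    "AmbiguityError",
]

#: |delta| below this is labeled an object/pet, not a person.
OBJECT_GATE_LBS = 30.0


class AmbiguityError(ValueError):
    """Step magnitudes do not split cleanly into <= 2 person groups."""


@dataclass(frozen=True)
class WeightEvent:
    time_s: float
    delta_lbs: float
    pre_plateau_lbs: float
    post_plateau_lbs: float
    person_label: str = "unassigned"


@dataclass(frozen=True)
class OccupancyInterval:
    start_s: float
    end_s: float
    person_label: str = "unassigned"
    weight_lbs: float = float("nan")


def total_weight(frame: SensorFrame, cal: CalibrationModel | None = None) -> np.ndarray:
    """Pointwise gain-weighted channel sum mapped through the AU->lbs model."""
    if frame.units == "lbs":
        return frame.channels.sum(axis=1)
    if cal is None:
        raise ValueError("raw-AU frame requires a CalibrationModel")
    if cal.channel_gains.size != frame.n_channels:
        raise ValueError(
            f"calibration has {cal.channel_gains.size} gains, frame has "
            f"{frame.n_channels} channels"
        )
    total_au = frame.channels @ cal.channel_gains
    return cal.au_to_lbs(total_au)


def detect_weight_events(
    total,
    fs: float,
    min_step_lbs: float = 5.0,
    settle_s: float = 3.0,
    guard_s: float = 0.5,
    t0: float = 0.0,
):
    """Extract large differential weight changes from the total-load signal.

    A candidate transition is where the 1-s-spanning difference of a rolling
    median exceeds ``min_step_lbs``; each event's delta is the median of the
    post-settle plateau minus the median of the pre-settle plateau, with the
    transition itself (``guard_s`` on each side) excluded from both plateaus.
    Plateaus are clipped against neighbouring events so closely spaced steps
    (down to ~2 x guard_s apart) stay separable.
    """
    if min_step_lbs <= 0:
        raise ValueError("min_step_lbs must be > 0")
    x = np.asarray(total, dtype=float)
    n = x.size
    med_w = max(int(round(0.5 * fs)), 1)
    m = pd.Series(x).rolling(med_w, center=True, min_periods=1).median().to_numpy()
    k = max(int(round(0.5 * fs)), 1)  # 1-s-span difference
    d = np.zeros(n)
    d[k:-k] = m[2 * k:] - m[:-2 * k]
    cand = np.abs(d) >= min_step_lbs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], cand.view(np.int8), [0]))))
    centers = []
    for i0, i1 in zip(edges[::2], edges[1::2]):
        centers.append(i0 + int(np.argmax(np.abs(d[i0:i1]))))
    events = []
    g = int(round(guard_s * fs))
    s = int(round(settle_s * fs))
    for ci, c in enumerate(centers):
        lo_lim = centers[ci - 1] + g if ci > 0 else 0
        hi_lim = centers[ci + 1] - g if ci < len(centers) - 1 else n
        pre_lo = max(c - g - s, lo_lim, 0)
        pre_hi = max(c - g, pre_lo + 1)
        post_lo = min(c + g, n - 1)
        post_hi = min(c + g + s, hi_lim)
        post_hi = max(post_hi, post_lo + 1)
        pre = float(np.median(x[pre_lo:pre_hi]))
        post = float(np.median(x[post_lo:post_hi]))
        delta = post - pre
        if abs(delta) >= min_step_lbs:
            events.append(WeightEvent(
                time_s=t0 + c / fs, delta_lbs=delta,
                pre_plateau_lbs=pre, post_plateau_lbs=post,
            ))
    return events


def _split_sse(mags):
    """Best 2-cluster split of sorted 1-D data; returns (sse, split_index)."""
    m = np.sort(mags)
    best = (np.inf, 0)
    for i in range(1, m.size):
        sse = (np.sum((m[:i] - m[:i].mean()) ** 2)
               + np.sum((m[i:] - m[i:].mean()) ** 2))
        if sse < best[0]:
            best = (sse, i)
    return best


def attribute_persons(events, object_gate_lbs: float = OBJECT_GATE_LBS,
                      min_gap_lbs: float = 2.0):
    """Cluster person-scale step magnitudes into <= 2 groups.

    Steps below ``object_gate_lbs`` are labeled objects and excluded. Returns
    ``{label: (weight_mean, weight_sd, n_events)}`` with labels P1/P2 in
    order of first appearance; result is order-independent up to label swap.
    Raises :class:`AmbiguityError` if a third well-separated group is present.
    """
    person_events = [e for e in events if abs(e.delta_lbs) >= object_gate_lbs]
    if not person_events:
        return {}
    mags = np.array([abs(e.delta_lbs) for e in person_events])
    if mags.size == 1 or np.ptp(mags) < min_gap_lbs:
        return {"P1": (float(mags.mean()), float(mags.std()), int(mags.size))}
    sse2, split = _split_sse(mags)
    m_sorted = np.sort(mags)
    # three well-separated groups -> ambiguity, before any 2-group decision
    if mags.size >= 3:
        best3 = (np.inf, 0, 0)
        for i in range(1, mags.size - 1):
            for j in range(i + 1, mags.size):
                parts = (m_sorted[:i], m_sorted[i:j], m_sorted[j:])
                sse = sum(np.sum((p - p.mean()) ** 2) for p in parts)
                if sse < best3[0]:
                    best3 = (sse, i, j)
        _, i, j = best3
        parts = (m_sorted[:i], m_sorted[i:j], m_sorted[j:])
        gaps = (parts[1].min() - parts[0].max(), parts[2].min() - parts[1].max())
        spreads = [max(p.std(), 0.25) for p in parts]
        if all(g > max(min_gap_lbs, 3 * max(spreads)) for g in gaps):
            raise AmbiguityError(
                f"more than two plausible weight groups; magnitudes: "
                f"{m_sorted.round(2).tolist()}"
            )
    lo, hi = m_sorted[:split], m_sorted[split:]
    gap = hi.min() - lo.max()
    spread = max(lo.std(), hi.std(), 0.25)
    if gap < max(min_gap_lbs, 3 * spread):
        return {"P1": (float(mags.mean()), float(mags.std()), int(mags.size))}
    thresh = (lo.max() + hi.min()) / 2.0
    first_is_low = abs(person_events[0].delta_lbs) <= thresh
    out = {}
    for name, grp in (("P1", lo if first_is_low else hi),
                      ("P2", hi if first_is_low else lo)):
        out[name] = (float(grp.mean()), float(grp.std()), int(grp.size))
    return out


def occupancy(
    total,
    fs: float,
    empty_bed_lbs: float,
    person_threshold_lbs: float = 50.0,
    hysteresis_lbs: float = 5.0,
    epoch_s: float = 30.0,
    t0: float = 0.0,
):
    """In-bed intervals and a per-epoch binary series from the total signal.

    In-bed is entered when net load rises to >= the person threshold and left
    when it falls below threshold - hysteresis.
    """
    net = np.asarray(total, dtype=float) - empty_bed_lbs
    n = net.size
    state = net[0] >= person_threshold_lbs
    intervals = []
    start = 0 if state else None
    for i in range(1, n):
        if not state and net[i] >= person_threshold_lbs:
            state, start = True, i
        elif state and net[i] < person_threshold_lbs - hysteresis_lbs:
            intervals.append(OccupancyInterval(t0 + start / fs, t0 + i / fs))
            state = False
    if state:
        intervals.append(OccupancyInterval(t0 + start / fs, t0 + n / fs))
    n_epochs = int(np.ceil(n / fs / epoch_s))
    binary = np.zeros(n_epochs, dtype=bool)
    in_bed = net >= (person_threshold_lbs - hysteresis_lbs / 2)
    for e in range(n_epochs):
        i0, i1 = int(e * epoch_s * fs), min(int((e + 1) * epoch_s * fs), n)
        binary[e] = np.mean(in_bed[i0:i1]) >= 0.5
    return intervals, binary


def pct_time_in_bed(binary_epochs, epoch_s: float = 30.0) -> float:
    """Percent of epochs classified in-bed (%TIB)."""
    b = np.asarray(binary_epochs, dtype=bool)
    if b.size == 0:
        return float("nan")
    return 100.0 * float(np.mean(b))


def daily_weight(events, session_start: datetime | None = None):
    """Per-day weight: median of person-scale |entry|/|exit| magnitudes.

    Days run noon-to-noon; an event at time_s belongs to the day containing
    ``session_start + time_s - 12 h``. With no wall clock, day 0 starts at
    session time 0. Days without events are absent, never zero.
    """
    person_events = [e for e in events if abs(e.delta_lbs) >= OBJECT_GATE_LBS]
    if not person_events:
        return {}
    out: dict = {}
    for e in person_events:
        if session_start is None:
            day = int(e.time_s // 86400.0)
        else:
            wall = session_start + timedelta(seconds=e.time_s)
            day = (wall - timedelta(hours=12)).date()
        out.setdefault(day, []).append(abs(e.delta_lbs))
    return {day: (float(np.median(v)), len(v)) for day, v in sorted(out.items())}
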