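"""Session-to-months aggregation: plausibility filters, daily summaries, heatmaps.

Rate epochs (one per 30 s) are kept only when physiologically plausible —
strictly 6 < bpm < 40 for respiratory rate and 60 < bpm < 120 for heart
rate — then summarized per noon-to-noon day and exported as time-of-day x
day heatmap matrices (2880 30-s slots per day), with cells below a display
floor emitted as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .respiration import RateEpoch
from .weight import pct_time_in_bed

logger = logging.getLogger(__name__)

__all__ = [
    "DailySummary",
    "PLAUSIBLE_BPM",
    "plausibility_filter",
    "daily_summary",
    "heatmap_export",
]

#: Strict physiologic plausibility bounds per epoch kind (exclusive).
PLAUSIBLE_BPM = {"rr": (6.0, 40.0), "hr": (60.0, 120.0)}

SLOTS_PER_DAY = 2880  # 30 s slots in 24 h
EPOCH_S = 30.0


@dataclass(frozen=True)
class DailySummary:
    date: object
    mean_rr_bpm: float
    sd_rr_bpm: float
    mean_hr_bpm: float
    sd_hr_bpm: float
    weight_lbs: float
    pct_time_in_bed: float
    n_valid_rr_epochs: int
    n_valid_hr_epochs: int


def plausibility_filter(epochs, kind: str):
    """Keep epochs with strictly in-bounds rates (6-40 rr, 60-120 hr).

    Bounds are exclusive as printed: an epoch at exactly 60 bpm is excluded
    from the heart-rate average. Filter counts are logged.
    """
    lo, hi = PLAUSIBLE_BPM[kind]
    kept = [e for e in epochs
            if e.valid and np.isfinite(e.rate_bpm) and lo < e.rate_bpm < hi]
    logger.info("plausibility_filter(%s): kept %d of %d epochs",
                kind, len(kept), len(list(epochs)))
    return kept


def _day_of(epoch_start_s: float, session_start: datetime | None):
    """Noon-to-noon day bucket of an epoch."""
    if session_start is None:
        return int(epoch_start_s // 86400.0)
    wall = session_start + timedelta(seconds=epoch_start_s)
    return (wall - timedelta(hours=12)).date()


def daily_summary(rr_epochs, hr_epochs, occupancy_epochs=None,
                  daily_weights=None, session_start: datetime | None = None):
    """Per-day means/sds over plausibility-filtered epochs plus %TIB and weight.

    Days with zero valid epochs report NaN for the affected means — absent,
    never zero.
    """
    rr = plausibility_filter(rr_epochs, "rr")
    hr = plausibility_filter(hr_epochs, "hr")
    days = sorted(
        {_day_of(e.epoch_start_s, session_start) for e in list(rr_epochs) + list(hr_epochs)}
    )
    daily_weights = daily_weights or {}
    out = []
    for day in days:
        rr_d = [e.rate_bpm for e in rr if _day_of(e.epoch_start_s, session_start) == day]
        hr_d = [e.rate_bpm for e in hr if _day_of(e.epoch_start_s, session_start) == day]
        if occupancy_epochs is not None:
            occ_d = [o for e, o in occupancy_epochs
                     if _day_of(e, session_start) == day]
            tib = pct_time_in_bed(occ_d) if occ_d else float("nan")
        else:
            tib = float("nan")
        w = daily_weights.get(day, (float("nan"), 0))[0]
        out.append(DailySummary(
            date=day,
            mean_rr_bpm=float(np.mean(rr_d)) if rr_d else float("nan"),
            sd_rr_bpm=float(np.std(rr_d)) if rr_d else float("nan"),
            mean_hr_bpm=float(np.mean(hr_d)) if hr_d else float("nan"),
            sd_hr_bpm=float(np.std(hr_d)) if hr_d else float("nan"),
            weight_lbs=w,
            pct_time_in_bed=tib,
            n_valid_rr_epochs=len(rr_d),
            n_valid_hr_epochs=len(hr_d),
        ))
    return out


def heatmap_export(epochs, value_floor: float,
                   session_start: datetime | None = None,
                   path=None):
    """Time-of-day x day matrix of epoch rates (2880 30-s slots per day).

    The day axis runs noon-to-noon; cells below ``value_floor`` — and slots
    without an epoch — are missing (NaN). Optionally written as CSV with a
    time-of-day slot column and one ISO-dated column per day.
    """
    epochs = list(epochs)
    rows = []
    for e in epochs:
        day = _day_of(e.epoch_start_s, session_start)
        if session_start is None:
            sec_in_day = e.epoch_start_s % 86400.0
        else:
            wall = session_start + timedelta(seconds=e.epoch_start_s)
            noon = datetime.combine((wall - timedelta(hours=12)).date(),
                                    datetime.min.time()) + timedelta(hours=12)
            sec_in_day = (wall - noon).total_seconds()
        slot = int(sec_in_day // EPOCH_S) % SLOTS_PER_DAY
        val = e.rate_bpm if (e.valid and np.isfinite(e.rate_bpm)
                             and e.rate_bpm >= value_floor) else np.nan
        rows.append((slot, day, val))
    days = sorted({d for _, d, _ in rows})
    mat = np.full((SLOTS_PER_DAY, len(days)), np.nan)
    col = {d: j for j, d in enumerate(days)}
    for slot, day, val in rows:
        mat[slot, col[day]] = val
    df = pd.DataFrame(mat, columns=[str(d) for d in days])
    df.insert(0, "slot", np.arange(SLOTS_PER_DAY))
    if path is not None:
        df.to_csv(path, index=False)
    return mat, df
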