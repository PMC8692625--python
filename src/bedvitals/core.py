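"""Core data model, I/O, calibration and shared signal utilities.

Everything downstream (weight monitoring, respiration, ballistocardiography,
source separation) operates on :class:`SensorFrame` objects — timestamped
multi-channel force recordings from load cells under the bed legs — and uses
the filtering / moving-statistics / steady-region primitives defined here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

RAW_AU = "raw_AU"
LBS = "lbs"

__all__ = [
    "SensorFrame",
    "CalibrationModel",
    "SteadyRegion",
    "read_frame",
    "write_frame",
    "fit_joint_calibration",
    "two_point_calibrate",
    "bandpass",
    "moving_stat",
    "steady_regions",
    "adaptive_steady_threshold",
    "resample_uniform",
    "FormatError",
    "ParseError",
    "CalibrationError",
]


class FormatError(ValueError):
    """File lacks a required column/dataset or violates a frame invariant."""


class ParseError(ValueError):
    """A cell could not be converted to a number."""


class CalibrationError(ValueError):
    """Calibration inputs are insufficient or degenerate."""


@dataclass(frozen=True)
class SensorFrame:
    """A timestamped multi-channel force recording.

    Parameters
    ----------
    timestamps
        Seconds since session start, strictly increasing.
    channels
        (n_samples, n_channels) force readings, arbitrary digitizer units
        or lbs depending on ``units``.
    units
        ``"raw_AU"`` or ``"lbs"``.
    nominal_rate
        Nominal sampling rate in Hz (canonically ~80).
    """

    timestamps: np.ndarray
    channels: np.ndarray
    units: str = RAW_AU
    nominal_rate: float = 80.0

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim == 1:
            ch = ch[:, None]
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "channels", ch)
        if ch.shape[0] != t.shape[0]:
            raise FormatError(
                f"channels length {ch.shape[0]} != timestamps length {t.shape[0]}"
            )
        if ch.shape[1] < 1:
            raise FormatError("at least one channel required")
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise FormatError(
                f"timestamps not strictly increasing at index {bad[0] + 1}"
            )
        if not (60.0 <= self.nominal_rate <= 100.0):
            raise FormatError(
                f"nominal_rate {self.nominal_rate} Hz outside [60, 100] Hz"
            )
        if t.size > 1:
            med_dt = float(np.median(dt))
            if abs(med_dt - 1.0 / self.nominal_rate) > 0.2 / self.nominal_rate:
                raise FormatError(
                    f"median sample interval {med_dt:.4f} s inconsistent with "
                    f"nominal rate {self.nominal_rate} Hz"
                )
        if self.units not in (RAW_AU, LBS):
            raise FormatError(f"unknown units flag {self.units!r}")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    @property
    def fs(self) -> float:
        return self.nominal_rate

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass(frozen=True)
class CalibrationModel:
    """Per-channel gains plus the affine AU -> lbs map.

    ``total_lbs = (sum_j gains[j] * channel_j - affine_offset) * affine_scale``.
    The reference channel's gain is fixed to 1 during joint fitting (the
    overall scale is a gauge freedom absorbed by the affine map).
    """

    channel_gains: np.ndarray
    affine_offset: float = 0.0
    affine_scale: float = 1.0

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.channel_gains, dtype=float))
        object.__setattr__(self, "channel_gains", g)
        if np.any(g <= 0):
            raise CalibrationError("all channel gains must be > 0")
        if self.affine_scale <= 0:
            raise CalibrationError("affine_scale must be > 0")

    def au_to_lbs(self, total_au):
        """Map a gain-weighted total in AU to lbs."""
        return (np.asarray(total_au, dtype=float) - self.affine_offset) * self.affine_scale

    def calibrate_channels(self, frame: SensorFrame) -> SensorFrame:
        """Return a per-channel lbs-unit frame (tare offset left on the sum)."""
        if frame.units == LBS:
            return frame
        if frame.n_channels != self.channel_gains.size:
            raise CalibrationError(
                f"frame has {frame.n_channels} channels, calibration expects "
                f"{self.channel_gains.size}"
            )
        ch = frame.channels * self.channel_gains[None, :] * self.affine_scale
        return replace(frame, channels=ch, units=LBS)


@dataclass(frozen=True)
class SteadyRegion:
    """A movement-free stretch of a derived signal."""

    start_s: float
    end_s: float
    mean_variance: float
    channel_scope: str = "composite"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.start_s) & (t <= self.end_s)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_frame(path, format: str | None = None) -> SensorFrame:
    """Read a SensorFrame from CSV (``t,ch0,ch1,...``) or HDF5.

    Non-monotonic timestamps are rejected, never silently sorted.
    """
    path = str(path)
    if format is None:
        format = "hdf5" if path.endswith((".h5", ".hdf5")) else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        if "t" not in df.columns:
            raise FormatError(f"{path}: missing required time column 't'")
        ch_cols = [c for c in df.columns if c != "t"]
        if not ch_cols:
            raise FormatError(f"{path}: no channel columns found")
        tcol = df["t"]
        if tcol.dtype == object:
            try:
                t = pd.to_numeric(tcol).to_numpy(dtype=float)
            except (ValueError, TypeError):
                ts = pd.to_datetime(tcol, format="ISO8601")
                t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
        else:
            t = tcol.to_numpy(dtype=float)
        ch = np.empty((len(df), len(ch_cols)))
        for j, c in enumerate(ch_cols):
            col = pd.to_numeric(df[c], errors="coerce")
            bad = np.nonzero(col.isna().to_numpy() & df[c].notna().to_numpy())[0]
            if df[c].isna().any() or bad.size:
                idx = bad[0] if bad.size else int(np.nonzero(df[c].isna().to_numpy())[0][0])
                raise ParseError(f"{path}: non-numeric cell in column {c!r} at row {idx}")
            ch[:, j] = col.to_numpy(dtype=float)
        units = LBS if path.endswith(".lbs.csv") else RAW_AU
        rate = _infer_rate(t)
        return SensorFrame(t, ch, units=units, nominal_rate=rate)
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            if "timestamps" not in f or "channels" not in f:
                raise FormatError(f"{path}: missing /timestamps or /channels dataset")
            t = f["timestamps"][:]
            ch = f["channels"][:]
            units = f.attrs.get("units_flag", RAW_AU)
            if isinstance(units, bytes):
                units = units.decode()
            rate = float(f.attrs.get("nominal_rate", _infer_rate(t)))
        return SensorFrame(t, ch, units=str(units), nominal_rate=rate)
    raise FormatError(f"unknown format {format!r}")


def _infer_rate(t) -> float:
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        return 80.0
    return float(np.clip(round(1.0 / np.median(np.diff(t))), 60, 100))


def write_frame(frame: SensorFrame, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "hdf5" if path.endswith((".h5", ".hdf5")) else "csv"
    if format == "csv":
        cols = {"t": frame.timestamps}
        for j in range(frame.n_channels):
            cols[f"ch{j}"] = frame.channels[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("timestamps", data=frame.timestamps)
            f.create_dataset("channels", data=frame.channels)
            f.attrs["units_flag"] = frame.units
            f.attrs["nominal_rate"] = frame.nominal_rate
    else:
        raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def fit_joint_calibration(
    frames,
    known_load: float | None = None,
    reference_channel: int = 0,
) -> CalibrationModel:
    """Fit per-channel gains from one load placed at several bed positions.

    The gains minimize, in the least-squares sense, the across-placement
    variance of the gain-weighted channel sum, with the reference channel's
    gain fixed to 1 (the overall scale is unidentifiable and is absorbed by
    the affine AU->lbs map). If ``known_load`` is given the affine scale is
    set so the mean weighted total maps to that load.
    """
    if len(frames) < 2:
        raise CalibrationError("joint calibration needs >= 2 placements")
    M = np.vstack([np.mean(np.asarray(f.channels, dtype=float), axis=0) for f in frames])
    n_place, n_ch = M.shape
    if not (0 <= reference_channel < n_ch):
        raise CalibrationError("reference channel out of range")
    Mc = M - M.mean(axis=0, keepdims=True)
    free = [j for j in range(n_ch) if j != reference_channel]
    for j in free:
        if np.linalg.norm(Mc[:, j]) < 1e-12 * max(1.0, np.abs(M[:, j]).max()):
            raise CalibrationError(
                f"channel {j} constant across placements: degenerate design"
            )
    A = Mc[:, free]
    b = -Mc[:, reference_channel]
    g_free, *_ = np.linalg.lstsq(A, b, rcond=None)
    gains = np.ones(n_ch)
    gains[free] = g_free
    if np.any(gains <= 0):
        raise CalibrationError(f"fitted gains not all positive: {gains}")
    offset, scale = 0.0, 1.0
    if known_load is not None:
        mean_total = float(np.mean(M @ gains))
        if mean_total <= 0:
            raise CalibrationError("non-positive mean total; cannot scale to load")
        scale = known_load / mean_total
    return CalibrationModel(gains, affine_offset=offset, affine_scale=scale)


def two_point_calibrate(reading_zero: float, reading_ref: float, ref_load: float,
                        n_channels: int = 4) -> CalibrationModel:
    """Affine AU -> lbs map anchored at an empty reading and a known load."""
    if reading_ref == reading_zero:
        raise CalibrationError("two-point calibration readings are equal")
    if ref_load <= 0:
        raise CalibrationError("reference load must be > 0")
    scale = ref_load / (reading_ref - reading_zero)
    if scale <= 0:
        raise CalibrationError("reference reading below zero reading")
    return CalibrationModel(np.ones(n_channels), affine_offset=reading_zero,
                            affine_scale=scale)


# ---------------------------------------------------------------------------
# Signal utilities
# ---------------------------------------------------------------------------

def bandpass(x, fs: float, low_hz: float, high_hz: float, order: int = 4):
    """Zero-phase Butterworth bandpass along axis 0.

    Applied forward-backward (sosfiltfilt) so peak timing is preserved.
    ``high_hz`` is clipped to 0.99 x Nyquist with a logged warning when it
    exceeds Nyquist (e.g. a 50 Hz cutoff at 80 Hz sampling).
    """
    if low_hz <= 0 or high_hz <= low_hz:
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) Hz")
    nyq = fs / 2.0
    if high_hz >= nyq:
        clipped = 0.99 * nyq
        logger.warning("high cutoff %.3g Hz >= Nyquist %.3g Hz; clipping to %.3g Hz",
                       high_hz, nyq, clipped)
        high_hz = clipped
        if high_hz <= low_hz:
            raise ValueError("band collapsed after Nyquist clipping")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    return sps.sosfiltfilt(sos, x, axis=0)


def moving_stat(x, fs: float, window_s: float, stat: str = "mean"):
    """Centered moving mean or variance; edges use shrunken windows.

    Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    w = int(round(window_s * fs)) | 1  # odd length for a truly centered window
    if w <= 2:
        raise ValueError(f"window {window_s} s is <= 2 sample intervals at {fs} Hz")
    if w > n:
        raise ValueError(f"window {window_s} s longer than signal ({n / fs:.3g} s)")
    if stat not in ("mean", "variance"):
        raise ValueError(f"unknown stat {stat!r}")

    def _one(col):
        r = pd.Series(col).rolling(w, center=True, min_periods=1)
        out = (r.mean() if stat == "mean" else r.var(ddof=1)).to_numpy()
        if stat == "variance":
            out = np.nan_to_num(out, nan=0.0)
        return out

    if x.ndim == 1:
        return _one(x)
    return np.column_stack([_one(x[:, j]) for j in range(x.shape[1])])


def adaptive_steady_threshold(variance_series, factor: float = 4.0) -> float:
    """Default steady-region threshold: factor x the 10th variance percentile."""
    v = np.asarray(variance_series, dtype=float)
    return float(factor * np.percentile(v[np.isfinite(v)], 10))


def steady_regions(variance_series, fs: float, threshold: float,
                   min_duration_s: float, t0: float = 0.0,
                   channel_scope: str = "composite"):
    """Maximal runs of variance <= threshold lasting >= min_duration_s.

    Regions are disjoint and time-ordered; runs shorter than the minimum
    duration are rejected.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = np.asarray(variance_series, dtype=float)
    quiet = v <= threshold
    regions = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], quiet.view(np.int8), [0]))))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        dur = (i1 - i0) / fs
        if dur >= min_duration_s:
            regions.append(SteadyRegion(
                start_s=t0 + i0 / fs,
                end_s=t0 + i0 / fs + dur,
                mean_variance=float(np.mean(v[i0:i1])),
                channel_scope=channel_scope,
            ))
    return regions


def resample_uniform(frame: SensorFrame) -> SensorFrame:
    """Linear-interpolate onto a uniform grid at the nominal rate.

    Filtering assumes uniform sampling; recordings with timestamp jitter are
    put on a regular grid first.
    """
    t = frame.timestamps
    dt = np.diff(t)
    if t.size > 1 and np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        return frame
    step = 1.0 / frame.nominal_rate
    tg = np.arange(t[0], t[-1] + step / 2, step)
    ch = np.column_stack([
        np.interp(tg, t, frame.channels[:, j]) for j in range(frame.n_channels)
    ])
    return SensorFrame(tg, ch, units=frame.units, nominal_rate=frame.nominal_rate)
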