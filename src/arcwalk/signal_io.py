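"""Reading, resampling, and gravity-aligning raw tri-axial accelerometry.

Recordings come from a lower-back (L5) worn tri-axial accelerometer
(nominally 100 Hz, +/-8 g) stored as delimited long-format text with a
``time,x,y,z`` header.  Before any gait processing the signal is rotated
into a horizontal-vertical coordinate system in which an upright, static
wearer reads -1 g on the vertical axis; gravity direction is tracked with a
slow low-pass filter so the rotation follows posture, not steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as a recording."""


@dataclass
class AccelRecording:
    """Uniformly or non-uniformly sampled tri-axial acceleration.

    Attributes
    ----------
    t : np.ndarray
        Seconds since recording start, strictly increasing.
    ax, ay, az : np.ndarray
        Acceleration per device axis, in g.
    fs : float
        Nominal sampling rate in Hz.
    start_datetime : datetime | None
        Wall-clock anchor used for calendar-day bucketing.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    start_datetime: datetime | None = None
    range_g: float = 8.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.t.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise ValueError("time and axis arrays must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            k = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise FormatError(f"time not strictly increasing at row {k}")
        for name in ("ax", "ay", "az"):
            a = getattr(self, name)
            if a.size and np.nanmax(np.abs(a)) > self.range_g + 1e-9:
                raise FormatError(
                    f"{name} exceeds device range of +/-{self.range_g} g"
                )

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def xyz(self) -> np.ndarray:
        """Samples as an (n, 3) array."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class OrientedRecording:
    """Acceleration in the horizontal-vertical frame (upright static v = -1 g)."""

    t: np.ndarray
    v: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    fs: float
    start_datetime: datetime | None = None

    magnitude: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.magnitude = np.sqrt(self.v**2 + self.h1**2 + self.h2**2)

    def __len__(self) -> int:
        return self.t.size


def read_recording(
    path: str,
    fs: float = 100.0,
    range_g: float = 8.0,
) -> AccelRecording:
    """Read a delimited long-format recording (header ``time,x,y,z``).

    The time column may be seconds since start (numeric) or ISO-8601
    timestamps; timestamps are converted to seconds and the first one kept
    as the calendar anchor.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = ["time", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    start_dt: datetime | None = None
    tcol = df["time"]
    if pd.api.types.is_numeric_dtype(tcol):
        t = tcol.to_numpy(dtype=float)
    else:
        try:
            stamps = pd.to_datetime(tcol, format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: time column is neither numeric nor ISO-8601") from exc
        start_dt = stamps.iloc[0].to_pydatetime()
        t = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy()

    axes = []
    for c in ("x", "y", "z"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.index[vals.isna() & df[c].notna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric value in column {c} at row {bad[0] + 2}")
        if vals.isna().any():
            raise FormatError(f"{path}: missing value in column {c}")
        axes.append(vals.to_numpy(dtype=float))

    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            k = int(np.argmax(dt <= 0)) + 1
            raise FormatError(f"{path}: timestamp regression at row {k + 1}")
    return AccelRecording(t, *axes, fs=fs, start_datetime=start_dt, range_g=range_g)


def write_recording(rec: AccelRecording, path: str, float_format: str = "%.6f") -> None:
    """Write a recording in the long delimited format `read_recording` accepts."""
    pd.DataFrame({"time": rec.t, "x": rec.ax, "y": rec.ay, "z": rec.az}).to_csv(
        path, index=False, float_format=float_format
    )


def resample_uniform(
    rec: AccelRecording,
    fs_target: float,
    max_gap_s: float = 1.0,
) -> tuple[AccelRecording, list[tuple[float, float]]]:
    """Resample onto a uniform grid by linear interpolation.

    Sampling gaps longer than ``max_gap_s`` are treated as non-wear: they are
    returned as (start_s, end_s) intervals and no samples are fabricated
    inside them (grid samples falling in a gap are dropped, so the output time
    axis remains strictly increasing but may itself contain gaps).
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    if len(rec) < 2:
        raise ValueError("need at least 2 samples to resample")

    dt = np.diff(rec.t)
    gap_idx = np.nonzero(dt > max_gap_s)[0]
    gaps = [(float(rec.t[i]), float(rec.t[i + 1])) for i in gap_idx]

    grid = rec.t[0] + np.arange(int(np.floor((rec.t[-1] - rec.t[0]) * fs_target)) + 1) / fs_target
    keep = np.ones(grid.size, dtype=bool)
    for g0, g1 in gaps:
        keep &= ~((grid > g0) & (grid < g1))
    grid = grid[keep]

    axes = [np.interp(grid, rec.t, a) for a in (rec.ax, rec.ay, rec.az)]
    out = AccelRecording(
        grid, *axes, fs=fs_target, start_datetime=rec.start_datetime, range_g=rec.range_g
    )
    return out, gaps


def detect_nonwear(
    rec: AccelRecording,
    gap_s: float = 1.0,
    still_window_min: float = 30.0,
    still_sd_g: float = 0.005,
) -> list[tuple[float, float]]:
    """Non-wear intervals: sampling gaps > ``gap_s`` plus long motionless windows.

    A window of ``still_window_min`` minutes with per-axis SD below
    ``still_sd_g`` on all three axes is flagged (a worn device always shows
    breathing/posture micro-movement above this level).
    """
    intervals: list[tuple[float, float]] = []
    dt = np.diff(rec.t)
    for i in np.nonzero(dt > gap_s)[0]:
        intervals.append((float(rec.t[i]), float(rec.t[i + 1])))

    win = int(round(still_window_min * 60 * rec.fs))
    if win >= 2 and len(rec) >= win:
        xyz = rec.xyz()
        step = max(1, win // 2)
        still_start = None
        last_end = None
        for s in range(0, len(rec) - win + 1, step):
            seg = xyz[s : s + win]
            if np.all(seg.std(axis=0) < still_sd_g):
                t0, t1 = float(rec.t[s]), float(rec.t[s + win - 1])
                if still_start is None:
                    still_start, last_end = t0, t1
                elif t0 <= last_end:
                    last_end = t1
                else:
                    intervals.append((still_start, last_end))
                    still_start, last_end = t0, t1
        if still_start is not None:
            intervals.append((still_start, last_end))
    return sorted(intervals)


def write_nonwear_bed(
    intervals: list[tuple[float, float]], recording_id: str, path: str
) -> None:
    """Write non-wear intervals as a BED-like 3-column file (id, start_s, end_s)."""
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{recording_id}\t{s:.3f}\t{e:.3f}\n")


def _orthonormal_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pair of unit vectors orthogonal to unit vector ``u``."""
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(u)))] = 1.0
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def orient_to_vertical(
    rec: AccelRecording,
    window_s: float = 10.0,
    lowpass_hz: float = 0.25,
) -> OrientedRecording:
    """Rotate device axes into the horizontal-vertical frame.

    Gravity direction is estimated per sample from the low-pass filtered
    (default 0.25 Hz, 2nd-order zero-phase Butterworth) acceleration vector;
    this tracks slow posture changes at roughly the ``window_s`` timescale
    while steps average out.  The vertical channel is defined so that the
    static upright wearer reads -1 g; the two horizontal channels span the
    orthogonal complement.  Vector magnitude is preserved exactly per sample.

    Windows where the low-pass vector magnitude is near zero (free-fall
    artifact) cannot define a gravity direction; there the most recent valid
    direction is carried forward.
    """
    if rec.duration_s < window_s:
        raise ValueError(f"recording shorter than orientation window ({window_s} s)")
    xyz = rec.xyz()
    nyq = rec.fs / 2
    if lowpass_hz >= nyq:
        raise ValueError("gravity low-pass cutoff must be below Nyquist")
    b, a = butter(2, lowpass_hz / nyq, btype="low")
    grav = filtfilt(b, a, xyz, axis=0)

    norm = np.linalg.norm(grav, axis=1)
    ok = norm > 0.3  # free-fall / artifact guard, g
    if not ok.any():
        raise ValueError("no valid gravity estimate (signal magnitude near zero)")
    # carry last valid gravity direction through flagged stretches
    idx = np.where(ok, np.arange(len(ok)), -1)
    np.maximum.accumulate(idx, out=idx)
    first_ok = int(np.argmax(ok))
    idx[idx < 0] = first_ok
    u = grav[idx] / norm[idx, None]

    vdot = np.einsum("ij,ij->i", xyz, u)
    v = -vdot
    hvec = xyz - vdot[:, None] * u
    # horizontal basis from the mean gravity direction: a single fixed frame
    # keeps h1/h2 continuous; any constant in-plane rotation is immaterial
    u_mean = u.mean(axis=0)
    u_mean /= np.linalg.norm(u_mean)
    e1, e2 = _orthonormal_basis(u_mean)
    h1 = hvec @ e1
    h2 = hvec @ e2
    # re-embed any out-of-plane leakage (u varies, basis is fixed) into h1/h2
    # while preserving magnitude exactly
    hmag = np.linalg.norm(hvec, axis=1)
    planar = np.hypot(h1, h2)
    scale = np.divide(hmag, planar, out=np.ones_like(hmag), where=planar > 1e-12)
    h1 *= scale
    h2 *= scale
    return OrientedRecording(
        rec.t, v, h1, h2, fs=rec.fs, start_datetime=rec.start_datetime
    )
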