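"""Walking-bout detection from the oriented signal.

Candidate locomotion periods are found by a filter-and-threshold scheme:
the signal is low-pass filtered (2nd-order zero-phase Butterworth, 17 Hz
cutoff), then each sample is classified *upright* when the windowed mean
vertical acceleration sits near -1 g, and *candidate locomotion* when it is
upright and the windowed SD of the vector magnitude exceeds a movement
threshold.  Upright-posture gating is what excludes sleep, lying, and
sitting: lying moves gravity off the vertical axis, so the windowed vertical
mean leaves the -1 g band.

Candidate runs are assembled into walking bouts under two inclusion rules:
any rest of 2.5 s or more terminates a bout (shorter pauses are merged),
and a bout must contain at least 3 consecutive steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt

from .signal_io import OrientedRecording


@dataclass
class ActivityMask:
    """Per-sample posture/movement classification aligned with a signal."""

    t: np.ndarray
    upright: np.ndarray
    candidate: np.ndarray  # candidate implies upright
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.upright) == len(self.candidate)):
            raise ValueError("mask arrays must share the signal length")
        self.candidate = self.candidate & self.upright

    def __len__(self) -> int:
        return self.t.size

    def candidate_runs(self, erode_s: float = 0.0) -> list[tuple[float, float]]:
        """Maximal candidate runs as half-open (start_s, end_s) intervals.

        ``erode_s`` shrinks each run by that many seconds per edge,
        compensating the smear a sliding classification window adds (a
        window of w seconds extends each true edge by about w/2); runs
        eroded to nothing are dropped.
        """
        if len(self) == 0:
            return []
        c = self.candidate.astype(np.int8)
        edges = np.diff(np.concatenate(([0], c, [0])))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        dt = 1.0 / self.fs
        runs = [
            (float(self.t[s]) + erode_s, float(self.t[e - 1]) + dt - erode_s)
            for s, e in zip(starts, ends)
        ]
        return [(s, e) for s, e in runs if e > s]


@dataclass
class WalkingBout:
    """One detected locomotion episode (half-open [start_s, end_s))."""

    start_s: float
    end_s: float
    step_times_s: list[float]
    n_steps: int

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def lowpass_walking_filter(sig: OrientedRecording, cutoff_hz: float = 17.0,
                           order: int = 2) -> OrientedRecording:
    """Zero-phase low-pass Butterworth (two-pass) on every channel, DC gain 1."""
    if sig.fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    b, a = butter(order, cutoff_hz / (sig.fs / 2), btype="low")
    return OrientedRecording(
        sig.t,
        filtfilt(b, a, sig.v),
        filtfilt(b, a, sig.h1),
        filtfilt(b, a, sig.h2),
        fs=sig.fs,
        start_datetime=sig.start_datetime,
    )


def classify_activity(
    sig: OrientedRecording,
    window_s: float = 1.0,
    upright_band_g: tuple[float, float] = (-1.15, -0.85),
    sd_threshold_g: float = 0.025,
) -> ActivityMask:
    """Flag upright posture and candidate locomotion per sample.

    A sample is upright when the sliding-window mean of the vertical channel
    lies inside ``upright_band_g`` and candidate locomotion when it is
    additionally inside a window whose vector-magnitude SD exceeds
    ``sd_threshold_g``.
    """
    n = len(sig)
    if n == 0:
        return ActivityMask(sig.t, np.zeros(0, bool), np.zeros(0, bool), sig.fs)
    win = max(2, int(round(window_s * sig.fs)))
    if win > n:
        win = n
    vmean = uniform_filter1d(sig.v, size=win, mode="nearest")
    upright = (vmean >= upright_band_g[0]) & (vmean <= upright_band_g[1])
    m = sig.magnitude
    m1 = uniform_filter1d(m, size=win, mode="nearest")
    m2 = uniform_filter1d(m * m, size=win, mode="nearest")
    sd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
    moving = sd > sd_threshold_g
    return ActivityMask(sig.t, upright, upright & moving, sig.fs)


def segment_bouts(
    mask: ActivityMask | list[tuple[float, float]],
    step_events: np.ndarray | list[float],
    rest_merge_s: float = 2.5,
    min_steps: int = 3,
    snap_halfstep_s: float | None = None,
) -> list[WalkingBout]:
    """Assemble candidate runs into walking bouts.

    Runs separated by a gap strictly shorter than ``rest_merge_s`` are merged
    (a gap of exactly 2.5 s already counts as rest and splits); merged
    episodes with fewer than ``min_steps`` detected step events are
    discarded.  When ``snap_halfstep_s`` is given, bout edges are snapped to
    first/last step +/- that margin (half a step period), intersected with
    the merged episode so bouts stay non-overlapping.

    Accepts either an :class:`ActivityMask` or a pre-extracted list of
    candidate (start_s, end_s) intervals.
    """
    runs = mask.candidate_runs() if isinstance(mask, ActivityMask) else sorted(mask)
    events = np.sort(np.asarray(list(step_events), dtype=float))
    if not runs:
        return []

    merged: list[list[float]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < rest_merge_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    bouts: list[WalkingBout] = []
    for s, e in merged:
        inside = events[(events >= s) & (events < e)]
        if inside.size < min_steps:
            continue
        b0, b1 = s, e
        if snap_halfstep_s is not None:
            b0 = inside[0] - snap_halfstep_s
            b1 = inside[-1] + snap_halfstep_s
            if bouts and b0 < bouts[-1].end_s:  # keep bouts non-overlapping
                b0 = bouts[-1].end_s
        bouts.append(WalkingBout(b0, b1, inside.tolist(), int(inside.size)))
    return bouts


def bouts_to_table(bouts: list[WalkingBout], participant: str = "", day_s: float = 86400.0):
    """Tidy interval table (participant, day, start_s, end_s, duration_s, n_steps)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "participant": participant,
            "day": [int(b.start_s // day_s) for b in bouts],
            "start_s": [b.start_s for b in bouts],
            "end_s": [b.end_s for b in bouts],
            "duration_s": [b.duration_s for b in bouts],
            "n_steps": [b.n_steps for b in bouts],
        }
    )
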