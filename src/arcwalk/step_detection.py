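"""Gait-event (step) detection inside candidate walking periods.

The vertical acceleration is low-pass filtered (4th-order Butterworth,
20 Hz), integrated, and then smoothed-differentiated with a continuous
wavelet transform using a first-derivative-of-Gaussian kernel.  Local
minima of this first transform mark initial contacts (foot strike); the
transform is differentiated once more with the same kernel and local maxima
of the result mark final contacts (foot off).  Steps are counted as initial
contacts falling inside a bout interval.

The wavelet scale adapts to each segment's dominant cadence (spectral peak
in the 0.5-3 Hz locomotor band), which keeps the smoothing matched to step
duration across slow and fast walkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, detrend, filtfilt, find_peaks, periodogram


@dataclass
class GaitEvents:
    """Ordered initial- and final-contact times for one analyzed segment."""

    initial_contacts_s: np.ndarray
    final_contacts_s: np.ndarray

    def __post_init__(self) -> None:
        self.initial_contacts_s = np.asarray(self.initial_contacts_s, dtype=float)
        self.final_contacts_s = np.asarray(self.final_contacts_s, dtype=float)
        for name in ("initial_contacts_s", "final_contacts_s"):
            a = getattr(self, name)
            if a.size > 1 and not np.all(np.diff(a) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return int(self.initial_contacts_s.size)


def lowpass_step_filter(v: np.ndarray, fs: float, cutoff_hz: float = 20.0,
                        order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth on the vertical channel, DC gain 1."""
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    b, a = butter(order, cutoff_hz / (fs / 2), btype="low")
    return filtfilt(b, a, np.asarray(v, dtype=float))


def dominant_cadence(v: np.ndarray, fs: float,
                     band_hz: tuple[float, float] = (0.5, 3.0)) -> float:
    """Dominant step frequency (Hz) as the periodogram peak in the locomotor band.

    Falls back to the band center when no in-band power exists (e.g. a flat
    segment).
    """
    v = detrend(np.asarray(v, dtype=float))
    freqs, pxx = periodogram(v, fs=fs)
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not sel.any() or pxx[sel].max() <= 1e-18:  # flat segment: no real power
        return float(0.5 * (band_hz[0] + band_hz[1]))
    return float(freqs[sel][np.argmax(pxx[sel])])


def _cwt_gauss1(x: np.ndarray, scale_samples: float) -> np.ndarray:
    """Smoothed differentiation: single-scale CWT with a Gaussian-derivative kernel.

    Sign convention: the result approximates + d/dt of the Gaussian-smoothed
    input (pywt's 'gaus1' kernel yields the negative of that, hence the
    flip), so applying it to the integrated vertical acceleration returns
    the smoothed vertical acceleration itself.
    """
    coef, _ = pywt.cwt(x, [max(scale_samples, 1.0)], "gaus1")
    return -coef[0]


def detect_contacts(
    v_filtered: np.ndarray,
    fs: float,
    scale_s: float | None = None,
    t0: float = 0.0,
    step_time_band_s: tuple[float, float] = (0.25, 2.5),
    prominence_frac: float = 0.2,
    scale_factor: float = 0.4,
) -> GaitEvents:
    """Detect initial and final contacts in one candidate segment.

    Parameters
    ----------
    v_filtered : array
        Low-pass-filtered vertical acceleration for the segment, in g.
    fs : float
        Sampling rate, Hz.
    scale_s : float, optional
        Wavelet scale in seconds; when omitted it is set adaptively to
        ``scale_factor / dominant_cadence``.
    t0 : float
        Absolute time of the first sample; event times are reported on this
        axis.
    step_time_band_s : (float, float)
        Plausible inter-initial-contact interval; a contact closing a
        shorter-than-plausible interval is pruned (the weaker of the pair).
    prominence_frac : float
        Peak prominence floor, as a fraction of the segment's median
        absolute transform amplitude.

    Notes
    -----
    The segment is linearly detrended and integrated (cumulative trapezoid)
    before the first wavelet differentiation; detrending prevents the
    integral from drifting.  Minima of the first transform are the initial
    contacts; maxima of the second transform the final contacts.
    """
    v = np.asarray(v_filtered, dtype=float)
    if v.size / fs < 1.5:
        return GaitEvents(np.empty(0), np.empty(0))

    if scale_s is None:
        f_dom = dominant_cadence(v, fs)
        scale_s = scale_factor / f_dom
    scale = scale_s * fs

    integ = cumulative_trapezoid(detrend(v), dx=1.0 / fs, initial=0.0)
    tr1 = _cwt_gauss1(integ, scale)
    tr2 = _cwt_gauss1(tr1, scale)

    def _extrema(x: np.ndarray, minima: bool) -> tuple[np.ndarray, np.ndarray]:
        y = -x if minima else x
        floor = prominence_frac * np.median(np.abs(x)) if np.any(x) else 0.0
        peaks, props = find_peaks(y, prominence=max(floor, 1e-12))
        return peaks, props["prominences"]

    ic_idx, ic_prom = _extrema(tr1, minima=True)
    fc_idx, _ = _extrema(tr2, minima=False)

    # prune implausibly close initial contacts, dropping the weaker of the pair
    min_gap = int(round(step_time_band_s[0] * fs))
    keep = list(range(ic_idx.size))
    changed = True
    while changed and len(keep) > 1:
        changed = False
        for j in range(len(keep) - 1):
            a, b = keep[j], keep[j + 1]
            if ic_idx[b] - ic_idx[a] < min_gap:
                keep.pop(j if ic_prom[a] < ic_prom[b] else j + 1)
                changed = True
                break
    ic_idx = ic_idx[keep]

    ic = t0 + ic_idx / fs
    fc = t0 + fc_idx / fs
    return GaitEvents(ic, fc)


def count_steps(events: GaitEvents, bout: tuple[float, float]) -> int:
    """Steps in a bout = initial contacts inside the half-open interval."""
    start, end = bout
    ic = events.initial_contacts_s
    return int(np.count_nonzero((ic >= start) & (ic < end)))
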