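"""Cardiomyocyte beating-trace analysis and Poincare beat-rate variability.

A cantilever resting gently on a beating cardiomyocyte records a train of
force peaks.  Per-beat metrics are the beat force (peak height above the
local baseline), the beat-to-beat interval, the overall frequency, and
the full width at half maximum (FWHM) of each peak.

Beat-rate variability is quantified on the lag-1 Poincare map: each
interval is plotted against the one before it, and an ellipse centred on
the mean interval summarizes the scatter.  SD1 (dispersion perpendicular
to the identity line, the ellipse minor axis / 2) captures short-term
beat-to-beat variability; SD2 (dispersion along the identity line, major
axis / 2) the long-term variability; R = SD1/SD2 their balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .curves import DataError

__all__ = ["BeatRecord", "PoincareResult", "detect_beats", "poincare_analysis"]


class InsufficientBeatsError(RuntimeError):
    """Fewer beats than the analysis needs."""


@dataclass
class BeatRecord:
    peak_times: np.ndarray      # s
    beat_forces: np.ndarray     # N, peak minus local baseline
    fwhm: np.ndarray            # s per beat
    intervals: np.ndarray       # s, diff of peak times
    frequency: float            # Hz, (n-1) / (t_last - t_first)
    metadata: dict = field(default_factory=dict)


@dataclass
class PoincareResult:
    sd1: float                  # s
    sd2: float                  # s
    ratio: float                # SD1/SD2; inf when SD2 = 0, nan when both 0
    centroid: tuple[float, float]   # mean interval on both axes
    n_points: int

    @property
    def ellipse_axes(self) -> tuple[float, float]:
        """(minor, major) ellipse axis lengths: 2*SD1, 2*SD2."""
        return 2.0 * self.sd1, 2.0 * self.sd2


def _local_baseline(force: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Per-beat baseline: linear interpolation between flanking minima."""
    mins = []
    bounds = np.concatenate([[0], (peaks[:-1] + peaks[1:]) // 2, [force.size - 1]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = force[lo : hi + 1]
        mins.append(lo + int(np.argmin(seg)))
    mins = np.asarray(mins)
    base = np.empty(peaks.size)
    for k, p in enumerate(peaks):
        left = mins[mins <= p]
        right = mins[mins >= p]
        lo = left[-1] if left.size else mins[0]
        hi = right[0] if right.size else mins[-1]
        if hi == lo:
            base[k] = force[lo]
        else:
            w = (p - lo) / (hi - lo)
            base[k] = (1 - w) * force[lo] + w * force[hi]
    return base


def _fwhm(time: np.ndarray, force: np.ndarray, peak: int, baseline: float) -> float:
    half = baseline + 0.5 * (force[peak] - baseline)
    # walk left and right to the half-height crossings, interpolate linearly
    i = peak
    while i > 0 and force[i] > half:
        i -= 1
    if force[i] > half:
        t_left = time[i]
    else:
        t_left = np.interp(half, [force[i], force[i + 1]], [time[i], time[i + 1]])
    j = peak
    while j < force.size - 1 and force[j] > half:
        j += 1
    if force[j] > half:
        t_right = time[j]
    else:
        t_right = np.interp(half, [force[j], force[j - 1]], [time[j], time[j - 1]])
    return float(t_right - t_left)


def detect_beats(time: np.ndarray, force: np.ndarray,
                 min_prominence: float, *, min_spacing: float = 0.0) -> BeatRecord:
    """Detect beats in a calibrated force-vs-time trace.

    Peaks need at least ``min_prominence`` (N) of prominence and
    ``min_spacing`` (s) of separation.  Raises
    :class:`InsufficientBeatsError` below two peaks.
    """
    time = np.asarray(time, float)
    force = np.asarray(force, float)
    if time.shape != force.shape:
        raise DataError("time and force must have equal length")
    dt = float(np.median(np.diff(time)))
    distance = max(1, int(round(min_spacing / dt))) if min_spacing else 1
    peaks, _ = find_peaks(force, prominence=min_prominence, distance=distance)
    if peaks.size < 2:
        raise InsufficientBeatsError(f"found {peaks.size} beats, need >= 2")
    base = _local_baseline(force, peaks)
    fwhm = np.array([_fwhm(time, force, p, b) for p, b in zip(peaks, base)])
    pt = time[peaks]
    return BeatRecord(
        peak_times=pt,
        beat_forces=force[peaks] - base,
        fwhm=fwhm,
        intervals=np.diff(pt),
        frequency=float((peaks.size - 1) / (pt[-1] - pt[0])),
        metadata={"peak_indices": peaks},
    )


def poincare_analysis(intervals: np.ndarray) -> PoincareResult:
    """Lag-1 Poincare analysis of a beat-interval series.

    With points (x_n, x_{n+1}), SD1 is the sample standard deviation of
    the projections onto the perpendicular to the identity line and SD2
    along it:

        SD1^2 = Var(x_n - x_{n+1}) / 2
        SD2^2 = Var(x_n + x_{n+1}) / 2

    (sample, n-1 denominator).  When SD2 = 0 (e.g. perfectly alternating
    intervals) the ratio is returned as ``inf``; when both vanish
    (constant intervals) as ``nan`` -- never an exception.
    """
    x = np.asarray(intervals, float)
    if x.size < 3:
        raise DataError("need >= 3 intervals for a Poincare plot")
    a, b = x[:-1], x[1:]
    sd1 = float(np.sqrt(np.var(a - b, ddof=1) / 2.0))
    sd2 = float(np.sqrt(np.var(a + b, ddof=1) / 2.0))
    if sd2 > 0:
        ratio = sd1 / sd2
    else:
        ratio = np.nan if sd1 == 0 else np.inf
    mean = float(np.mean(x))
    return PoincareResult(sd1=sd1, sd2=sd2, ratio=ratio,
                          centroid=(mean, mean), n_points=a.size)
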