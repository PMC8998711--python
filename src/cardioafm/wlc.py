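"""Single-molecule sawtooth analysis with the worm-like chain model.

Pulling a multi-domain protein between tip and substrate produces a
sawtooth force--extension record: each rising branch is the entropic
stretching of the unfolded polypeptide, each drop ("rip") the unfolding
of one domain, which releases a fixed increment of contour length.

Each rising branch is fitted with the Marko--Siggia interpolation of the
worm-like chain,

    F(x) = (kB T / p) * [ 1 / (4 (1 - x/Lc)^2) - 1/4 + x/Lc ],

giving the contour length Lc and persistence length p per peak; the
spacing Delta-Lc between successive contour lengths measures the length
of one folded domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .curves import DataError, ForceCurve, Segment, tip_sample_separation

__all__ = ["BOLTZMANN", "WLCPeakFit", "wlc_force", "detect_sawtooth_peaks",
           "fit_wlc_per_peak", "fit_wlc_shared_p"]

BOLTZMANN = 1.380649e-23  # J/K


@dataclass
class WLCPeakFit:
    peak_index: int
    extension: float        # m, at the rupture peak
    rupture_force: float    # N
    contour_length: float   # m
    persistence_length: float  # m
    temperature: float      # K
    residual_rms: float     # N
    error: str | None = None


def wlc_force(x, contour_length: float, persistence_length: float,
              temperature: float = 298.0):
    """Marko--Siggia worm-like-chain force (N) at extension(s) x (m)."""
    x = np.asarray(x, float)
    r = np.clip(x / contour_length, 0.0, 1.0 - 1e-12)
    kbt = BOLTZMANN * temperature
    return (kbt / persistence_length) * (0.25 / (1.0 - r) ** 2 - 0.25 + r)


def _pulling_axes(curve: ForceCurve) -> tuple[np.ndarray, np.ndarray]:
    s = curve.segment_slice(Segment.RETRACT)
    if curve.force is None:
        raise DataError("curve must be calibrated")
    f = curve.force[s].astype(float)
    if curve.deflection is not None:
        x = tip_sample_separation(curve)[s]
    else:
        x = curve.piezo_position[s].astype(float)
    # extension increases away from the surface during pulling
    x = np.abs(x - x[0])
    return x, f


def detect_sawtooth_peaks(curve: ForceCurve, min_prominence: float,
                          *, min_distance: int = 5, smooth: int = 0) -> list[int]:
    """Indices (within the retract) of sawtooth rupture peaks.

    Peaks are local maxima of pulling force with at least
    ``min_prominence`` (N) of prominence, ordered by extension.
    ``smooth`` applies a moving-average of that many samples before
    detection (for noisy records); peak indices refer to the raw trace.
    """
    _, f = _pulling_axes(curve)
    if smooth > 1:
        f = np.convolve(f, np.ones(smooth) / smooth, mode="same")
    peaks, _ = find_peaks(f, prominence=min_prominence, distance=min_distance)
    return [int(p) for p in peaks]


def _wlc_partials(x: np.ndarray, lc: float, p: float, temperature: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(dF/dLc, dF/dp) of the Marko--Siggia force at extensions x."""
    r = np.clip(x / lc, 0.0, 1.0 - 1e-12)
    kbt = BOLTZMANN * temperature
    dF_dr = (kbt / p) * (0.5 / (1.0 - r) ** 3 + 1.0)
    dF_dlc = dF_dr * (-x / lc**2)
    dF_dp = -(kbt / p**2) * (0.25 / (1.0 - r) ** 2 - 0.25 + r)
    return dF_dlc, dF_dp


def _coarse_wlc_start(xb: np.ndarray, fb: np.ndarray, xmax: float,
                      temperature: float) -> list[float]:
    """Coarse (Lc, p) grid minimum as a starting point for the refinement.

    The WLC least-squares surface is a narrow curved valley; a grid over
    Lc/x_max in [1.02, 3] and p in [0.1, 3] nm keeps the local solver out
    of the shallow shoulder far from the optimum.
    """
    sub = slice(None, None, max(1, xb.size // 50))
    xs, fs = xb[sub], fb[sub]
    best, x0 = np.inf, [1.2 * xmax, 0.4e-9]
    for lc in xmax * np.geomspace(1.02, 3.0, 25):
        model_unit = wlc_force(xs, lc, 1e-9, temperature)  # scales as 1/p
        for pp in np.geomspace(0.1e-9, 3e-9, 15):
            cost = float(np.sum((model_unit * (1e-9 / pp) - fs) ** 2))
            if cost < best:
                best, x0 = cost, [float(lc), float(pp)]
    return x0


def _branch_slices(x: np.ndarray, peaks: list[int]) -> list[slice]:
    out = []
    prev_end = 0
    for p in peaks:
        out.append(slice(prev_end, p + 1))
        prev_end = p + 1
    return out


def fit_wlc_per_peak(curve: ForceCurve, peaks: list[int] | None = None,
                     *, temperature: float = 298.0,
                     min_prominence: float | None = None,
                     min_branch_samples: int = 10,
                     force_floor_fraction: float = 0.02) -> list[WLCPeakFit]:
    """Fit (Lc, p) on the rising branch below each rupture peak.

    Samples with force below ``force_floor_fraction`` of the branch peak
    are excluded (near-zero extension carries no shape information).  A
    branch with fewer than ``min_branch_samples`` usable samples yields a
    fit record carrying ``error``; the other peaks proceed.
    """
    x, f = _pulling_axes(curve)
    if peaks is None:
        if min_prominence is None:
            raise ValueError("give peaks or min_prominence")
        peaks = detect_sawtooth_peaks(curve, min_prominence)
    fits: list[WLCPeakFit] = []
    for p, br in zip(peaks, _branch_slices(x, peaks)):
        xb, fb = x[br], f[br]
        keep = fb > force_floor_fraction * f[p]
        xb, fb = xb[keep], fb[keep]
        rec = WLCPeakFit(peak_index=p, extension=float(x[p]),
                         rupture_force=float(f[p]), contour_length=np.nan,
                         persistence_length=np.nan, temperature=temperature,
                         residual_rms=np.nan)
        if xb.size < min_branch_samples:
            rec.error = "branch too short"
            fits.append(rec)
            continue
        xmax = float(np.max(xb))
        f_scale = float(f[p])  # nondimensionalize: raw forces are ~1e-10 N

        def resid(q):
            return (wlc_force(xb, q[0], q[1], temperature) - fb) / f_scale

        def jac(q):
            d_lc, d_p = _wlc_partials(xb, q[0], q[1], temperature)
            return np.stack([d_lc, d_p], axis=1) / f_scale

        x0 = _coarse_wlc_start(xb, fb, xmax, temperature)
        sol = least_squares(resid, x0=x0, jac=jac,
                            bounds=([xmax * 1.0001, 1e-12], [100 * xmax, 1e-6]),
                            x_scale=[xmax, 1e-10],
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        res = resid(sol.x) * f_scale
        rec.contour_length = float(sol.x[0])
        rec.persistence_length = float(sol.x[1])
        rec.residual_rms = float(np.sqrt(np.mean(res**2)))
        fits.append(rec)
    return fits


def contour_length_increments(fits: list[WLCPeakFit]) -> np.ndarray:
    """Delta-Lc between successive successful peak fits (m)."""
    lc = np.array([f.contour_length for f in fits if f.error is None])
    return np.diff(lc)


def fit_wlc_shared_p(curve: ForceCurve, peaks: list[int],
                     *, temperature: float = 298.0,
                     min_branch_samples: int = 10,
                     force_floor_fraction: float = 0.02) -> tuple[float, list[WLCPeakFit]]:
    """Global fit: one persistence length shared by all branches.

    Returns ``(p_shared, fits)``; whether successive unfolding peaks of
    one molecule share p is a modelling choice, so both this and the
    per-peak mode are provided.
    """
    x, f = _pulling_axes(curve)
    branches = []
    for p, br in zip(peaks, _branch_slices(x, peaks)):
        xb, fb = x[br], f[br]
        keep = fb > force_floor_fraction * f[p]
        if keep.sum() >= min_branch_samples:
            branches.append((p, xb[keep], fb[keep]))
    if not branches:
        raise DataError("no fittable branches")
    x0 = [0.4e-9] + [1.3 * float(np.max(xb)) for _, xb, _ in branches]
    lb = [1e-12] + [float(np.max(xb)) * 1.0001 for _, xb, _ in branches]
    ub = [1e-6] + [100 * float(np.max(xb)) for _, xb, _ in branches]

    f_scale = max(float(np.max(fb)) for _, _, fb in branches)

    def resid(q):
        pp = q[0]
        parts = [wlc_force(xb, lc, pp, temperature) - fb
                 for lc, (_, xb, fb) in zip(q[1:], branches)]
        return np.concatenate(parts) / f_scale

    n_total = sum(xb.size for _, xb, _ in branches)

    def jac(q):
        pp = q[0]
        out = np.zeros((n_total, 1 + len(branches)))
        row = 0
        for col, (lc, (_, xb, _)) in enumerate(zip(q[1:], branches), start=1):
            d_lc, d_p = _wlc_partials(xb, lc, pp, temperature)
            out[row : row + xb.size, 0] = d_p
            out[row : row + xb.size, col] = d_lc
            row += xb.size
        return out / f_scale

    scale = [1e-10] + [float(np.max(xb)) for _, xb, _ in branches]
    sol = least_squares(resid, x0=x0, jac=jac, bounds=(lb, ub), x_scale=scale,
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    p_shared = float(sol.x[0])
    fits = []
    for lc, (pk, xb, fb) in zip(sol.x[1:], branches):
        res = wlc_force(xb, lc, p_shared, temperature) - fb
        fits.append(WLCPeakFit(peak_index=pk, extension=float(x[pk]),
                               rupture_force=float(f[pk]), contour_length=float(lc),
                               persistence_length=p_shared, temperature=temperature,
                               residual_rms=float(np.sqrt(np.mean(res**2)))))
    return p_shared, fits
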