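"""Dwell-segment stress-relaxation analysis.

During the dwell the piezo is held still and the contact force decays
through viscoelastic stress relaxation.  The normalized force profile is
modelled by a generalized Maxwell solid -- one spring in parallel with two
(by default) spring--dashpot elements:

    G(t) = G0 + sum_i Gi * exp(-t / tau_i)

where G0 is the dimensionless equilibrium modulus (the t -> infinity
asymptote), Gi the element weights and tau_i = eta_i / Gi the relaxation
times.  The percent relaxation at the end of the dwell is
``[1 - G(t_end)] * 100``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .curves import DataError, ForceCurve, Segment

__all__ = [
    "RelaxationTrace",
    "MaxwellFit",
    "FitError",
    "maxwell_model",
    "extract_relaxation",
    "fit_maxwell",
    "percent_relaxation",
    "compare_exponential_orders",
    "hertz_contact_area",
]


class FitError(RuntimeError):
    pass


@dataclass
class RelaxationTrace:
    """Normalized dwell-force decay.

    ``g`` is the force rebased to the [0, 1] normalized range: baseline
    zero subtracted, then divided by the maximum, so g(0) = 1.  ``time``
    starts at 0 at the beginning of the dwell.
    """

    time: np.ndarray
    g: np.ndarray
    stress: np.ndarray | None = None    # Pa, force / contact area
    dwell_duration: float = 60.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.g = np.asarray(self.g, float)
        if self.time.shape != self.g.shape:
            raise DataError("time and g must have equal length")
        if self.time[0] != 0.0:
            self.time = self.time - self.time[0]
        if not np.isclose(np.max(self.g), 1.0, atol=1e-9):
            raise DataError("normalized trace must have max(g) = 1")


@dataclass
class MaxwellFit:
    g0: float
    weights: tuple[float, ...]      # G1, G2, ... ordered by tau
    taus: tuple[float, ...]         # s, ascending
    residual_rms: float
    percent_relaxation: float
    degenerate: bool = False

    @property
    def n_terms(self) -> int:
        return len(self.taus)

    @property
    def viscosities(self) -> tuple[float, ...]:
        """eta_i = Gi * tau_i for each Maxwell element."""
        return tuple(g * t for g, t in zip(self.weights, self.taus))

    def model(self, t: np.ndarray | float) -> np.ndarray:
        return maxwell_model(t, self.g0, self.weights, self.taus)


def maxwell_model(t, g0, weights, taus):
    t = np.asarray(t, float)
    out = np.full_like(t, g0, dtype=float)
    for g, tau in zip(weights, taus):
        out += g * np.exp(-t / tau)
    return out


def hertz_contact_area(tip_radius: float, indentation: float) -> float:
    """Spherical-contact area pi * R * delta (m^2) at maximum indentation."""
    return float(np.pi * tip_radius * indentation)


def extract_relaxation(curve: ForceCurve, contact_area: float | None = None,
                       *, baseline: float | None = None,
                       dwell_duration: float | None = None) -> RelaxationTrace:
    """Extract and normalize the dwell-force decay from a force curve.

    The dwell force is rebased so that the baseline zero maps to 0 and the
    maximum to 1.  ``baseline`` defaults to the median pre-contact force of
    the approach segment (instrument zero when no approach is present).
    When ``contact_area`` (m^2) is supplied, a parallel stress channel
    force/area is attached.
    """
    if not curve.has_segment(Segment.DWELL):
        raise DataError("curve has no dwell segment")
    if curve.force is None:
        raise DataError("curve must be calibrated")
    s = curve.segment_slice(Segment.DWELL)
    t = curve.time[s] - curve.time[s][0]
    f = curve.force[s].astype(float)
    if baseline is None:
        if curve.has_segment(Segment.APPROACH):
            fa = curve.force[curve.segment_slice(Segment.APPROACH)]
            baseline = float(np.median(fa[: max(5, fa.size // 10)]))
        else:
            baseline = 0.0
    f = f - baseline
    fmax = np.max(f)
    if not fmax > 0:
        raise DataError("non-positive maximum dwell force after baseline removal")
    g = f / fmax
    stress = f / contact_area if contact_area else None
    return RelaxationTrace(time=t, g=g, stress=stress,
                           dwell_duration=dwell_duration or float(t[-1]),
                           metadata={"baseline": baseline, "f_max": float(fmax)})


def _fit_once(t, g, tau0, w0, g0_0):
    n = len(tau0)

    def pack(g0, w, tau):
        return np.concatenate([[g0], w, np.log(tau)])

    def unpack(p):
        return p[0], p[1 : 1 + n], np.exp(p[1 + n :])

    def resid(p):
        g0, w, tau = unpack(p)
        return maxwell_model(t, g0, w, tau) - g

    lb = np.concatenate([[0.0], np.zeros(n), np.full(n, -30.0)])
    ub = np.concatenate([[1.5], np.full(n, 1.5), np.full(n, 30.0)])
    sol = least_squares(resid, pack(g0_0, w0, tau0), bounds=(lb, ub),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return sol


def fit_maxwell(trace: RelaxationTrace, n_terms: int = 2,
                *, n_starts: int = 6,
                degeneracy_tau_ratio: float = 1.5,
                degeneracy_weight: float = 1e-3) -> MaxwellFit:
    """Nonlinear least-squares fit of the generalized Maxwell decay.

    Multi-start initialization: relaxation times are seeded on a
    logarithmic grid between the sampling interval and the dwell duration
    (all ascending combinations), weights from the endpoint values.  The
    returned relaxation times are sorted ascending.  Fits where two times
    coalesce or a weight vanishes are flagged ``degenerate`` (the data do
    not support the requested number of terms).
    """
    t, g = trace.time, trace.g
    if t.size < 10 * n_terms:
        raise FitError(f"need >= {10 * n_terms} samples for {n_terms} terms")
    dt = max(np.median(np.diff(t)), 1e-6)
    grid = np.geomspace(2 * dt, max(t[-1], 4 * dt), n_starts)
    from itertools import combinations
    starts = list(combinations(grid, n_terms)) or [tuple(grid[:n_terms])]
    g_end = float(np.clip(g[-1], 0.0, 1.0))
    w0 = np.full(n_terms, max((1.0 - g_end) / n_terms, 1e-3))
    best = None
    for tau0 in starts:
        try:
            sol = _fit_once(t, g, np.array(tau0), w0, g_end)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("no Maxwell fit converged from any start")
    g0 = float(best.x[0])
    w = np.asarray(best.x[1 : 1 + n_terms], float)
    tau = np.exp(np.asarray(best.x[1 + n_terms :], float))
    order = np.argsort(tau)
    w, tau = w[order], tau[order]
    resid = maxwell_model(t, g0, w, tau) - g
    degenerate = bool(
        np.any(w < degeneracy_weight)
        or np.any(tau[1:] / np.maximum(tau[:-1], 1e-300) < degeneracy_tau_ratio)
    )
    fit = MaxwellFit(
        g0=g0, weights=tuple(map(float, w)), taus=tuple(map(float, tau)),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        percent_relaxation=percent_relaxation(trace),
        degenerate=degenerate,
    )
    return fit


def percent_relaxation(trace: RelaxationTrace, t_end: float | None = None) -> float:
    """Percent relaxation [1 - G(t_end)] x 100 from the normalized trace.

    ``t_end`` defaults to the dwell duration (60 s in the standard
    protocol).  If the trace stops short of ``t_end`` the final sample is
    used with a warning.
    """
    if t_end is None:
        t_end = trace.dwell_duration
    if trace.time[-1] < t_end - 1e-9:
        warnings.warn("trace ends before t_end; using final sample",
                      stacklevel=2)
        g_end = trace.g[-1]
    else:
        g_end = float(np.interp(t_end, trace.time, trace.g))
    return float((1.0 - g_end) * 100.0)


def compare_exponential_orders(trace: RelaxationTrace, orders=(1, 2, 3),
                               *, bic_margin: float = 10.0) -> dict:
    """Fit several exponential orders and tabulate fit quality.

    Returns a dict with one row per order (``rss``, ``aic``, ``bic``,
    ``fit`` or ``error``) and a ``recommended`` entry.  The default
    recommendation is 2 terms unless a higher order improves the BIC by
    more than ``bic_margin``: a single exponential misses the fast early
    decay, while a third term rarely earns its extra parameters.
    """
    t, g = trace.time, trace.g
    n = t.size
    rows: dict[int, dict] = {}
    for k in orders:
        try:
            fit = fit_maxwell(trace, n_terms=k)
        except (FitError, DataError) as exc:
            rows[k] = {"error": str(exc)}
            continue
        rss = float(np.sum((fit.model(t) - g) ** 2))
        p = 1 + 2 * k
        rss = max(rss, 1e-300)
        rows[k] = {
            "fit": fit,
            "rss": rss,
            "aic": n * np.log(rss / n) + 2 * p,
            "bic": n * np.log(rss / n) + p * np.log(n),
        }
    ok = [k for k in orders if "fit" in rows.get(k, {})]
    recommended = None
    if ok:
        recommended = 2 if 2 in ok else ok[0]
        for k in ok:
            if k > recommended and rows[k]["bic"] < rows[recommended]["bic"] - bic_margin:
                recommended = k
    return {"orders": rows, "recommended": recommended}
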