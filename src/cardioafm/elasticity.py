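"""Approach-curve elasticity analysis.

Contact-point detection on the approach segment followed by a
geometry-aware contact-mechanics fit of the Young's modulus:

* sphere (Hertz):         F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2)
* cone (Sneddon):         F = (2/pi) E/(1-nu^2) tan(alpha) delta^2
* four-sided pyramid:     conical form with an effective half-angle
                          (default 35 degrees, MLCT-like probes)

Both models are linear in E at fixed contact point, so the modulus is
obtained in closed form once the contact position is known; a joint
nonlinear refinement of (E, contact) is used on noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .curves import Cantilever, DataError, ForceCurve, Segment, TipGeometry

__all__ = [
    "ElasticityResult",
    "NoContactError",
    "FitError",
    "contact_model_force",
    "detect_contact_point",
    "fit_youngs_modulus",
    "check_thin_sample",
    "PYRAMID_EFFECTIVE_HALF_ANGLE",
]

# Effective cone half-angle substituted for a four-sided pyramidal tip.
PYRAMID_EFFECTIVE_HALF_ANGLE = np.deg2rad(35.0)


class NoContactError(RuntimeError):
    """No sustained force rise found on the approach segment."""


class FitError(RuntimeError):
    """Contact-model fit failed or produced a non-physical modulus."""


@dataclass
class ElasticityResult:
    youngs_modulus: float          # Pa
    contact_index: int             # sample index within the approach segment
    contact_position: float        # piezo position at contact, m
    max_indentation: float         # m
    fit_slice: slice               # samples used for the fit
    residual_rms: float            # N
    thin_sample_valid: bool | None = None


def _geometry_shape(cantilever: Cantilever, delta: np.ndarray) -> np.ndarray:
    """phi(delta) such that F = E * phi(delta) for the probe geometry."""
    nu = cantilever.poisson_ratio_sample
    geom = cantilever.tip_geometry
    d = np.clip(delta, 0.0, None)
    if geom is TipGeometry.SPHERE:
        return (4.0 / 3.0) / (1 - nu**2) * np.sqrt(cantilever.tip_radius) * d**1.5
    if geom is TipGeometry.CONE:
        return (2.0 / np.pi) / (1 - nu**2) * np.tan(cantilever.half_angle) * d**2
    if geom is TipGeometry.PYRAMID:
        alpha = cantilever.half_angle if cantilever.half_angle is not None else PYRAMID_EFFECTIVE_HALF_ANGLE
        return (2.0 / np.pi) / (1 - nu**2) * np.tan(alpha) * d**2
    raise FitError("tipless cantilevers have no indentation contact model")


def contact_model_force(cantilever: Cantilever, youngs_modulus: float,
                        delta: np.ndarray | float) -> np.ndarray:
    """Model force (N) at indentation depth(s) ``delta`` (m)."""
    return youngs_modulus * _geometry_shape(cantilever, np.asarray(delta, float))


def _approach_arrays(curve: ForceCurve) -> tuple[np.ndarray, np.ndarray]:
    s = curve.segment_slice(Segment.APPROACH)
    z = curve.piezo_position[s]
    if curve.force is not None:
        f = curve.force[s]
    else:
        raise DataError("curve must be calibrated before elasticity analysis")
    return z, f


def detect_contact_point(curve: ForceCurve, method: str = "ratio_of_variance",
                         *, window: int | None = None,
                         slope_fraction: float = 0.05) -> tuple[int, float]:
    """Locate the tip--sample contact point on the approach segment.

    The position where the force sharply and persistently rises above the
    pre-contact baseline marks the contact.  Two detectors are available:

    ``ratio_of_variance``
        Maximizes var(force after) / var(force before) over a sliding
        window -- robust to noise, the default.
    ``gradient_kink``
        First sample whose force slope exceeds ``slope_fraction`` of the
        maximum slope -- sharp on clean data.

    Returns ``(index, piezo_position)`` with the index relative to the
    approach segment.  Raises :class:`NoContactError` when the segment
    shows no rise (an all-baseline curve).
    """
    z, f = _approach_arrays(curve)
    n = f.size
    if n < 20:
        raise DataError("approach segment needs >= 20 samples")
    if window is None:
        window = max(10, n // 20)

    # no-contact guard: total rise indistinguishable from baseline scatter
    head = f[: max(window, 10)]
    noise = np.std(head)
    if np.max(f) - np.median(head) <= 5 * noise + 1e-18:
        raise NoContactError("no sustained force rise above baseline")

    if method == "ratio_of_variance":
        eps = 1e-12 * max(np.var(f), 1e-300)
        idx = np.arange(window, n - window)
        rov = np.empty(idx.size)
        csum = np.cumsum(f)
        csum2 = np.cumsum(f * f)

        def win_var(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
            m = hi - lo
            s1 = csum[hi - 1] - np.where(lo > 0, csum[lo - 1], 0.0)
            s2 = csum2[hi - 1] - np.where(lo > 0, csum2[lo - 1], 0.0)
            return s2 / m - (s1 / m) ** 2

        rov = win_var(idx, idx + window) / (win_var(idx - window, idx) + eps)
        i = int(idx[np.argmax(rov)])
    elif method == "gradient_kink":
        df = np.gradient(f, z)
        thresh = slope_fraction * np.max(df)
        above = df > thresh
        # first index from which the slope stays mostly above threshold
        i = int(np.argmax(above))
        if not above[i]:
            raise NoContactError("no slope kink found")
    else:
        raise ValueError(f"unknown method {method!r}")
    return i, float(z[i])


def fit_youngs_modulus(curve: ForceCurve, cantilever: Cantilever,
                       contact: tuple[int, float] | None = None,
                       *, fit_fraction: float = 1.0,
                       min_points: int = 10,
                       refine_contact: bool = True) -> ElasticityResult:
    """Fit E on the post-contact part of the approach segment.

    The indentation is the tip--sample separation travel past contact,
    ``delta = (z - z0) - (d - d0)`` (piezo travel minus cantilever
    bending); when the deflection channel was not retained, bending is
    reconstructed from force / spring constant.  The pre-contact baseline
    (offset and slope) is estimated and removed before fitting.

    ``fit_fraction`` restricts the fit window to the shallow part of the
    indentation, ``[0, fit_fraction * delta_max]``, to limit substrate
    contributions.
    """
    z, f_raw = _approach_arrays(curve)
    s = curve.segment_slice(Segment.APPROACH)
    k = curve.metadata.get("spring_constant", cantilever.spring_constant)
    if curve.deflection is not None:
        d_raw = curve.deflection[s]
    else:
        d_raw = f_raw / k

    def prepared(z0_try: float):
        """Baseline-corrected force/deflection and indentation for a trial z0."""
        pre = z < z0_try
        if pre.sum() >= 5:
            coeffs = np.polyfit(z[pre], f_raw[pre], 1)
            f = f_raw - np.polyval(coeffs, z)
        else:
            f = f_raw - (np.median(f_raw[pre]) if pre.any() else 0.0)
        if curve.deflection is None:
            d = f / k
        else:
            d = d_raw - (d_raw[pre].mean() if pre.any() else 0.0)
        delta = (z - z0_try) - d
        return f, delta

    def closed_form_E(z0_try: float) -> tuple[float, np.ndarray, np.ndarray]:
        f, delta = prepared(z0_try)
        dmax = np.nanmax(delta)
        if not dmax > 0:
            raise FitError("no post-contact samples for this contact position")
        hi = fit_fraction * dmax
        in_fit = (delta > 0) & (delta <= hi + 1e-30)
        if in_fit.sum() < min_points:
            raise FitError("too few post-contact samples for the fit")
        phi = _geometry_shape(cantilever, np.where(in_fit, delta, 0.0))
        denom = float(phi @ phi)
        if denom <= 0:
            raise FitError("degenerate indentation range")
        E = float(phi @ (f * in_fit)) / denom
        # residual over the whole approach: baseline region must stay flat,
        # which pins the contact position against drifting into the contact
        model = E * _geometry_shape(cantilever, np.clip(delta, 0.0, hi))
        resid = np.where(delta <= hi + 1e-30, f - model, 0.0)
        return E, resid, in_fit

    def cost(z0_try: float) -> float:
        try:
            _, resid, in_fit = closed_form_E(z0_try)
        except FitError:
            return np.inf
        n_used = int((resid != 0).sum()) or 1
        return float(np.sum(resid**2) / n_used)

    if contact is None and refine_contact:
        # global 1-D profile search for the contact position
        zmin, zmax = z[5], z[-min_points]
        grid = np.linspace(zmin, zmax, 80)
        costs = np.array([cost(g) for g in grid])
        j = int(np.argmin(costs))
        lo, hi_b = grid[max(j - 1, 0)], grid[min(j + 1, grid.size - 1)]
        sol = minimize_scalar(cost, bounds=(lo, hi_b), method="bounded",
                              options={"xatol": 1e-6 * (zmax - zmin)})
        z0 = float(sol.x) if np.isfinite(sol.fun) else float(grid[j])
    else:
        if contact is None:
            contact = detect_contact_point(curve)
        z0 = contact[1]
        if refine_contact:
            dz = float(np.median(np.abs(np.diff(z)))) or 1e-10
            sol = minimize_scalar(cost, bounds=(z0 - 20 * dz, z0 + 20 * dz),
                                  method="bounded", options={"xatol": 1e-4 * dz})
            if np.isfinite(sol.fun):
                z0 = float(sol.x)

    E, resid, in_fit = closed_form_E(z0)
    idx = np.flatnonzero(in_fit)
    fit_slice = slice(int(idx[0]), int(idx[-1]) + 1)
    resid = resid[in_fit]
    if not E > 0:
        raise FitError(f"non-positive modulus estimate ({E:.3g} Pa)")
    _, delta = prepared(z0)
    return ElasticityResult(
        youngs_modulus=E,
        contact_index=int(np.searchsorted(z, z0)),
        contact_position=z0,
        max_indentation=float(np.nanmax(delta)),
        fit_slice=fit_slice,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def check_thin_sample(result: ElasticityResult, sample_height: float,
                      *, max_fraction: float = 0.10) -> bool:
    """Thin-sample validity rule: indentation within 10% of the sample height.

    Deeper indentation probes the hard substrate underneath and inflates
    the apparent modulus.  The boundary is inclusive.
    """
    if not sample_height > 0:
        raise ValueError("sample_height must be > 0")
    valid = result.max_indentation <= max_fraction * sample_height
    result.thin_sample_valid = bool(valid)
    return bool(valid)
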