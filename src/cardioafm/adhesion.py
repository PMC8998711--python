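"""Retract-curve adhesion metrics and unbinding-event detection.

The overall adhesion of a retract curve is summarized by three numbers:
the maximum adhesion (detachment) force -- the deepest force excursion
below the zero-force line; the distance from the start of the withdrawal
at which it occurs; and the work of adhesion -- the energy dissipated in
detaching, obtained by integrating the area enclosed between the retract
curve and the zero line.

Discrete unbinding events are upward force steps on the retract: a step
preceded by a rising force ramp is a *rupture* (a receptor anchored to
the cytoskeleton loads elastically before letting go), while a step
preceded by a force plateau is a *tether* (a membrane nanotube pulled at
nearly constant force, receptor unanchored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import DataError, ForceCurve, Segment, tip_sample_separation

__all__ = ["AdhesionEvent", "AdhesionResult", "adhesion_metrics",
           "detect_unbinding_events"]


@dataclass
class AdhesionEvent:
    index: int          # sample index of the step within the retract
    position: float     # m, distance axis value at the step
    force_step: float   # N, upward jump height
    kind: str           # "rupture" or "tether"


@dataclass
class AdhesionResult:
    max_adhesion_force: float       # N, magnitude of deepest excursion
    distance_at_max: float          # m from retract start
    work_of_adhesion: float         # J
    baseline: float                 # N, estimated zero-force level
    events: list[AdhesionEvent] = field(default_factory=list)
    configuration: str = "tip_on_cell"  # metadata: which side carried the cell


def _retract_axes(curve: ForceCurve, use_separation: bool) -> tuple[np.ndarray, np.ndarray]:
    s = curve.segment_slice(Segment.RETRACT)
    if curve.force is None:
        raise DataError("curve must be calibrated")
    f = curve.force[s].astype(float)
    if use_separation and curve.deflection is not None:
        x = tip_sample_separation(curve)[s]
    else:
        x = curve.piezo_position[s].astype(float)
    return x, f


def estimate_baseline(force: np.ndarray, tail_fraction: float = 0.10) -> float:
    """Zero-force level: median of the far-from-surface tail of the retract."""
    n = max(int(round(tail_fraction * force.size)), 3)
    return float(np.median(force[-n:]))


def adhesion_metrics(curve: ForceCurve, *, use_separation: bool = True,
                     tail_fraction: float = 0.10,
                     configuration: str = "tip_on_cell") -> AdhesionResult:
    """Maximum adhesion force, its distance, and the work of adhesion.

    Forces are referenced to the zero line estimated from the retract
    tail.  A retract that never drops below that line yields an
    all-zero result rather than an error.  The distance axis is the
    tip--sample separation when the deflection channel is available
    (falling back to piezo travel), measured from the first retract
    sample.  Work integrates only the negative excursion, by trapezoid.
    """
    x, f = _retract_axes(curve, use_separation)
    baseline = estimate_baseline(f, tail_fraction)
    fc = f - baseline
    imin = int(np.argmin(fc))
    if fc[imin] >= 0:
        return AdhesionResult(0.0, 0.0, 0.0, baseline, configuration=configuration)
    neg = np.minimum(fc, 0.0)
    work = float(abs(np.trapezoid(neg, x)))
    return AdhesionResult(
        max_adhesion_force=float(-fc[imin]),
        distance_at_max=float(abs(x[imin] - x[0])),
        work_of_adhesion=work,
        baseline=baseline,
        configuration=configuration,
    )


def detect_unbinding_events(curve: ForceCurve, min_step: float,
                            *, use_separation: bool = True,
                            slope_window: int = 10,
                            plateau_tolerance: float = 0.05,
                            plateau_scale: float = 100e-9) -> list[AdhesionEvent]:
    """Locate upward force steps >= ``min_step`` on the retract and classify.

    Classification inspects the loading slope over ``slope_window``
    samples before each step: |slope| below ``plateau_tolerance`` of the
    step height per ``plateau_scale`` of travel (default 5% per 100 nm)
    means a plateau, hence a tether; otherwise a rupture.
    """
    x, f = _retract_axes(curve, use_separation)
    df = np.diff(f)
    jump = df >= min_step
    events: list[AdhesionEvent] = []
    i = 0
    while i < jump.size:
        if not jump[i]:
            i += 1
            continue
        j = i
        while j + 1 < jump.size and jump[j + 1]:
            j += 1
        step = float(f[j + 1] - f[i])
        lo = max(0, i - slope_window)
        if i - lo >= 2 and abs(x[i] - x[lo]) > 0:
            slope = float(np.polyfit(x[lo : i + 1], f[lo : i + 1], 1)[0])
        else:
            slope = 0.0
        slope_limit = plateau_tolerance * step / plateau_scale
        kind = "tether" if abs(slope) <= slope_limit else "rupture"
        events.append(AdhesionEvent(index=i, position=float(x[i]),
                                    force_step=step, kind=kind))
        i = j + 1
    return events
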