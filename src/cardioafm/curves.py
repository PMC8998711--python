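"""Force-curve containers, calibration and delimited-text I/O.

Conventions
-----------
All quantities are SI internally (m, s, N, Pa).

``piezo_position`` is the piezo *extension toward the sample*: it increases
during the approach, is constant during the dwell and decreases during the
retract.  ``deflection`` is the cantilever bending in metres, positive for
repulsive (pushing) contact.  The tip--sample separation coordinate is then

    separation = piezo_position - deflection

so that before contact (zero deflection) it equals the piezo position, and
past contact the cantilever absorbs part of the piezo travel.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TipGeometry",
    "Cantilever",
    "Segment",
    "ForceCurve",
    "FormatError",
    "DataError",
    "StateError",
    "read_force_curve",
    "write_force_curve",
    "calibrate_deflection",
    "tip_sample_separation",
]


class FormatError(ValueError):
    """Input file does not match the declared column layout."""


class DataError(ValueError):
    """Input data violates a container invariant (e.g. non-monotone time)."""


class StateError(RuntimeError):
    """Operation applied to a curve in the wrong calibration state."""


class TipGeometry(str, enum.Enum):
    SPHERE = "sphere"
    CONE = "cone"
    PYRAMID = "pyramid"
    TIPLESS = "tipless"


@dataclass(frozen=True)
class Cantilever:
    """AFM cantilever/probe description.

    Parameters
    ----------
    spring_constant : float
        Cantilever stiffness k in N/m.  Soft probes for tissue work sit in
        the 0.1--0.6 N/m range.
    tip_geometry : TipGeometry
        Indenter shape used by the contact-mechanics models.
    tip_radius : float, optional
        Sphere radius in metres (required for ``SPHERE``).
    half_angle : float, optional
        Cone half-opening angle in radians (required for ``CONE`` and
        ``PYRAMID``; for a four-sided pyramid this is the effective
        half-angle of the equivalent cone).
    poisson_ratio_sample : float
        Poisson ratio of the sample, default 0.5 (incompressible soft
        tissue).
    """

    spring_constant: float
    tip_geometry: TipGeometry = TipGeometry.SPHERE
    tip_radius: float | None = None
    half_angle: float | None = None
    poisson_ratio_sample: float = 0.5

    def __post_init__(self) -> None:
        if not self.spring_constant > 0:
            raise ValueError("spring_constant must be > 0")
        if not 0.0 <= self.poisson_ratio_sample <= 0.5:
            raise ValueError("poisson_ratio_sample must be in [0, 0.5]")
        geom = TipGeometry(self.tip_geometry)
        object.__setattr__(self, "tip_geometry", geom)
        if geom is TipGeometry.SPHERE:
            if self.tip_radius is None or not self.tip_radius > 0:
                raise ValueError("sphere geometry requires tip_radius > 0")
        elif geom in (TipGeometry.CONE, TipGeometry.PYRAMID):
            if self.half_angle is None or not 0 < self.half_angle < np.pi / 2:
                raise ValueError("cone/pyramid geometry requires half_angle in (0, pi/2)")


class Segment(str, enum.Enum):
    APPROACH = "approach"
    DWELL = "dwell"
    RETRACT = "retract"


_SEGMENT_ORDER = (Segment.APPROACH, Segment.DWELL, Segment.RETRACT)


@dataclass
class ForceCurve:
    """One approach--dwell--retract record of an AFM force experiment.

    Exactly one of ``deflection`` (uncalibrated, metres) or ``force``
    (calibrated, newtons) must be present at construction; calibration adds
    the force channel while retaining the deflection.
    """

    time: np.ndarray
    piezo_position: np.ndarray
    segment: np.ndarray  # array of str labels from Segment
    deflection: np.ndarray | None = None
    force: np.ndarray | None = None
    calibrated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.piezo_position = np.asarray(self.piezo_position, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        if self.deflection is not None:
            self.deflection = np.asarray(self.deflection, dtype=float)
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if n < 2:
            raise DataError("force curve needs at least 2 samples")
        for name in ("piezo_position", "segment", "deflection", "force"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n,):
                raise DataError(f"{name} length does not match time")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        if self.deflection is None and self.force is None:
            raise DataError("curve needs a deflection or force channel")
        # each present segment label must be one contiguous block
        labels = pd.unique(self.segment)
        for lab in labels:
            idx = np.flatnonzero(self.segment == lab)
            if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise DataError(f"segment {lab!r} is not contiguous")

    def __len__(self) -> int:
        return self.time.size

    def has_segment(self, which: Segment | str) -> bool:
        return bool(np.any(self.segment == str(Segment(which).value)))

    def segment_slice(self, which: Segment | str) -> slice:
        lab = Segment(which).value
        idx = np.flatnonzero(self.segment == lab)
        if idx.size == 0:
            raise DataError(f"curve has no {lab} segment")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def extract(self, which: Segment | str) -> "ForceCurve":
        """Sub-curve of one segment (views are copied)."""
        s = self.segment_slice(which)
        return ForceCurve(
            time=self.time[s].copy(),
            piezo_position=self.piezo_position[s].copy(),
            segment=self.segment[s].copy(),
            deflection=None if self.deflection is None else self.deflection[s].copy(),
            force=None if self.force is None else self.force[s].copy(),
            calibrated=self.calibrated,
            metadata=dict(self.metadata),
        )


def infer_segments(piezo_position: np.ndarray, stationary_tol: float = 1e-10) -> np.ndarray:
    """Label samples approach/dwell/retract from piezo motion.

    Approach is the initial stretch where the piezo extension rises, dwell
    is where it is stationary within ``stationary_tol`` (metres per sample,
    default 0.1 nm) and the remainder is the retract.
    """
    z = np.asarray(piezo_position, float)
    dz = np.diff(z)
    labels = np.empty(z.size, dtype=object)
    # classify gaps, then assign sample i the label of gap i-1 (first sample
    # takes the label of gap 0)
    gap = np.where(np.abs(dz) <= stationary_tol, Segment.DWELL.value,
                   np.where(dz > 0, Segment.APPROACH.value, Segment.RETRACT.value))
    labels[1:] = gap
    labels[0] = gap[0] if gap.size else Segment.APPROACH.value
    # force contiguity: first approach block, then dwell, then retract
    out = np.array(labels, dtype=object)
    first_non_approach = np.argmax(out != Segment.APPROACH.value) if np.any(out != Segment.APPROACH.value) else out.size
    seen_retract = False
    for i in range(out.size):
        if i < first_non_approach:
            continue
        if out[i] == Segment.RETRACT.value:
            seen_retract = True
        if seen_retract:
            out[i] = Segment.RETRACT.value
        elif out[i] == Segment.APPROACH.value:
            out[i] = Segment.DWELL.value
    return out


def read_force_curve(
    path: str | Path | io.TextIOBase,
    columns: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    decimal: str = ".",
    calibrated: bool = False,
    stationary_tol: float = 1e-10,
) -> ForceCurve:
    """Read a delimited-text force curve (JPK-style export).

    Parameters
    ----------
    columns : mapping
        Maps field names (``time``, ``piezo_position``, ``deflection`` or
        ``force``, optional ``segment``) to column headers in the file.
        Defaults to identity names.
    sep : str, optional
        Field delimiter; ``None`` sniffs tab/comma/whitespace.
    decimal : str
        Decimal mark, ``"."`` or ``","`` for European exports.
    """
    columns = dict(columns or {})
    for key in ("time", "piezo_position"):
        columns.setdefault(key, key)
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", decimal=decimal, comment="#")
    else:
        df = pd.read_csv(path, sep=sep, decimal=decimal, comment="#")
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}; found {list(df.columns)}")
    time = df[columns["time"]].to_numpy(float)
    z = df[columns["piezo_position"]].to_numpy(float)
    defl = force = None
    if "deflection" in columns:
        defl = df[columns["deflection"]].to_numpy(float)
    if "force" in columns:
        force = df[columns["force"]].to_numpy(float)
    if defl is None and force is None:
        for guess in ("deflection", "force"):
            if guess in df.columns:
                (defl, force) = (df[guess].to_numpy(float), None) if guess == "deflection" else (None, df[guess].to_numpy(float))
                break
        else:
            raise FormatError("no deflection or force column declared or found")
    if "segment" in columns:
        seg = df[columns["segment"]].astype(str).to_numpy(dtype=object)
    elif "segment" in df.columns:
        seg = df["segment"].astype(str).to_numpy(dtype=object)
    else:
        seg = infer_segments(z, stationary_tol=stationary_tol)
    calibrated = calibrated or (force is not None and defl is None)
    return ForceCurve(time=time, piezo_position=z, segment=seg,
                      deflection=defl, force=force, calibrated=calibrated)


def write_force_curve(curve: ForceCurve, path: str | Path, *, sep: str = "\t") -> None:
    """Write a curve as delimited text with a header; lossless round-trip."""
    cols: dict[str, object] = {
        "time": curve.time,
        "piezo_position": curve.piezo_position,
        "segment": curve.segment,
    }
    if curve.deflection is not None:
        cols["deflection"] = curve.deflection
    if curve.force is not None:
        cols["force"] = curve.force
    df = pd.DataFrame(cols)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def calibrate_deflection(curve: ForceCurve, cantilever: Cantilever) -> ForceCurve:
    """Convert the deflection channel to force via Hooke's law F = k d.

    The deflection channel is retained so that the tip--sample separation
    can still be computed.
    """
    if curve.calibrated:
        raise StateError("curve is already calibrated")
    if curve.deflection is None:
        raise StateError("no deflection channel to calibrate")
    force = cantilever.spring_constant * curve.deflection
    out = replace(curve, force=force, calibrated=True)
    out.metadata = dict(curve.metadata, spring_constant=cantilever.spring_constant)
    return out


def tip_sample_separation(curve: ForceCurve) -> np.ndarray:
    """Tip--sample separation coordinate: piezo_position - deflection."""
    if curve.deflection is None:
        raise StateError("deflection channel required for separation")
    return curve.piezo_position - curve.deflection
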