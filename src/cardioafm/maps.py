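"""Stiffness-map and micrograph containers with TSV/PNG I/O.

A :class:`StiffnessMap` is a rectangular grid of Young's modulus values
(one per quantitative-imaging pixel) with physical coordinates in
micrometres; pixels whose force curve was discarded are stored as NaN and
excluded from every statistic.  A :class:`LabeledImage` couples an RGB
micrograph with an optional binary positivity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio

from .curves import DataError, FormatError

__all__ = [
    "StiffnessMap",
    "LabeledImage",
    "read_stiffness_tsv",
    "write_stiffness_tsv",
    "read_image",
    "write_image",
    "write_mask_png",
]


@dataclass
class StiffnessMap:
    """Regular grid of Young's modulus values.

    Attributes
    ----------
    x, y : 1-D arrays, micrometres
        Physical pixel-centre coordinates of the grid columns / rows
        (0-based, row-major layout: ``modulus[i, j]`` sits at
        ``(x[j], y[i])``).
    modulus : 2-D array, Pa
        Young's modulus per pixel; NaN marks missing (discarded) pixels.
    height : 2-D array, m, optional
        Topography channel.
    """

    x: np.ndarray
    y: np.ndarray
    modulus: np.ndarray
    height: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.modulus = np.asarray(self.modulus, float)
        if self.modulus.shape != (self.y.size, self.x.size):
            raise DataError("modulus shape must be (len(y), len(x))")
        if self.height is not None:
            self.height = np.asarray(self.height, float)
            if self.height.shape != self.modulus.shape:
                raise DataError("height shape must match modulus")
        with np.errstate(invalid="ignore"):
            if np.any(self.modulus < 0):
                raise DataError("Young's modulus must be >= 0 where defined")

    @property
    def shape(self) -> tuple[int, int]:
        return self.modulus.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of pixels that carry a modulus value."""
        return ~np.isnan(self.modulus)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.modulus).sum())

    @property
    def pixel_size(self) -> float:
        """Grid spacing in micrometres (grids are square-pitch)."""
        dx = np.diff(self.x)
        return float(dx[0]) if dx.size else 0.0

    @property
    def scan_area(self) -> float:
        """Scanned area in square micrometres (pixel count x pixel area)."""
        return self.modulus.size * self.pixel_size ** 2


@dataclass
class LabeledImage:
    """RGB micrograph plus optional binary positivity mask."""

    rgb: np.ndarray
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise FormatError("image must be H x W x 3 RGB")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.rgb.shape[:2]:
                raise DataError("mask shape must match image")

    @property
    def rgb_float(self) -> np.ndarray:
        """Image scaled to float [0, 1] regardless of storage dtype."""
        if np.issubdtype(self.rgb.dtype, np.integer):
            return self.rgb.astype(float) / 255.0
        return self.rgb.astype(float)

    @property
    def positive_fraction(self) -> float:
        if self.mask is None:
            raise DataError("image has no mask")
        return float(self.mask.mean())


def _regular_axis(values: np.ndarray, tol: float) -> np.ndarray:
    axis = np.unique(values)
    if axis.size > 1:
        steps = np.diff(axis)
        if np.any(np.abs(steps - steps.mean()) > tol * max(steps.mean(), 1e-30)):
            raise FormatError("coordinates do not form a regular grid")
    return axis

def read_stiffness_tsv(path: str | Path, *, sep: str = "\t",
                       grid_tol: float = 1e-6) -> StiffnessMap:
    """Assemble a stiffness map from a TSV of (x, y, E) rows.

    The coordinate list is pivoted onto a mesh grid mirroring the scanned
    image; rows may arrive in any order and absent grid cells become
    flagged missing pixels.  x and y are micrometres, E is Pa.
    """
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        xc, yc, ec = cols["x"], cols["y"], next(cols[k] for k in ("e", "youngs_modulus", "modulus") if k in cols)
    except (KeyError, StopIteration):
        raise FormatError(f"need x, y and E columns; found {list(df.columns)}") from None
    x = _regular_axis(df[xc].to_numpy(float), grid_tol)
    y = _regular_axis(df[yc].to_numpy(float), grid_tol)
    grid = np.full((y.size, x.size), np.nan)
    ix = np.searchsorted(x, df[xc].to_numpy(float))
    iy = np.searchsorted(y, df[yc].to_numpy(float))
    grid[iy, ix] = df[ec].to_numpy(float)
    return StiffnessMap(x=x, y=y, modulus=grid)


def write_stiffness_tsv(smap: StiffnessMap, path: str | Path, *, sep: str = "\t") -> None:
    """Write (x, y, E) rows; missing pixels are omitted, as in real exports."""
    yy, xx = np.meshgrid(smap.y, smap.x, indexing="ij")
    ok = smap.valid
    df = pd.DataFrame({"x": xx[ok], "y": yy[ok], "E": smap.modulus[ok]})
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_image(path: str | Path) -> LabeledImage:
    """Load a PNG/TIFF micrograph as 8-bit RGB with an empty mask."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return LabeledImage(rgb=arr)


def write_image(image: LabeledImage, path: str | Path) -> None:
    arr = image.rgb
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.clip(np.rint(arr * 255), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr.astype(np.uint8))


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Binary mask as an 8-bit 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
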