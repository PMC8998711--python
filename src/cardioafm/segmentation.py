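"""Quantitative-imaging stiffness-map segmentation.

Fibrotic extracellular matrix (ECM) is stiffer than the surrounding
myocardium, so on a QI stiffness map it shows up as high-modulus regions.
Two segmentation routes are provided:

* **image-space** -- render the map with a colormap, isolate the green
  channel, threshold it and binarize, then translate the modulus values
  onto the mesh grid and read them out under the mask.  This mirrors how
  vendor-rendered map images are segmented in practice.
* **value-space** -- threshold the modulus values directly.  This is the
  recommended route when the numeric map is available, since it does not
  depend on the colormap; for a monotone-green colormap the two routes
  coincide.

The rendered image never carries a scale bar, so no cropping step is
needed before channel extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from skimage.filters import threshold_otsu

from .curves import DataError
from .maps import LabeledImage, StiffnessMap

__all__ = [
    "SegmentationResult",
    "render_stiffness_image",
    "segment_ecm_image",
    "segment_ecm_direct",
    "isolate_region_values",
    "correct_height_offset_linewise",
]

DEFAULT_COLORMAP = "viridis"   # green channel rises monotonically with value


@dataclass
class SegmentationResult:
    mask: np.ndarray                    # True = ECM
    ecm_fraction: float                 # over valid pixels
    ecm_values: np.ndarray              # Pa
    background_values: np.ndarray       # Pa
    summary: dict                       # per-class median/mean/sd
    provenance: dict = field(default_factory=dict)


def render_stiffness_image(smap: StiffnessMap, colormap: str = DEFAULT_COLORMAP,
                           value_range: tuple[float, float] | None = None) -> LabeledImage:
    """Render the modulus grid as an 8-bit RGB image.

    ``value_range`` defaults to the data range of the valid pixels;
    a degenerate (zero-width) range is an error.  Missing pixels render
    black.
    """
    vals = smap.modulus
    ok = smap.valid
    if value_range is None:
        value_range = (float(np.nanmin(vals)), float(np.nanmax(vals)))
    vmin, vmax = value_range
    if not vmax > vmin:
        raise DataError("degenerate value range for rendering")
    norm = np.clip((vals - vmin) / (vmax - vmin), 0.0, 1.0)
    cmap = colormaps[colormap]
    rgb = cmap(np.where(ok, norm, 0.0))[..., :3]
    rgb[~ok] = 0.0
    img = np.clip(np.rint(rgb * 255), 0, 255).astype(np.uint8)
    return LabeledImage(rgb=img, metadata={
        "colormap": colormap, "value_range": value_range})


def segment_ecm_image(image: LabeledImage, threshold: float | str = "otsu",
                      *, polarity: str = "above") -> np.ndarray:
    """Binary ECM mask from the green channel of a rendered map image.

    The green channel is isolated and thresholded (Otsu by default, or a
    fixed value on the [0, 1] scale).  ``polarity`` says whether ECM is
    the bright ("above") or dark ("below") side, which depends on the
    colormap; with the default monotone-green colormap stiff ECM is
    bright.
    """
    green = image.rgb_float[..., 1]
    if threshold == "otsu":
        t = float(threshold_otsu(green))
    else:
        t = float(threshold)
    mask = green > t if polarity == "above" else green < t
    return mask


def segment_ecm_direct(smap: StiffnessMap, threshold: float | str = "otsu") -> np.ndarray:
    """Binary ECM mask from the modulus values themselves (E above threshold).

    ``threshold`` is in Pa, or ``"otsu"`` to separate the value histogram
    automatically.  Missing pixels are never in the mask.
    """
    vals = smap.modulus
    ok = smap.valid
    if threshold == "otsu":
        t = float(threshold_otsu(vals[ok]))
    else:
        t = float(threshold)
    return ok & (vals > t)


def isolate_region_values(smap: StiffnessMap, mask: np.ndarray,
                          *, exclusion: np.ndarray | None = None,
                          provenance: dict | None = None) -> SegmentationResult:
    """Collect modulus values under the mask and summarize per class.

    ``exclusion`` optionally removes user-marked regions (vessels, tissue
    boundary) from both classes.  The full value lists are kept on the
    result so that nothing has to be picked out point by point.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != smap.shape:
        raise DataError("mask shape must match the map grid")
    ok = smap.valid
    if exclusion is not None:
        exclusion = np.asarray(exclusion, bool)
        if exclusion.shape != smap.shape:
            raise DataError("exclusion mask shape must match the map grid")
        ok = ok & ~exclusion
    ecm = smap.modulus[mask & ok]
    bg = smap.modulus[~mask & ok]
    n_valid = int(ok.sum())
    frac = float((mask & ok).sum() / n_valid) if n_valid else 0.0

    def stats(v: np.ndarray) -> dict:
        if v.size == 0:
            return {"n": 0, "median": np.nan, "mean": np.nan, "sd": np.nan}
        return {"n": int(v.size), "median": float(np.median(v)),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0}

    return SegmentationResult(
        mask=mask & ok, ecm_fraction=frac, ecm_values=ecm,
        background_values=bg,
        summary={"ECM": stats(ecm), "non-ECM": stats(bg)},
        provenance=dict(provenance or {}),
    )


def correct_height_offset_linewise(smap: StiffnessMap, mode: str = "median") -> StiffnessMap:
    """Remove a per-scanline offset (or tilt) from the height channel.

    Scanner drift between lines leaves each scanline with its own height
    offset; ``mode="median"`` subtracts the line median, ``mode="linear"``
    removes a per-line linear fit.  The modulus channel is untouched.
    """
    if smap.height is None:
        raise DataError("map has no height channel")
    h = smap.height.copy()
    if mode == "median":
        h -= np.nanmedian(h, axis=1, keepdims=True)
    elif mode == "linear":
        xs = np.arange(h.shape[1], dtype=float)
        for i in range(h.shape[0]):
            row = h[i]
            ok = ~np.isnan(row)
            if ok.sum() >= 2:
                c = np.polyfit(xs[ok], row[ok], 1)
                h[i] = row - np.polyval(c, xs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StiffnessMap(x=smap.x.copy(), y=smap.y.copy(),
                        modulus=smap.modulus.copy(), height=h,
                        metadata=dict(smap.metadata, height_correction=mode))
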