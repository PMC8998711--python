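"""Collagen quantification of stained-tissue micrographs.

Picrosirius red (PSR) stains fibrillar collagen I/III red; second
harmonic generation (SHG) imaging renders fibrillar collagen as a bright
channel without staining.  Both are quantified as the fraction of
positive pixels under a per-pixel classification rule.

The PSR rule is the conjunction of four conditions at each pixel:

(i)   red intensity exceeds both green and blue,
(ii)  green intensity is below a threshold (Otsu on the green channel by
      default),
(iii) HSV hue lies in the circular red interval -- at or above
      ``hue_high`` or at or below ``hue_low`` (defaults 0.8 and 0.0),
(iv)  HSV saturation lies in [0.125, 1].

The SHG rule is a single threshold on the red channel.  8-bit images are
normalized to [0, 1] before HSV conversion; hue is in [0, 1), saturation
is (max - min)/max.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .maps import LabeledImage

__all__ = ["PSRMaskParams", "psr_condition_masks", "psr_quantify", "shg_quantify"]


@dataclass(frozen=True)
class PSRMaskParams:
    green_threshold: float | str = "otsu"   # [0,1] scale or "otsu"
    hue_high: float = 0.8                   # positive when hue >= hue_high ...
    hue_low: float = 0.0                    # ... or hue <= hue_low (wraps at 1)
    saturation_min: float = 0.125
    saturation_max: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.hue_high, self.hue_low, self.saturation_min, self.saturation_max):
            if not 0.0 <= v <= 1.0:
                raise ValueError("HSV interval bounds must lie in [0, 1]")


def psr_condition_masks(image: LabeledImage, params: PSRMaskParams | None = None
                        ) -> tuple[dict[str, np.ndarray], float]:
    """The four PSR conditions as separate masks, plus the green threshold used."""
    params = params or PSRMaskParams()
    rgb = image.rgb_float
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    hsv = rgb2hsv(rgb)
    hue, sat = hsv[..., 0], hsv[..., 1]
    if params.green_threshold == "otsu":
        t_green = float(threshold_otsu(g))
    else:
        t_green = float(params.green_threshold)
    masks = {
        "red_dominant": (r > g) & (r > b),
        "green_below": g < t_green,
        "hue": (hue >= params.hue_high) | (hue <= params.hue_low),
        "saturation": (sat >= params.saturation_min) & (sat <= params.saturation_max),
    }
    return masks, t_green


def psr_quantify(image: LabeledImage, params: PSRMaskParams | None = None) -> LabeledImage:
    """Picrosirius-red collagen mask and positive-pixel fraction.

    Returns a copy of the image with ``mask`` set to the AND of the four
    conditions and metadata recording the thresholds used.
    """
    params = params or PSRMaskParams()
    masks, t_green = psr_condition_masks(image, params)
    mask = masks["red_dominant"] & masks["green_below"] & masks["hue"] & masks["saturation"]
    meta = dict(image.metadata, stain="picrosirius_red", green_threshold=t_green,
                hue_interval=(params.hue_high, params.hue_low),
                saturation_interval=(params.saturation_min, params.saturation_max))
    return LabeledImage(rgb=image.rgb, mask=mask, metadata=meta)


def shg_quantify(image: LabeledImage, red_threshold: float | str = "otsu") -> LabeledImage:
    """SHG collagen mask: red-channel intensity above a threshold.

    ``red_threshold`` is on the [0, 1] scale or ``"otsu"``.  Single-channel
    SHG exports should be loaded as grayscale RGB (all channels equal), in
    which case the red channel carries the signal as required.
    """
    red = image.rgb_float[..., 0]
    if red_threshold == "otsu":
        t = float(threshold_otsu(red))
    else:
        t = float(red_threshold)
    mask = red > t
    meta = dict(image.metadata, stain="shg", red_threshold=t)
    return LabeledImage(rgb=image.rgb, mask=mask, metadata=meta)
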