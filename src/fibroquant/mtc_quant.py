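"""Masson's trichrome quantification: blue extracellular matrix per tissue area.

Blue-stained ECM is segmented with an inclusive HSB threshold box
(hue 121-179, saturation 20-255, brightness 10-255 by default) and scored
as *mean blue intensity per tissue area*: the sum of the HSB brightness of
blue-positive pixels divided by the number of tissue pixels. This is an
intensity-weighted area measure on the 0-255 scale; the plain area
fraction (blue pixels / tissue pixels) is reported alongside as a
secondary metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color_model import BLUE_ECM_RANGE, HSBRange, rgb_to_hsb
from .preprocess import UnquantifiableImageError

__all__ = ["ECMResult", "quantify_ecm"]


@dataclass(frozen=True)
class ECMResult:
    """Blue-pixel statistics for one trichrome image."""

    blue_pixel_count: int
    blue_intensity_sum: int
    tissue_area: int
    mean_blue_intensity: float
    blue_area_fraction: float

    def __post_init__(self) -> None:
        if self.tissue_area < 1:
            raise ValueError("tissue_area must be >= 1")
        if self.blue_pixel_count > self.tissue_area:
            raise ValueError("blue pixels exceed tissue area")
        if not (0.0 <= self.mean_blue_intensity <= 255.0):
            raise ValueError("mean blue intensity outside [0, 255]")


def quantify_ecm(
    img: np.ndarray,
    tissue: np.ndarray,
    blue_range: HSBRange = BLUE_ECM_RANGE,
) -> ECMResult:
    """Score a trichrome image against a tissue mask.

    ``tissue`` is a boolean mask of the same spatial shape as ``img``;
    blue-positive pixels are those inside the mask whose HSB value falls
    in ``blue_range``. A mask with no tissue pixels raises
    :class:`UnquantifiableImageError`.
    """
    arr = np.asarray(img)
    mask = np.asarray(tissue).astype(bool)
    if mask.shape != arr.shape[:2]:
        raise ValueError("tissue mask shape does not match image")
    area = int(mask.sum())
    if area == 0:
        raise UnquantifiableImageError("tissue area is 0; image cannot be quantified")
    hsb = rgb_to_hsb(arr)
    blue = blue_range.contains(hsb[..., 0], hsb[..., 1], hsb[..., 2]) & mask
    count = int(blue.sum())
    intensity = int(hsb[..., 2][blue].astype(np.int64).sum())
    return ECMResult(
        blue_pixel_count=count,
        blue_intensity_sum=intensity,
        tissue_area=area,
        mean_blue_intensity=intensity / area,
        blue_area_fraction=count / area,
    )
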