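"""Background correction of polarized-light images and automated ROI building.

The region of interest (ROI) for birefringence scoring is the tissue area:
total pixels minus empty background and glandular lumen space. Both appear
near-white in the brightfield partner image, so the automatic ROI excludes
pixels that are simultaneously bright and unsaturated. Lumens are invisible
(dark) under polarization, which is why the ROI is derived from the
registered brightfield image and applied to the polarized one.

Background coloration in polarized images (camera offset, residual
transmission) is estimated from the darkest pixels and subtracted per
channel. These rules replace interactive tools with deterministic,
parameterized equivalents; a user-supplied mask file bypasses the automatic
ROI entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .color_model import rgb_to_hsb

__all__ = [
    "BackgroundEstimate",
    "ROISpec",
    "UnquantifiableImageError",
    "estimate_background",
    "correct_background",
    "tissue_mask",
    "build_roi",
]

logger = logging.getLogger(__name__)

DEFAULT_DARK_QUANTILE = 0.25
DEFAULT_WHITE_CUT = 230
DEFAULT_MIN_SAT = 25


class UnquantifiableImageError(ValueError):
    """Raised when an image has no scorable tissue area (ROI size 0)."""


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-channel background offsets and the pixel fraction they came from."""

    r0: int
    g0: int
    b0: int
    fraction: float

    def __post_init__(self) -> None:
        if not all(0 <= v <= 255 for v in (self.r0, self.g0, self.b0)):
            raise ValueError("background offsets must lie in [0, 255]")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("estimation fraction must lie in (0, 1]")

    @property
    def offsets(self) -> np.ndarray:
        return np.array([self.r0, self.g0, self.b0], dtype=np.int64)


@dataclass(frozen=True)
class ROISpec:
    """A region of interest: a boolean mask plus provenance.

    ``mode`` records whether the mask was supplied by the user
    (``"provided"``) or derived from the brightfield partner (``"auto"``).
    ``roi_size`` is the number of True pixels; a zero-size ROI marks the
    image as unquantifiable downstream.
    """

    mode: str
    mask: np.ndarray
    roi_size: int

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "provided"):
            raise ValueError(f"unknown ROI mode {self.mode!r}")
        if self.mask.dtype != bool:
            raise ValueError("ROI mask must be boolean")
        if self.roi_size != int(self.mask.sum()):
            raise ValueError("roi_size does not match mask")

    @property
    def quantifiable(self) -> bool:
        return self.roi_size >= 1


def estimate_background(polarized: np.ndarray, dark_quantile: float = DEFAULT_DARK_QUANTILE) -> BackgroundEstimate:
    """Estimate background colour as the per-channel median of the darkest pixels.

    Pixel darkness is ranked by HSB brightness (max channel); the darkest
    ``dark_quantile`` fraction is selected and the per-channel median of
    that subset, rounded to the nearest integer, is the offset triple.
    Deterministic for a fixed input.

    ``dark_quantile`` must lie in (0, 0.5]: the estimate must come from a
    minority, definitely-background portion of the image.
    """
    if not (0.0 < dark_quantile <= 0.5):
        raise ValueError(f"dark_quantile must be in (0, 0.5], got {dark_quantile}")
    img = np.asarray(polarized)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    flat = img.reshape(-1, 3).astype(np.int64)
    brightness = flat.max(axis=1)
    cut = np.quantile(brightness, dark_quantile)
    dark = flat[brightness <= cut]
    if brightness.min() == brightness.max():
        logger.warning("degenerate image: uniform brightness; background set to its own value")
    r0, g0, b0 = (int(round(float(np.median(dark[:, c])))) for c in range(3))
    return BackgroundEstimate(r0, g0, b0, fraction=dark.shape[0] / flat.shape[0])


def correct_background(img: np.ndarray, bg: BackgroundEstimate) -> np.ndarray:
    """Subtract per-channel background offsets, clamping at zero."""
    arr = np.asarray(img).astype(np.int64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {arr.shape}")
    out = np.clip(arr - bg.offsets, 0, 255)
    return out.astype(np.uint8)


def tissue_mask(
    brightfield: np.ndarray,
    white_cut: int = DEFAULT_WHITE_CUT,
    min_sat: int = DEFAULT_MIN_SAT,
) -> np.ndarray:
    """Tissue mask from a brightfield image: exclude near-white pixels.

    A pixel is "near-white" (empty slide or glandular lumen) when its HSB
    brightness is at least ``white_cut`` AND its saturation is at most
    ``min_sat``. Everything else counts as tissue. Raising ``white_cut``
    can only shrink the excluded set, so the mask is monotone in it.
    """
    for name, v in (("white_cut", white_cut), ("min_sat", min_sat)):
        if not (0 <= v <= 255):
            raise ValueError(f"{name}={v} outside [0, 255]")
    hsb = rgb_to_hsb(brightfield)
    near_white = (hsb[..., 2] >= white_cut) & (hsb[..., 1] <= min_sat)
    return ~near_white


def build_roi(
    polarized: np.ndarray,
    brightfield: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    white_cut: int = DEFAULT_WHITE_CUT,
    min_sat: int = DEFAULT_MIN_SAT,
) -> ROISpec:
    """Build the scoring ROI for a polarized image.

    Exactly one of ``mask`` (user-provided, mode ``"provided"``) or
    ``brightfield`` (automatic tissue mask, mode ``"auto"``) must be given.
    The mask shape must match the polarized image's spatial shape; the
    brightfield partner is assumed pixel-registered with the polarized
    image (same field of view).
    """
    pol = np.asarray(polarized)
    shape = pol.shape[:2]
    if (mask is None) == (brightfield is None):
        raise ValueError("provide exactly one of `mask` or `brightfield`")
    if mask is not None:
        m = np.asarray(mask)
        if m.shape != shape:
            raise ValueError(f"mask shape {m.shape} does not match image shape {shape}")
        m = m.astype(bool)
        mode = "provided"
    else:
        bf = np.asarray(brightfield)
        if bf.shape[:2] != shape:
            raise ValueError(
                f"brightfield shape {bf.shape[:2]} does not match polarized shape {shape}"
            )
        m = tissue_mask(bf, white_cut=white_cut, min_sat=min_sat)
        mode = "auto"
    size = int(m.sum())
    if size == 0:
        logger.warning("ROI is empty: image flagged unquantifiable")
    return ROISpec(mode=mode, mask=m, roi_size=size)
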