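"""8-bit HSB colour space, threshold boxes, and the four-bin hue classification.

Polarized-light Picrosirius red quantification classifies birefringent pixels
by hue on the 8-bit hue wheel used by ImageJ-style threshold tools: the hue
angle in degrees is scaled by 255/360 and truncated, and saturation and
brightness are likewise expressed on 0-255. All threshold bounds are
inclusive on every axis. Achromatic pixels get hue 0 and saturation 0 by
convention, which places them outside every stain bin (red starts at hue 1).

The conversion is done in exact integer arithmetic so that the quantization
is reproducible: ``h8 = floor(255 * h_deg / 360)`` and
``s8 = floor(255 * (max-min) / max)``, with brightness equal to the maximum
channel. This matches the truncation convention of Java/ImageJ HSB.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "HSBRange",
    "HueBinSet",
    "PSR_BINS",
    "BLUE_ECM_RANGE",
    "FULL_RANGE",
    "BIN_NAMES",
    "UNCLASSIFIED",
    "rgb_to_hsb",
    "hsb_to_rgb",
    "in_range",
    "classify_hue",
    "classify_image",
    "threshold_mask",
]

BIN_NAMES = ("red", "orange", "yellow", "green")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class HSBRange:
    """Inclusive threshold box in 8-bit hue/saturation/brightness space."""

    h_lo: int
    h_hi: int
    s_lo: int
    s_hi: int
    b_lo: int
    b_hi: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0 <= v <= 255):
                raise ValueError(f"{f.name}={v} outside [0, 255]")
        for axis in "hsb":
            lo, hi = getattr(self, f"{axis}_lo"), getattr(self, f"{axis}_hi")
            if lo > hi:
                raise ValueError(f"{axis}_lo={lo} > {axis}_hi={hi}")

    def contains(self, h, s, b):
        """Vectorized membership test; bounds inclusive on all three axes."""
        h = np.asarray(h)
        s = np.asarray(s)
        b = np.asarray(b)
        return (
            (h >= self.h_lo) & (h <= self.h_hi)
            & (s >= self.s_lo) & (s <= self.s_hi)
            & (b >= self.b_lo) & (b <= self.b_hi)
        )

    def hue_overlaps(self, other: "HSBRange") -> bool:
        return self.h_lo <= other.h_hi and other.h_lo <= self.h_hi


#: Blue extracellular-matrix threshold for Masson's trichrome images.
BLUE_ECM_RANGE = HSBRange(121, 179, 20, 255, 10, 255)

#: Box accepting every pixel; useful as an identity threshold.
FULL_RANGE = HSBRange(0, 255, 0, 255, 0, 255)


@dataclass(frozen=True)
class HueBinSet:
    """Ordered birefringence hue bins: red, orange, yellow, green.

    Hue increases from red (thick collagen bundles) through orange and
    yellow to green (thin fibrils). Hue intervals must be pairwise
    disjoint so no pixel is ever counted in two bins.
    """

    red: HSBRange
    orange: HSBRange
    yellow: HSBRange
    green: HSBRange

    def __post_init__(self) -> None:
        named = self.as_dict()
        names = list(named)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if named[a].hue_overlaps(named[b]):
                    raise ValueError(f"hue bins {a!r} and {b!r} overlap")

    def as_dict(self) -> dict[str, HSBRange]:
        return {name: getattr(self, name) for name in BIN_NAMES}

    @classmethod
    def default(cls) -> "HueBinSet":
        return cls(
            red=HSBRange(1, 13, 10, 255, 20, 255),
            orange=HSBRange(14, 25, 10, 255, 20, 255),
            yellow=HSBRange(26, 52, 10, 255, 20, 255),
            green=HSBRange(53, 110, 10, 255, 20, 255),
        )


#: Default Picrosirius red birefringence bins.
PSR_BINS = HueBinSet.default()


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return img.astype(np.int64)


def rgb_to_hsb(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit HSB, shape-preserving.

    Hue is the standard hexagonal hue angle scaled by 255/360 and floored;
    saturation is ``floor(255*(max-min)/max)``; brightness is the maximum
    channel. Achromatic pixels (max == min, including black) map to
    hue 0, saturation 0. Computed in integer arithmetic, so e.g. pure blue
    lands exactly on hue 170 (= floor(240 * 255/360)).

    Accepts a single pixel as a length-3 sequence as well (returned as a
    length-3 array).
    """
    arr = np.asarray(img)
    single = arr.ndim == 1 and arr.shape == (3,)
    if single:
        arr = arr.reshape(1, 1, 3)
    arr = _as_rgb(arr)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    d = mx - mn

    # hue numerator t such that h_deg = 60 * t / d, piecewise by max channel
    t = np.zeros_like(mx)
    mr = (mx == r) & (d > 0)
    mg = (mx == g) & (d > 0) & ~mr
    mb = (mx == b) & (d > 0) & ~mr & ~mg
    # max == r: ((g-b)/d) mod 6 -> (g-b) mod (6d), keeps hue in [0, 360)
    t[mr] = np.mod(g[mr] - b[mr], 6 * d[mr])
    t[mg] = (b[mg] - r[mg]) + 2 * d[mg]
    t[mb] = (r[mb] - g[mb]) + 4 * d[mb]

    h = np.zeros_like(mx)
    s = np.zeros_like(mx)
    chrom = d > 0
    # h8 = floor(255 * (60*t/d) / 360) = floor(255*t / (6*d))
    h[chrom] = (255 * t[chrom]) // (6 * d[chrom])
    s[chrom] = (255 * d[chrom]) // mx[chrom]

    out = np.stack([h, s, mx], axis=-1).astype(np.uint8)
    return out[0, 0] if single else out


def hsb_to_rgb(hsb: np.ndarray) -> np.ndarray:
    """Inverse conversion (8-bit in, 8-bit out, nearest-integer rounding).

    Exact inversion is impossible on a quantized wheel; for fully saturated,
    fully bright pixels the round trip preserves hue to within one unit.
    Brightness is preserved exactly (the maximum output channel equals the
    input brightness).
    """
    arr = np.asarray(hsb)
    single = arr.ndim == 1 and arr.shape == (3,)
    if single:
        arr = arr.reshape(1, 1, 3)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 HSB image, got shape {arr.shape}")
    h = arr[..., 0].astype(np.float64) * (360.0 / 255.0)
    s = arr[..., 1].astype(np.float64) / 255.0
    v = arr[..., 2].astype(np.float64)

    c = v * s
    hp = h / 60.0
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    z = np.zeros_like(c)
    sector = np.floor(hp).astype(int) % 6
    r1 = np.choose(sector, [c, x, z, z, x, c])
    g1 = np.choose(sector, [x, c, c, x, z, z])
    b1 = np.choose(sector, [z, z, x, c, c, x])
    m = v - c
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1)
    out = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return out[0, 0] if single else out


def in_range(pixel, r: HSBRange) -> bool:
    """True iff an HSB pixel lies inside the threshold box (all bounds inclusive)."""
    h, s, b = (int(v) for v in np.asarray(pixel).reshape(3))
    return bool(r.contains(h, s, b))


def classify_hue(pixel, bins: HueBinSet = PSR_BINS) -> str:
    """Assign one HSB pixel to its birefringence bin, or ``"unclassified"``.

    A pixel failing any bin's saturation or brightness bounds is
    unclassified even if its hue falls in a bin interval.
    """
    for name, r in bins.as_dict().items():
        if in_range(pixel, r):
            return name
    return UNCLASSIFIED


def classify_image(hsb: np.ndarray, bins: HueBinSet = PSR_BINS) -> np.ndarray:
    """Label every pixel of an HSB image: 0 = unclassified, 1..4 = bin index.

    Bin disjointness (a HueBinSet invariant) guarantees the labels are
    well defined regardless of evaluation order.
    """
    hsb = np.asarray(hsb)
    h, s, b = hsb[..., 0], hsb[..., 1], hsb[..., 2]
    labels = np.zeros(hsb.shape[:-1], dtype=np.uint8)
    for i, (_, r) in enumerate(bins.as_dict().items(), start=1):
        labels[r.contains(h, s, b)] = i
    return labels


def threshold_mask(img: np.ndarray, r: HSBRange) -> np.ndarray:
    """Boolean mask of RGB-image pixels whose HSB value lies in the box."""
    hsb = rgb_to_hsb(img)
    return np.asarray(r.contains(hsb[..., 0], hsb[..., 1], hsb[..., 2]))
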