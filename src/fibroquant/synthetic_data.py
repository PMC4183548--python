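"""Synthetic histology inputs with exact painted ground truth.

Every generator is a pure function of its seed and parameters and records
precisely what it painted, so the measurement code can be tested for exact
(zero-tolerance) recovery:

* :func:`gen_psr_pair` — a registered brightfield/polarized pair. The
  polarized image is a near-black background plus fibre strokes whose HSB
  colours sit at least ``hue_margin`` units inside their target hue bin, at
  full saturation, so RGB<->HSB quantization cannot move a pixel across a
  bin edge. Fibre pixels carry the uniform background offset additively,
  so dark-quantile background correction restores the painted colours
  exactly. The brightfield partner is a pink tissue field with near-white
  glandular lumens; fibres never enter lumens.
* :func:`gen_mtc_image` — a trichrome-like field: blue ECM strokes at a
  fixed brightness on red-pink cytoplasm, with the blue pixel count hit
  exactly so the mean-blue-intensity score has a closed form.
* :func:`gen_shg_stack` — fibres spread over 12-15 optical sections with
  Gaussian intensity falloff in z. Each fibre reaches its full amplitude
  in its own centre slice, so the expected maximum-intensity projection is
  known analytically (per-pixel max of fibre amplitudes), independent of
  how the slices are assembled.
* :func:`gen_cohort` — a TURP-style clinical table (age, PSA, prostate
  size, symptom index, post-void residuals, treatment flags) with
  configurable per-covariate missingness and a collagen metric that is a
  linear function of chosen covariates plus Gaussian noise. Default
  slopes and treatment effects are zero: the null cohort.

These fixtures exercise the measurement code; they make no attempt at
optical realism (no polarization physics, no point-spread function beyond
the z falloff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.draw import ellipse, line

from .color_model import (
    BIN_NAMES,
    HueBinSet,
    PSR_BINS,
    classify_hue,
    hsb_to_rgb,
    rgb_to_hsb,
)

__all__ = [
    "DEFAULT_FRACTIONS",
    "PSRParams",
    "MTCParams",
    "SHGParams",
    "CohortParams",
    "SynthGroundTruth",
    "gen_psr_pair",
    "gen_mtc_image",
    "gen_shg_stack",
    "gen_cohort",
    "sample_bin_fractions",
    "orange_shifted_fractions",
]

#: Baseline per-bin image-area fractions for PSR fixtures. Together they
#: give ~42% birefringent area within tissue, in the range reported for
#: benign glandular prostate, with thin (green/yellow) fibres dominating.
DEFAULT_FRACTIONS: dict[str, float] = {
    "red": 0.05,
    "orange": 0.12,
    "yellow": 0.15,
    "green": 0.10,
}


@dataclass(frozen=True)
class PSRParams:
    """Parameters for a brightfield/polarized Picrosirius red pair."""

    seed: int = 0
    shape: tuple[int, int] = (96, 96)
    fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    background: tuple[int, int, int] = (8, 6, 10)
    lumen_count: int = 3
    lumen_radius: tuple[int, int] = (6, 14)
    segment_count: int = 3
    segment_length: tuple[int, int] = (8, 20)
    fiber_width: tuple[int, int] = (1, 2)
    noise: int = 0
    tissue_color: tuple[int, int, int] = (235, 190, 205)
    lumen_color: tuple[int, int, int] = (250, 247, 248)
    fiber_saturation: int = 255
    fiber_brightness: int = 240
    hue_margin: int = 2
    bins: HueBinSet = PSR_BINS

    def __post_init__(self) -> None:
        fr = dict(self.fractions)
        if any(f < 0 for f in fr.values()):
            raise ValueError("bin fractions must be nonnegative")
        if sum(fr.values()) > 1.0 + 1e-12:
            raise ValueError("bin fractions must sum to at most 1")
        if self.fiber_brightness + max(self.background) > 255:
            raise ValueError("fiber brightness plus background offset overflows 8 bits")


@dataclass(frozen=True)
class MTCParams:
    """Parameters for a Masson's-trichrome-like image."""

    seed: int = 0
    shape: tuple[int, int] = (96, 96)
    ecm_fraction: float = 0.12
    ecm_hue: int = 150
    ecm_saturation: int = 200
    ecm_brightness: int = 200
    cytoplasm_color: tuple[int, int, int] = (210, 120, 130)
    segment_count: int = 3
    segment_length: tuple[int, int] = (8, 20)
    fiber_width: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ecm_fraction <= 1.0):
            raise ValueError("ecm_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SHGParams:
    """Parameters for an SHG optical-section stack."""

    seed: int = 0
    shape: tuple[int, int] = (96, 96)
    z_range: tuple[int, int] = (12, 15)
    max_depth: int = 32
    n_fibers: int = 30
    amplitude: tuple[int, int] = (80, 255)
    sigma_z: float = 1.5
    segment_count: int = 3
    segment_length: tuple[int, int] = (8, 20)
    fiber_width: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        lo, hi = self.z_range
        if not (1 <= lo <= hi <= self.max_depth):
            raise ValueError(
                f"z_range {self.z_range} outside [1, {self.max_depth}]"
            )


#: Per-covariate availability matching a retrospective TURP chart review
#: (fractions of patients with the value recorded).
DEFAULT_AVAILABILITY: dict[str, float] = {
    "age": 1.0,
    "psa": 0.72,
    "prostate_size": 0.32,
    "auasi": 0.32,
    "pvr_pre": 0.40,
    "pvr_post": 0.51,
}


@dataclass(frozen=True)
class CohortParams:
    """Parameters for a synthetic clinical cohort.

    Covariate distributions are chosen so their medians land near typical
    TURP-population values (PSA median ~4 ng/ml, prostate size ~35 g,
    AUASI ~21, pre-TURP PVR ~160 ml, post-TURP PVR ~80 ml). ``slopes``
    maps covariate names to the linear effect of that covariate on the
    collagen metric; ``flag_effects`` maps treatment flags to additive
    group effects. Both default to empty (a null cohort).
    """

    seed: int = 0
    n: int = 47
    metric_name: str = "total_collagen"
    metric_intercept: float = 56.0
    metric_sd: float = 10.0
    slopes: Mapping[str, float] = field(default_factory=dict)
    flag_effects: Mapping[str, float] = field(default_factory=dict)
    finasteride_rate: float = 22 / 47
    alpha_blocker_rate: float = 37 / 47
    availability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AVAILABILITY)
    )

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")


@dataclass
class SynthGroundTruth:
    """What a generator actually painted, for zero-tolerance checks.

    Fields are populated per modality: PSR pairs fill ``bin_labels`` /
    ``counts`` / ``lumen_mask``; trichrome images fill ``ecm_mask`` and
    ``expected_mean_blue``; SHG stacks fill ``expected_mip`` (computed
    analytically from fibre amplitudes, not by projecting the stack);
    cohorts fill ``cohort_truth``.
    """

    params: object
    bin_labels: np.ndarray | None = None
    counts: dict[str, int] | None = None
    lumen_mask: np.ndarray | None = None
    ecm_mask: np.ndarray | None = None
    expected_mean_blue: float | None = None
    expected_mip: np.ndarray | None = None
    expected_mip_mean: float | None = None
    cohort_truth: dict | None = None


def _stroke_coords(
    rng: np.random.Generator,
    shape: tuple[int, int],
    segment_count: int,
    segment_length: tuple[int, int],
    fiber_width: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of one random polyline stroke with integer width."""
    h, w = shape
    r = int(rng.integers(0, h))
    c = int(rng.integers(0, w))
    angle = rng.uniform(0, 2 * np.pi)
    width = int(rng.integers(fiber_width[0], fiber_width[1] + 1))
    canvas = np.zeros(shape, dtype=bool)
    for _ in range(segment_count):
        length = int(rng.integers(segment_length[0], segment_length[1] + 1))
        angle += rng.uniform(-0.5, 0.5)  # gentle curvature
        r2 = int(np.clip(round(r + length * np.sin(angle)), 0, h - 1))
        c2 = int(np.clip(round(c + length * np.cos(angle)), 0, w - 1))
        rr, cc = line(r, c, r2, c2)
        canvas[rr, cc] = True
        r, c = r2, c2
    if width > 1:
        rr, cc = np.nonzero(canvas)
        half = width // 2
        for dr in range(-half, width - half):
            for dc in range(-half, width - half):
                canvas[np.clip(rr + dr, 0, h - 1), np.clip(cc + dc, 0, w - 1)] = True
    return np.nonzero(canvas)


def _interior_hue(rng: np.random.Generator, lo: int, hi: int, margin: int) -> int:
    a, b = lo + margin, hi - margin
    if a > b:
        raise ValueError(f"hue bin [{lo}, {hi}] too narrow for margin {margin}")
    return int(rng.integers(a, b + 1))


def gen_psr_pair(params: PSRParams) -> tuple[np.ndarray, np.ndarray, SynthGroundTruth]:
    """Generate a registered (brightfield, polarized) Picrosirius red pair.

    Fibre strokes are painted per bin until the bin's target pixel count
    (fraction x image area) is reached; crossing fibres are resolved by
    draw order, and the ground truth records final per-pixel ownership.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    n_px = h * w
    bins = params.bins.as_dict()

    # glandular lumens: random ellipses, near-white in brightfield only
    lumen = np.zeros((h, w), dtype=bool)
    for _ in range(params.lumen_count):
        rc = int(rng.integers(0, h))
        cc_ = int(rng.integers(0, w))
        ra = int(rng.integers(params.lumen_radius[0], params.lumen_radius[1] + 1))
        rb = int(rng.integers(params.lumen_radius[0], params.lumen_radius[1] + 1))
        rr, cc2 = ellipse(rc, cc_, ra, rb, shape=(h, w))
        lumen[rr, cc2] = True

    labels = np.zeros((h, w), dtype=np.uint8)
    hue_map = np.zeros((h, w), dtype=np.uint8)
    checked_hues: dict[tuple[int, str], None] = {}

    def paint_bin(idx: int, name: str, target: int, spare_others: bool) -> None:
        rng_cap = 0
        while int((labels == idx).sum()) < target:
            rng_cap += 1
            if rng_cap > 50 * max(1, target):
                raise RuntimeError("fibre painting failed to reach target fraction")
            rr, cc2 = _stroke_coords(
                rng, (h, w), params.segment_count, params.segment_length,
                params.fiber_width,
            )
            keep = ~lumen[rr, cc2]
            if spare_others:
                keep &= labels[rr, cc2] == 0
            rr, cc2 = rr[keep], cc2[keep]
            if rr.size == 0:
                continue
            r_ = bins[name]
            hue = _interior_hue(rng, r_.h_lo, r_.h_hi, params.hue_margin)
            if (hue, name) not in checked_hues:
                # quantization safety: the painted colour must classify back
                # into its intended bin
                px = hsb_to_rgb(
                    np.array([hue, params.fiber_saturation, params.fiber_brightness])
                )
                got = classify_hue(rgb_to_hsb(px), params.bins)
                if got != name:
                    raise RuntimeError(
                        f"painted hue {hue} classified as {got}, expected {name}"
                    )
                checked_hues[(hue, name)] = None
            labels[rr, cc2] = idx
            hue_map[rr, cc2] = hue

    targets = {
        name: int(round(params.fractions.get(name, 0.0) * n_px))
        for name in BIN_NAMES
    }
    # first pass may overwrite earlier bins (crossing fibres);
    # second pass tops up any bin left short, without stealing
    for i, name in enumerate(BIN_NAMES, start=1):
        if targets[name] > 0:
            paint_bin(i, name, targets[name], spare_others=False)
    for i, name in enumerate(BIN_NAMES, start=1):
        if targets[name] > 0 and int((labels == i).sum()) < targets[name]:
            paint_bin(i, name, targets[name], spare_others=True)

    # polarized image: fibres (in HSB, converted) + additive background offset
    bg = np.array(params.background, dtype=np.int64)
    polarized = np.empty((h, w, 3), dtype=np.int64)
    polarized[...] = bg
    fiber_px = labels > 0
    hsb = np.stack(
        [
            hue_map,
            np.full((h, w), params.fiber_saturation, dtype=np.uint8),
            np.full((h, w), params.fiber_brightness, dtype=np.uint8),
        ],
        axis=-1,
    )
    fiber_rgb = hsb_to_rgb(hsb).astype(np.int64)
    polarized[fiber_px] = fiber_rgb[fiber_px] + bg
    if params.noise > 0:
        jitter = rng.integers(
            -params.noise, params.noise + 1, size=(h, w, 3)
        )
        jitter[fiber_px] = 0  # noise models the dark camera background only
        polarized = np.clip(polarized + jitter, 0, 255)
    polarized = polarized.astype(np.uint8)

    brightfield = np.empty((h, w, 3), dtype=np.uint8)
    brightfield[...] = np.array(params.tissue_color, dtype=np.uint8)
    brightfield[lumen] = np.array(params.lumen_color, dtype=np.uint8)

    counts = {
        name: int((labels == i).sum()) for i, name in enumerate(BIN_NAMES, start=1)
    }
    gt = SynthGroundTruth(
        params=params, bin_labels=labels, counts=counts, lumen_mask=lumen
    )
    return brightfield, polarized, gt


def gen_mtc_image(params: MTCParams) -> tuple[np.ndarray, SynthGroundTruth]:
    """Generate a trichrome-like image with an exact blue-ECM pixel count.

    Strokes are painted until the target count is met, then trimmed back
    to it exactly, so the mean blue intensity per tissue area has the
    closed form ``count * ecm_brightness / area``.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    n_px = h * w
    target = int(round(params.ecm_fraction * n_px))

    ecm = np.zeros((h, w), dtype=bool)
    guard = 0
    while int(ecm.sum()) < target:
        guard += 1
        if guard > 50 * max(1, target):
            raise RuntimeError("ECM painting failed to reach target fraction")
        rr, cc = _stroke_coords(
            rng, (h, w), params.segment_count, params.segment_length,
            params.fiber_width,
        )
        ecm[rr, cc] = True
    excess = int(ecm.sum()) - target
    if excess > 0:
        rr, cc = np.nonzero(ecm)
        drop = rng.choice(rr.size, size=excess, replace=False)
        ecm[rr[drop], cc[drop]] = False

    blue_rgb = hsb_to_rgb(
        np.array([params.ecm_hue, params.ecm_saturation, params.ecm_brightness])
    )
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = np.array(params.cytoplasm_color, dtype=np.uint8)
    img[ecm] = blue_rgb

    expected = target * params.ecm_brightness / n_px
    gt = SynthGroundTruth(params=params, ecm_mask=ecm, expected_mean_blue=expected)
    return img, gt


def gen_shg_stack(params: SHGParams) -> tuple[np.ndarray, SynthGroundTruth]:
    """Generate an SHG stack with an analytically known max projection.

    Each fibre has a centre slice where its intensity equals its full
    amplitude, with Gaussian falloff on neighbouring slices; overlapping
    intensities combine by maximum. The expected projection is therefore
    the per-pixel maximum of fibre amplitudes, computed without touching
    the stack.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    z = int(rng.integers(params.z_range[0], params.z_range[1] + 1))
    stack = np.zeros((z, h, w), dtype=np.uint8)
    expected_mip = np.zeros((h, w), dtype=np.uint8)

    for _ in range(params.n_fibers):
        rr, cc = _stroke_coords(
            rng, (h, w), params.segment_count, params.segment_length,
            params.fiber_width,
        )
        amp = int(rng.integers(params.amplitude[0], params.amplitude[1] + 1))
        z0 = int(rng.integers(0, z))
        for zi in range(z):
            a = int(round(amp * np.exp(-((zi - z0) ** 2) / (2 * params.sigma_z**2))))
            if a <= 0:
                continue
            sl = stack[zi]
            sl[rr, cc] = np.maximum(sl[rr, cc], a)
        expected_mip[rr, cc] = np.maximum(expected_mip[rr, cc], amp)

    gt = SynthGroundTruth(
        params=params,
        expected_mip=expected_mip,
        expected_mip_mean=float(expected_mip.mean()),
    )
    return stack, gt


def gen_cohort(params: CohortParams) -> tuple[pd.DataFrame, SynthGroundTruth]:
    """Generate a clinical cohort table with a planted (or null) association.

    The collagen metric is computed from the *complete* covariate values;
    missingness is applied afterwards, so a planted slope survives
    listwise deletion unbiased.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    full = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "age": rng.normal(68.0, 8.0, n),
            "psa": rng.lognormal(np.log(4.05), 0.7, n),
            "prostate_size": np.clip(rng.normal(35.0, 8.0, n), 10.0, None),
            "auasi": np.clip(np.round(rng.normal(21.0, 5.0, n)), 0, 35),
            "pvr_pre": rng.lognormal(np.log(164.0), 0.8, n),
            "pvr_post": rng.lognormal(np.log(80.0), 1.0, n),
            "finasteride": rng.random(n) < params.finasteride_rate,
            "alpha_blocker": rng.random(n) < params.alpha_blocker_rate,
        }
    )
    for flag in ("finasteride", "alpha_blocker"):
        # flag-group t-tests need both groups populated
        if full[flag].all() or not full[flag].any():
            raise ValueError(f"degenerate cohort: flag {flag!r} has a single group")

    metric = np.full(n, params.metric_intercept, dtype=float)
    for cov, slope in params.slopes.items():
        metric += slope * full[cov].to_numpy(dtype=float)
    for flag, eff in params.flag_effects.items():
        metric += eff * full[flag].to_numpy(dtype=float)
    metric += rng.normal(0.0, params.metric_sd, n)
    full[params.metric_name] = metric

    table = full.copy()
    for cov, avail in params.availability.items():
        missing = rng.random(n) >= avail
        table.loc[missing, cov] = np.nan

    gt = SynthGroundTruth(
        params=params,
        cohort_truth={
            "slopes": dict(params.slopes),
            "flag_effects": dict(params.flag_effects),
            "complete": full,
        },
    )
    return table, gt


def sample_bin_fractions(
    rng: np.random.Generator,
    base: Mapping[str, float],
    dispersion: float = 0.18,
) -> dict[str, float]:
    """Per-patient bin fractions: lognormal multiplicative jitter around a base.

    ``dispersion`` is the log-scale standard deviation of the jitter
    (~relative SD between patients). Jitter is independent per bin;
    the result is rescaled if the fractions would sum past 0.95.
    """
    out = {
        b: float(base.get(b, 0.0) * rng.lognormal(0.0, dispersion))
        for b in BIN_NAMES
    }
    total = sum(out.values())
    if total > 0.95:
        out = {b: v * 0.95 / total for b, v in out.items()}
    return out


def orange_shifted_fractions(
    base: Mapping[str, float], prop_shift: float
) -> dict[str, float]:
    """Raise the orange image fraction so the orange *proportion* within
    birefringent pixels increases by ``prop_shift`` (e.g. 0.25 for +25%),
    leaving the other bins' absolute fractions unchanged."""
    total = sum(base.get(b, 0.0) for b in BIN_NAMES)
    rest = total - base.get("orange", 0.0)
    p0 = base.get("orange", 0.0) / total
    p1 = p0 * (1.0 + prop_shift)
    if not (0.0 < p1 < 1.0):
        raise ValueError("shifted orange proportion outside (0, 1)")
    out = dict(base)
    out["orange"] = p1 * rest / (1.0 - p1)
    return out
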