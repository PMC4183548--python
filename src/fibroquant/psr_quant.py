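"""Picrosirius red birefringence quantification.

Two denominators coexist deliberately. Total collagen content is the
proportion of birefringent (any-bin) pixels over the ROI size. The colour
proportions — the fibre-thickness readout — are computed *within*
birefringent pixels, i.e. each bin count over the total positive count.
Group comparisons use proportions normalized to a reference group's mean,
so the reference group averages exactly 1 per bin.

Per-patient values are unweighted means over replicate images (triplicate
fields in the full-slide workflow, duplicate cores on an array). Replicates
with no birefringent pixels have undefined colour proportions; they are
dropped from the proportion average but retained for total collagen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color_model import BIN_NAMES, HueBinSet, PSR_BINS, classify_image, rgb_to_hsb
from .preprocess import ROISpec, UnquantifiableImageError

__all__ = [
    "BirefringenceResult",
    "SampleResult",
    "quantify_birefringence",
    "average_replicates",
    "normalize_to_reference",
]

PROPORTION_COLUMNS = [f"prop_{b}" for b in BIN_NAMES]


@dataclass(frozen=True)
class BirefringenceResult:
    """Per-bin pixel counts and derived fractions for one polarized image."""

    counts: dict[str, int]
    roi_size: int
    total_positive: int = field(init=False)
    total_fraction: float = field(init=False)
    proportions: dict[str, float] | None = field(init=False)

    def __post_init__(self) -> None:
        if set(self.counts) != set(BIN_NAMES):
            raise ValueError(f"counts must have keys {BIN_NAMES}")
        if self.roi_size < 1:
            raise ValueError("roi_size must be >= 1")
        total = int(sum(self.counts.values()))
        if total > self.roi_size:
            raise ValueError("bin counts exceed ROI size")
        object.__setattr__(self, "total_positive", total)
        object.__setattr__(self, "total_fraction", total / self.roi_size)
        props = (
            {b: self.counts[b] / total for b in BIN_NAMES} if total > 0 else None
        )
        object.__setattr__(self, "proportions", props)


@dataclass(frozen=True)
class SampleResult:
    """Replicate-averaged birefringence metrics for one patient (or core)."""

    patient_id: str
    replicates: tuple[BirefringenceResult, ...]
    total_fraction: float
    proportions: dict[str, float] | None


def quantify_birefringence(
    polarized: np.ndarray,
    roi: ROISpec,
    bins: HueBinSet = PSR_BINS,
) -> BirefringenceResult:
    """Count birefringent pixels per hue bin inside the ROI.

    The image is expected to be background-corrected. Pixels outside the
    ROI are ignored entirely; within it, each pixel is assigned to at most
    one bin (bins are disjoint in hue and share saturation/brightness
    gates).
    """
    pol = np.asarray(polarized)
    if roi.mask.shape != pol.shape[:2]:
        raise ValueError("ROI mask shape does not match image")
    if not roi.quantifiable:
        raise UnquantifiableImageError("ROI size is 0; image cannot be quantified")
    labels = classify_image(rgb_to_hsb(pol), bins)
    inside = labels[roi.mask]
    hist = np.bincount(inside, minlength=len(BIN_NAMES) + 1)
    counts = {b: int(hist[i + 1]) for i, b in enumerate(BIN_NAMES)}
    return BirefringenceResult(counts=counts, roi_size=roi.roi_size)


def average_replicates(
    replicates: list[BirefringenceResult],
    patient_id: str = "",
) -> SampleResult:
    """Unweighted mean of total fraction and colour proportions over replicates.

    Replicates whose proportions are undefined (zero birefringent pixels)
    contribute to the total-fraction mean but not to the proportion means;
    if no replicate has birefringent pixels the sample's proportions are
    undefined (None).
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    total = float(np.mean([r.total_fraction for r in replicates]))
    defined = [r.proportions for r in replicates if r.proportions is not None]
    props = (
        {b: float(np.mean([p[b] for p in defined])) for b in BIN_NAMES}
        if defined
        else None
    )
    return SampleResult(
        patient_id=patient_id,
        replicates=tuple(replicates),
        total_fraction=total,
        proportions=props,
    )


def samples_to_frame(samples: list[SampleResult], groups: list[str] | None = None) -> pd.DataFrame:
    """Tidy one-row-per-patient table of averaged metrics."""
    rows = []
    for i, s in enumerate(samples):
        row: dict = {"patient_id": s.patient_id, "total_fraction": s.total_fraction}
        for b in BIN_NAMES:
            row[f"prop_{b}"] = s.proportions[b] if s.proportions is not None else np.nan
        if groups is not None:
            row["group"] = groups[i]
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_to_reference(
    samples: pd.DataFrame,
    reference_group: str,
    group_col: str = "group",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Divide each sample's per-bin proportion by the reference group's mean.

    Returns a copy of ``samples`` with added ``norm_<bin>`` columns. The
    reference group's normalized mean is exactly 1 in each bin by
    construction. The reference label is always explicit — it is the group
    plotted at 1.000 in the comparison figures, never inferred from the
    data. Samples with undefined proportions (NaN) stay NaN and are
    excluded from the reference mean.
    """
    if columns is None:
        columns = PROPORTION_COLUMNS
    if group_col not in samples.columns:
        raise ValueError(f"missing group column {group_col!r}")
    ref = samples[samples[group_col] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    out = samples.copy()
    for col in columns:
        ref_mean = ref[col].mean()
        if not np.isfinite(ref_mean) or ref_mean == 0:
            raise ValueError(
                f"reference group {reference_group!r} has zero or undefined mean in {col!r}"
            )
        out[col.replace("prop_", "norm_")] = out[col] / ref_mean
    return out
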