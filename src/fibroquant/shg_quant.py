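"""Second-harmonic-generation scoring: maximum-intensity projection and mean gray.

SHG optical sections of a core (typically 12-15 per stack) are flattened
into a maximum-intensity z-projection, and collagen content is the mean
gray intensity of the projection — over the whole field by default, or
over a user-supplied region mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SHGResult", "MAX_STACK_DEPTH", "max_project", "mean_gray"]

#: Largest accepted stack depth; acquisitions here use 12-15 sections.
MAX_STACK_DEPTH = 32


@dataclass(frozen=True)
class SHGResult:
    """Mean projected intensity over the scored region."""

    mean_gray: float
    region: str  # "whole" or "mask"
    n_pixels: int


def max_project(stack: np.ndarray, max_depth: int = MAX_STACK_DEPTH) -> np.ndarray:
    """Elementwise maximum across the z-axis of a Z x H x W stack."""
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise ValueError(f"expected Z x H x W stack, got shape {arr.shape}")
    z = arr.shape[0]
    if z < 1:
        raise ValueError("empty stack")
    if z > max_depth:
        raise ValueError(f"stack depth {z} exceeds maximum {max_depth}")
    if np.asarray(arr).min() < 0:
        raise ValueError("intensities must be nonnegative")
    return arr.max(axis=0)


def mean_gray(projection: np.ndarray, region: np.ndarray | None = None) -> SHGResult:
    """Arithmetic mean intensity of a projection, optionally within a mask."""
    proj = np.asarray(projection)
    if proj.ndim != 2:
        raise ValueError(f"expected 2-D projection, got shape {proj.shape}")
    if region is None:
        return SHGResult(mean_gray=float(proj.mean()), region="whole", n_pixels=proj.size)
    mask = np.asarray(region).astype(bool)
    if mask.shape != proj.shape:
        raise ValueError("region mask shape does not match projection")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("region mask is empty")
    return SHGResult(mean_gray=float(proj[mask].mean()), region="mask", n_pixels=n)
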