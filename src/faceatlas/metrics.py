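"""Segmentation agreement metrics: Dice overlap, average symmetric surface
distance (ASSD, mm) and pairwise percent volume difference.

Definitions
-----------
Dice(M1, M2)    = 2 |M1 ∩ M2| / (|M1| + |M2|)
ASSD(S1, S2)    = 1/2 ( mean_{x in S1} dist(x, S2) + mean_{y in S2} dist(y, S1) )
diffVol(V1, V2) = 2 |V1 - V2| / (V1 + V2), reported as a percentage

Surfaces are the sets of foreground voxels with at least one background
6-neighbour (the grid border counts as background); distances are Euclidean
between voxel centres in world millimetres, so anisotropic spacing is
honoured.  Distances are evaluated with a Euclidean distance transform on
the surface indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage

from .core import SegmentationMask

__all__ = [
    "SurfaceVoxelSet",
    "MetricsReport",
    "extract_surface",
    "surface_indicator",
    "dice",
    "assd",
    "volume_difference",
    "classify_overlap",
    "summarize",
    "compare_masks",
]

_FACES = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class SurfaceVoxelSet:
    """Boundary voxel centres of a segmentation, in world mm."""

    points: np.ndarray  # (n, 3) world coordinates
    indices: np.ndarray  # (n, 3) integer voxel indices
    spacing: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MetricsReport:
    """Agreement metrics for one pair of segmentations."""

    pair: tuple[str, str]
    dice: float
    assd_mm: float
    vol_diff_pct: float


def surface_indicator(m: SegmentationMask) -> np.ndarray:
    """Boolean grid of boundary voxels (6-neighbour rule, border = background)."""
    fg = m.labels.astype(bool)
    eroded = ndimage.binary_erosion(fg, structure=_FACES, border_value=0)
    return fg & ~eroded


def extract_surface(m: SegmentationMask) -> SurfaceVoxelSet:
    """All and only the boundary voxels of a non-empty mask, as world points."""
    if m.is_empty:
        raise ValueError("cannot extract the surface of an empty mask")
    idx = np.argwhere(surface_indicator(m))
    pts = np.asarray(m.origin) + idx * np.asarray(m.spacing)
    return SurfaceVoxelSet(points=pts, indices=idx, spacing=m.spacing)


def dice(m1: SegmentationMask, m2: SegmentationMask) -> float:
    """Dice overlap in [0, 1]; two empty masks are defined as identical (1)."""
    m1.require_same_grid(m2)
    n1, n2 = m1.voxel_count, m2.voxel_count
    if n1 == 0 and n2 == 0:
        warnings.warn("Dice of two empty masks defined as 1", stacklevel=2)
        return 1.0
    inter = int(np.count_nonzero(m1.labels & m2.labels))
    return 2.0 * inter / (n1 + n2)


def assd(m1: SegmentationMask, m2: SegmentationMask) -> float:
    """Average symmetric surface distance in mm (both masks must be non-empty)."""
    m1.require_same_grid(m2)
    if m1.is_empty or m2.is_empty:
        raise ValueError("ASSD is undefined for an empty mask")
    s1 = surface_indicator(m1)
    s2 = surface_indicator(m2)
    # distance from every voxel centre to the nearest surface voxel centre
    d_to_s2 = ndimage.distance_transform_edt(~s2, sampling=m1.spacing)
    d_to_s1 = ndimage.distance_transform_edt(~s1, sampling=m1.spacing)
    return 0.5 * (float(np.mean(d_to_s2[s1])) + float(np.mean(d_to_s1[s2])))


def volume_difference(m1: SegmentationMask, m2: SegmentationMask) -> float:
    """Pairwise percent volume difference 2|V1-V2|/(V1+V2) x 100, in [0, 200]."""
    v1, v2 = m1.physical_volume, m2.physical_volume
    if v1 == 0 and v2 == 0:
        raise ValueError("volume difference undefined for two empty masks")
    return 200.0 * abs(v1 - v2) / (v1 + v2)


def classify_overlap(
    d: float, good_threshold: float = 0.7, acceptable_threshold: float = 0.8
) -> str:
    """Label a Dice score: >= 0.8 'acceptable' (the stricter, internal bar),
    >= 0.7 'good', otherwise 'poor'."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"Dice score out of range [0, 1]: {d}")
    if d >= acceptable_threshold:
        return "acceptable"
    if d >= good_threshold:
        return "good"
    return "poor"


def summarize(values) -> tuple[float, float, float, float]:
    """(median, IQR, min, max) with linear-interpolation quantiles."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty list")
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return float(q50), float(q75 - q25), float(vals.min()), float(vals.max())


def compare_masks(
    m1: SegmentationMask, m2: SegmentationMask, pair: tuple[str, str] = ("a", "b")
) -> MetricsReport:
    """All three agreement metrics for one pair of masks."""
    return MetricsReport(
        pair=pair,
        dice=dice(m1, m2),
        assd_mm=assd(m1, m2),
        vol_diff_pct=volume_difference(m1, m2),
    )
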