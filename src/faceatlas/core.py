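"""Core grid types: 3D scalar volumes and binary segmentation masks.

Grid convention
---------------
Arrays are indexed ``(i, j, k)`` along the world ``(x, y, z)`` axes, voxel
indices are 0-based, orientation is identity, and the world coordinate of
voxel ``(i, j, k)`` is ``origin + index * spacing`` (millimetres).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Volume3D", "SegmentationMask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing!r}")
    return s


def _as_origin(origin) -> tuple[float, float, float]:
    o = tuple(float(v) for v in origin)
    if len(o) != 3:
        raise ValueError(f"origin must have 3 components, got {origin!r}")
    return o


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with anisotropic mm spacing and origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("intensity grid must be 3D with >=1 voxel per axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume3D | SegmentationMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "Volume3D | SegmentationMask") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centres."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing, self.origin)


@dataclass
class SegmentationMask:
    """A binary label grid aligned to a :class:`Volume3D` grid.

    ``voxel_count`` is |M|, the number of foreground voxels, and
    ``physical_volume`` is V = |M| x voxel volume in mm^3.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3 or min(lab.shape) < 1:
            raise ValueError("label grid must be 3D with >=1 voxel per axis")
        uniq = np.unique(lab)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"labels must be binary (0/1), found values {uniq[:10]}")
        self.labels = lab.astype(np.uint8)
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    # shared grid helpers
    shape = Volume3D.shape
    voxel_volume = Volume3D.voxel_volume
    same_grid = Volume3D.same_grid
    require_same_grid = Volume3D.require_same_grid
    world_coordinates = Volume3D.world_coordinates

    @property
    def data(self) -> np.ndarray:  # grid-duck-typing with Volume3D
        return self.labels

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    @property
    def physical_volume(self) -> float:
        return self.voxel_count * self.voxel_volume

    @property
    def is_empty(self) -> bool:
        return self.voxel_count == 0

    def copy(self) -> "SegmentationMask":
        return SegmentationMask(self.labels.copy(), self.spacing, self.origin)

    @classmethod
    def from_bool(cls, mask: np.ndarray, like: "Volume3D | SegmentationMask") -> "SegmentationMask":
        """Build a mask on the same grid as ``like``."""
        return cls(np.asarray(mask).astype(np.uint8), like.spacing, like.origin)
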