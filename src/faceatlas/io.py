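"""Read and write volumes and masks in NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd).

SimpleITK handles the on-disk formats; this module converts between its
``(z, y, x)`` array layout and the package's ``(x, y, z)`` convention and
assumes identity orientation (volumes axis-aligned before export).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import SegmentationMask, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "VolumeReadError",
    "NonVolumeError",
    "HeaderError",
]


class VolumeReadError(IOError):
    """Base class for image-reading failures."""


class NonVolumeError(VolumeReadError):
    """The file holds an image that is not a 3D volume."""


class HeaderError(VolumeReadError):
    """The file exists but its header cannot be parsed as an image."""


_SUPPORTED = (".nii", ".nii.gz", ".mha", ".mhd")


def read_volume(path: str | os.PathLike, as_mask: bool = False) -> Volume3D | SegmentationMask:
    """Read a 3D volume; with ``as_mask`` any value > 0.5 becomes label 1.

    Raises ``FileNotFoundError`` for a missing file, ``NonVolumeError`` for a
    non-3D image and ``HeaderError`` for an unreadable header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise HeaderError(f"cannot read image header of {path}: {exc}") from exc
    if img.GetDimension() != 3 or min(img.GetSize()) < 1:
        raise NonVolumeError(
            f"{path} is {img.GetDimension()}D with size {img.GetSize()}, expected 3D"
        )
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = img.GetSpacing()
    origin = img.GetOrigin()
    if as_mask:
        return SegmentationMask((arr > 0.5).astype(np.uint8), spacing, origin)
    return Volume3D(arr.astype(np.float64), spacing, origin)


def write_volume(vol: Volume3D | SegmentationMask, path: str | os.PathLike) -> None:
    """Write a volume or mask; spacing and origin go into the header.

    Masks are stored as unsigned 8-bit integers, intensities as float32.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    if isinstance(vol, SegmentationMask):
        arr = vol.labels.astype(np.uint8)
    else:
        arr = vol.data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))
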