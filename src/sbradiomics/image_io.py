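"""Volume/mask containers and NIfTI round-trip.

Internal grids are ordered (x, y, z), matching the axes of the NIfTI affine;
all physical quantities (distances, areas, volumes) use the header voxel
spacing in millimetres. The pipeline never resamples: a volume and its VOI
mask must live on the same grid, and a mismatch is an error rather than a
silent interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

#: spacing agreement tolerance between a volume and its mask, in mm
SPACING_TOL = 1e-4

#: mask voxels with value above this threshold count as foreground
FOREGROUND_THRESHOLD = 0.5


class GridMismatchError(ValueError):
    """Volume and mask do not share a grid (shape or spacing)."""


class EmptyMaskError(ValueError):
    """VOI mask has no foreground voxels."""


@dataclass
class VolumeImage:
    """A 3D scalar image with anisotropic voxel spacing.

    Parameters
    ----------
    values
        3D array of finite intensities, axes ordered (x, y, z).
    spacing
        Voxel edge lengths in mm along (x, y, z); all positive.
    origin
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class VoiMask:
    """A binary 3D volume-of-interest mask aligned to a :class:`VolumeImage`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={arr.ndim}")
        if arr.dtype != bool:
            arr = arr > FOREGROUND_THRESHOLD
        self.values = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not self.values.any():
            raise EmptyMaskError("empty VOI: mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(image: VolumeImage | VoiMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI with spacing encoded in the affine."""
    data = image.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(image.spacing, image.origin)), str(path))


def load_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI scalar volume; spacing comes from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeImage(data, zooms, origin)


def load_mask(path: str | Path) -> VoiMask:
    vol = load_volume(path)
    return VoiMask(vol.values, vol.spacing, vol.origin)


def check_aligned(volume: VolumeImage, mask: VoiMask) -> None:
    """Raise :class:`GridMismatchError` unless volume and mask share a grid."""
    if volume.shape != mask.shape:
        raise GridMismatchError(
            f"grid mismatch: volume shape {volume.shape} vs mask shape {mask.shape}"
        )
    if any(abs(a - b) > SPACING_TOL for a, b in zip(volume.spacing, mask.spacing)):
        raise GridMismatchError(
            f"grid mismatch: volume spacing {volume.spacing} vs mask {mask.spacing}"
        )


def load_case(
    volume_paths: Mapping[str, str | Path], mask_path: str | Path
) -> tuple[dict[str, VolumeImage], VoiMask]:
    """Load one case: a volume per sequence role plus its VOI mask.

    Parameters
    ----------
    volume_paths
        Mapping from sequence role (e.g. ``"GD"``, ``"T2"``) to NIfTI path.
    mask_path
        NIfTI path of the binary VOI mask.

    Returns
    -------
    (volumes, mask) with every volume verified to share the mask's grid.
    """
    mask = load_mask(mask_path)
    volumes: dict[str, VolumeImage] = {}
    for role, p in volume_paths.items():
        vol = load_volume(p)
        check_aligned(vol, mask)
        volumes[role] = vol
    return volumes, mask
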