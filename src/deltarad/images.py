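"""Geometric substrate: 3D image volumes with voxel spacing, and aligned binary ROI masks.

Volumes are plain float arrays indexed (x, y, z) with millimetre spacing per
axis.  NIfTI round-trips go through nibabel; the affine encodes spacing and
origin only (axis-aligned, no rotation), which is all this pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "RoiMask", "read_nifti_volume", "read_nifti_mask"]


class DegenerateRoiError(ValueError):
    """ROI mask has no foreground voxels where one is required."""


@dataclass
class ImageVolume:
    """3D intensity grid with physical spacing (mm) and origin (mm)."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.intensities.ndim}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.intensities.astype(np.float32), self.affine()), path)


@dataclass
class RoiMask:
    """Binary mask on the same grid as its companion :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.voxels.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self) -> None:
        if not self.voxels.any():
            raise DegenerateRoiError("ROI mask has no foreground voxels")

    def require_aligned(self, volume: ImageVolume) -> None:
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )

    def to_nifti(self, path: str) -> None:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), aff), path)


def read_nifti_volume(path: str) -> ImageVolume:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in np.asarray(img.affine)[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def read_nifti_mask(path: str) -> RoiMask:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RoiMask(np.asarray(img.dataobj) > 0.5, spacing)
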