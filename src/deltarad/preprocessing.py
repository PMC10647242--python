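"""Image preprocessing: isotropic resampling, Z-score intensity normalisation,
and a one-level separable 3D wavelet sub-band bank.

The wavelet transform is undecimated (stationary), so every sub-band keeps the
grid shape of the input and the ROI mask applies to every band unchanged.
Sub-band labels follow the per-axis filter convention with axis order (x, y, z):
``LHL`` means low-pass along x, high-pass along y, low-pass along z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .images import DegenerateRoiError, ImageVolume, RoiMask

__all__ = [
    "WAVELET_BAND_LABELS",
    "WaveletBank",
    "resample_isotropic",
    "znormalize",
    "wavelet_bank",
]

# Order matters: it fixes the feature-name catalog.
WAVELET_BAND_LABELS = ("LLL", "LLH", "LHL", "LHH", "HHL", "HLH", "HLL", "HHH")
ALL_BAND_LABELS = ("original",) + WAVELET_BAND_LABELS


class DegenerateIntensityError(ValueError):
    """Constant intensities where variation is required."""


@dataclass
class WaveletBank:
    """Ordered map band label -> ImageVolume; 'original' plus 8 sub-bands."""

    bands: dict[str, ImageVolume]

    def __post_init__(self) -> None:
        if tuple(self.bands) != ALL_BAND_LABELS:
            raise ValueError(
                f"band labels must be {ALL_BAND_LABELS}, got {tuple(self.bands)}"
            )
        shape = self.bands["original"].shape
        for label, vol in self.bands.items():
            if vol.shape != shape:
                raise ValueError(f"band {label} shape {vol.shape} != {shape}")

    def __getitem__(self, label: str) -> ImageVolume:
        return self.bands[label]

    def __iter__(self):
        return iter(self.bands.items())


def resample_isotropic(
    volume: ImageVolume,
    mask: RoiMask,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[ImageVolume, RoiMask]:
    """Resample a volume/mask pair onto an isotropic grid (default 1 mm³).

    Intensities are interpolated trilinearly, the mask with nearest neighbour
    so it stays binary.  Physical extent is preserved to within one voxel.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    mask.require_aligned(volume)

    if volume.spacing_mm == target_spacing:
        return volume, mask

    zoom = [old / new for old, new in zip(volume.spacing_mm, target_spacing)]
    new_shape = [max(1, int(round(n * z))) for n, z in zip(volume.shape, zoom)]
    # scipy's zoom maps the corner samples of the input grid onto the corners
    # of the output grid, which is the trilinear scheme the tests oracle-check.
    exact_zoom = [ns / n for ns, n in zip(new_shape, volume.shape)]
    out = ndimage.zoom(volume.intensities, exact_zoom, order=1, mode="nearest", grid_mode=False)
    out_mask = ndimage.zoom(mask.voxels.astype(np.uint8), exact_zoom, order=0, mode="nearest", grid_mode=False)

    new_volume = ImageVolume(out, target_spacing, volume.origin_mm)
    new_mask = RoiMask(out_mask > 0, target_spacing)
    if mask.voxels.any() and not new_mask.voxels.any():
        raise DegenerateRoiError("ROI vanished during resampling")
    return new_volume, new_mask


def znormalize(
    volume: ImageVolume,
    mask: RoiMask | None = None,
    scope: str = "whole_image",
) -> ImageVolume:
    """Z-score transform: subtract the mean and divide by the population SD.

    ``scope='whole_image'`` (default) uses all voxels; ``scope='roi'`` uses the
    ROI voxels to define mean/SD but rescales the whole grid.
    """
    if scope not in ("whole_image", "roi"):
        raise ValueError(f"scope must be 'whole_image' or 'roi', got {scope!r}")
    data = volume.intensities
    if scope == "roi":
        if mask is None:
            raise ValueError("scope='roi' requires a mask")
        mask.require_aligned(volume)
        mask.require_nonempty()
        sample = data[mask.voxels]
    else:
        sample = data
    mu = float(sample.mean())
    sigma = float(sample.std())  # population (n) convention
    if sigma == 0.0:
        raise DegenerateIntensityError("zero intensity variance in normalisation scope")
    return ImageVolume((data - mu) / sigma, volume.spacing_mm, volume.origin_mm)


def wavelet_bank(volume: ImageVolume, wavelet: str = "haar") -> WaveletBank:
    """One-level separable 3D stationary wavelet decomposition.

    Returns the original plus the 8 sub-bands LLL..HHH, every band full-size.
    Axis order for the label is (x, y, z); boundary handling is periodic
    extension after symmetric padding to even length per axis.
    """
    if any(n < 2 for n in volume.shape):
        raise ValueError(f"every axis needs >= 2 voxels, got shape {volume.shape}")

    data = volume.intensities
    pad = [(0, n % 2) for n in data.shape]  # swt needs even lengths
    padded = np.pad(data, pad, mode="symmetric")

    coeffs = pywt.swtn(padded, wavelet, level=1, norm=False)[0]
    # pywt labels per-axis with 'a' (approx/low) / 'd' (detail/high), axis 0 first.
    bands: dict[str, ImageVolume] = {
        "original": ImageVolume(data.copy(), volume.spacing_mm, volume.origin_mm)
    }
    crop = tuple(slice(0, n) for n in data.shape)
    for label in WAVELET_BAND_LABELS:
        key = "".join("a" if c == "L" else "d" for c in label)
        bands[label] = ImageVolume(coeffs[key][crop], volume.spacing_mm, volume.origin_mm)
    return WaveletBank(bands)
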