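"""In-memory containers for CT volumes and tumor masks, with NIfTI I/O.

A :class:`Volume` is a 3-D intensity grid with per-axis voxel spacing (mm)
and an origin offset; a :class:`Mask` is a binary ROI aligned to a volume's
grid. Volumes and masks round-trip through NIfTI-1 (``.nii`` / ``.nii.gz``)
via nibabel, with spacing carried on the affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "Mask", "load_volume", "load_mask", "save_volume", "save_mask"]


@dataclass
class Volume:
    """A 3-D scalar image with voxel spacing in millimetres."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.intensities.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class Mask:
    """A binary ROI on the same grid as its companion :class:`Volume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(bool)
        if self.labels.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.labels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.labels.sum())


def _affine(spacing_mm, origin) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.intensities.astype(np.float32), _affine(vol.spacing_mm, vol.origin))
    nib.save(img, str(path))


def save_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), _affine(mask.spacing_mm, mask.origin))
    nib.save(img, str(path))


def _load(path: str | Path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return data, spacing, origin


def load_volume(path: str | Path) -> Volume:
    data, spacing, origin = _load(path)
    return Volume(data.astype(np.float64), spacing, origin)


def load_mask(path: str | Path) -> Mask:
    data, spacing, origin = _load(path)
    return Mask(data > 0.5, spacing, origin)
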