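"""CT preprocessing: isotropic resampling, Z-score normalization, wavelet bank.

The preprocessing chain mirrors standard radiomics practice for texture
analysis on chest CT:

1. resample volume + ROI to isotropic 1 mm voxels (trilinear intensities,
   nearest-neighbour labels),
2. Z-score the intensities over the whole volume,
3. one-level separable 3-D wavelet filtering, low-pass (L) or high-pass (H)
   along each axis, yielding the eight subbands LLL ... HHH alongside the
   original image.

The wavelet transform is *undecimated* (stationary): every subband lives on
the same grid as the input, so a single ROI mask indexes all nine image sets.
Filter taps come from the Coiflet-1 wavelet with symmetric (reflect) boundary
handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .image import Mask, Volume

__all__ = [
    "SUBBAND_NAMES",
    "IMAGE_SET_NAMES",
    "WaveletBank",
    "resample_isotropic",
    "zscore_normalize",
    "wavelet_decompose",
]

#: the eight one-level subbands, in fixed (x, y, z) filter order
SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
#: the nine image sets features are computed on
IMAGE_SET_NAMES = ("original",) + SUBBAND_NAMES

_WAVELET = "coif1"


@dataclass
class WaveletBank:
    """Nine named image sets (original + eight subbands) on one shared grid."""

    image_sets: dict[str, Volume]

    def __post_init__(self) -> None:
        missing = set(IMAGE_SET_NAMES) - set(self.image_sets)
        if missing:
            raise ValueError(f"wavelet bank missing image sets: {sorted(missing)}")
        shapes = {v.shape for v in self.image_sets.values()}
        if len(shapes) != 1:
            raise ValueError(f"image sets disagree on grid shape: {shapes}")

    def __getitem__(self, name: str) -> Volume:
        return self.image_sets[name]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image_sets["original"].shape


def resample_isotropic(vol: Volume, mask: Mask, target_mm: float = 1.0) -> tuple[Volume, Mask]:
    """Resample a volume and its mask to isotropic ``target_mm`` voxels.

    Intensities are trilinearly interpolated; the mask is resampled with
    nearest-neighbour interpolation and re-binarized so labels stay crisp.

    Raises
    ------
    ValueError
        If the input mask is empty, or the mask vanishes under resampling.
    """
    if mask.voxel_count == 0:
        raise ValueError("cannot resample an empty mask")
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")

    factors = tuple(s / target_mm for s in vol.spacing_mm)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        out_spacing = (target_mm,) * 3
        return (
            Volume(vol.intensities.copy(), out_spacing, vol.origin),
            Mask(mask.labels.copy(), out_spacing, mask.origin),
        )

    intens = ndimage.zoom(vol.intensities, factors, order=1, mode="nearest")
    labels = ndimage.zoom(mask.labels.astype(np.uint8), factors, order=0, mode="nearest") > 0
    if not labels.any():
        raise ValueError("mask vanished under resampling; ROI smaller than one target voxel")
    out_spacing = (target_mm,) * 3
    return Volume(intens, out_spacing, vol.origin), Mask(labels, out_spacing, mask.origin)


def zscore_normalize(vol: Volume) -> Volume:
    """Standardize intensities to zero mean / unit SD over the whole volume."""
    if vol.intensities.size <= 1:
        raise ValueError("Z-score normalization needs more than one voxel")
    mu = float(vol.intensities.mean())
    sd = float(vol.intensities.std())
    if sd == 0.0:
        raise ValueError("volume has zero intensity variance; Z-score undefined")
    return Volume((vol.intensities - mu) / sd, vol.spacing_mm, vol.origin)


def _separable_filter(data: np.ndarray, taps: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    out = data
    for axis, t in enumerate(taps):
        out = ndimage.correlate1d(out, t, axis=axis, mode="reflect")
    return out


def wavelet_decompose(vol: Volume, wavelet: str = _WAVELET) -> WaveletBank:
    """One-level stationary 3-D wavelet decomposition into eight subbands.

    Each subband applies the wavelet's low- (L) or high-pass (H) analysis
    filter along x, y and z respectively; the subband name spells the filter
    applied per axis. All subbands keep the input grid.
    """
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo, dtype=np.float64)
    hi = np.asarray(w.dec_hi, dtype=np.float64)
    flen = len(lo)
    for axis, n in enumerate(vol.shape):
        if n < flen:
            raise ValueError(
                f"axis {axis} has length {n} < filter length {flen} for wavelet {wavelet}"
            )
    bank: dict[str, Volume] = {"original": Volume(vol.intensities.copy(), vol.spacing_mm, vol.origin)}
    for name in SUBBAND_NAMES:
        taps = tuple(lo if c == "L" else hi for c in name)
        sub = _separable_filter(vol.intensities, taps)
        bank[name] = Volume(sub, vol.spacing_mm, vol.origin)
    return WaveletBank(bank)
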