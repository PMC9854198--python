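"""Gray-level discretization of an ROI for matrix-based texture features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import Mask, Volume

__all__ = ["QuantizedROI", "discretize"]


@dataclass
class QuantizedROI:
    """Integer gray levels 1..n_levels on the ROI bounding box; 0 = outside mask.

    ``levels`` is the bounding-box subgrid so downstream matrix scans touch
    only the tumor neighbourhood, not the full volume.
    """

    levels: np.ndarray  # int grid, 0 outside mask
    n_levels: int
    voxel_count: int

    def __post_init__(self) -> None:
        inside = self.levels[self.levels > 0]
        if inside.size != self.voxel_count:
            raise ValueError("voxel_count inconsistent with levels grid")
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels outside [1, n_levels]")


def _bounding_box(labels: np.ndarray) -> tuple[slice, ...]:
    coords = np.nonzero(labels)
    return tuple(slice(int(c.min()), int(c.max()) + 1) for c in coords)


def discretize(vol: Volume, mask: Mask, n_bins: int = 32) -> QuantizedROI:
    """Fixed-bin-number quantization over the in-mask intensity range.

    Values are mapped to integer levels ``1..n_bins`` over the in-mask
    min-max range. A constant ROI collapses to a single level
    (``n_levels == 1``), which downstream features treat as degenerate.
    """
    if mask.voxel_count == 0:
        raise ValueError("cannot discretize an empty mask")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    box = _bounding_box(mask.labels)
    sub_int = vol.intensities[box]
    sub_lab = mask.labels[box]
    vals = sub_int[sub_lab]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(sub_int.shape, dtype=np.int32)
    if hi == lo:
        levels[sub_lab] = 1
        return QuantizedROI(levels, 1, int(sub_lab.sum()))
    q = np.floor((sub_int - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    np.clip(q, 1, n_bins, out=q)
    levels[sub_lab] = q[sub_lab]
    return QuantizedROI(levels, n_bins, int(sub_lab.sum()))
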