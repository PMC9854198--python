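"""Slice-wise rotation-invariant uniform local binary patterns (LBP).

LBP codes (8 neighbours, radius 1, riu2 coding → 10 possible codes) are
computed on each axial slice; codes at in-mask pixels with a full in-image
neighbourhood are pooled over all slices into one normalized histogram.
The 12 features are the 10 bin frequencies plus the mean and entropy of the
pooled code distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.feature import local_binary_pattern

from ..image import Mask, Volume

__all__ = ["LBP_FEATURE_NAMES", "lbp_features"]

_P, _R = 8, 1
_N_CODES = _P + 2  # riu2: codes 0..P uniform + one non-uniform bin

LBP_FEATURE_NAMES = tuple(f"bin{k}" for k in range(_N_CODES)) + ("code_mean", "code_entropy")


def lbp_features(vol: Volume, mask: Mask) -> dict[str, float]:
    """Pooled riu2 LBP histogram (normalized), code mean and code entropy.

    Axial slices are taken along the third axis. Pixels on the slice border
    lack a complete 8-neighbourhood and are excluded; if no in-mask pixel
    has a valid neighbourhood the ROI cannot be characterized and an error
    is raised.
    """
    if mask.voxel_count == 0:
        raise ValueError("LBP features need a non-empty mask")
    counts = np.zeros(_N_CODES, dtype=np.float64)
    interior = np.zeros(mask.shape[:2], dtype=bool)
    interior[1:-1, 1:-1] = True
    for k in range(mask.shape[2]):
        m = mask.labels[:, :, k] & interior
        if not m.any():
            continue
        with warnings.catch_warnings():
            # float input is intended: subbands are continuous-valued
            warnings.simplefilter("ignore", UserWarning)
            codes = local_binary_pattern(vol.intensities[:, :, k], _P, _R, method="uniform")
        np.add.at(counts, codes[m].astype(np.int64), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask pixel has a complete LBP neighbourhood")
    p = counts / total
    nz = p > 0
    feats = {f"bin{k}": float(p[k]) for k in range(_N_CODES)}
    feats["code_mean"] = float((np.arange(_N_CODES) * p).sum())
    feats["code_entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    return feats
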