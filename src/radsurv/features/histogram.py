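"""First-order (intensity histogram) features over the in-mask voxels."""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..image import Mask, Volume

__all__ = ["HISTOGRAM_FEATURE_NAMES", "histogram_features"]

HISTOGRAM_FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "range",
    "iqr",
    "energy",
    "entropy",
    "uniformity",
    "rms",
    "mad",
)

_N_BINS = 32


def histogram_features(vol: Volume, mask: Mask) -> dict[str, float]:
    """14 first-order features of the in-mask intensity distribution.

    Conventions: population (biased) variance; kurtosis is the plain fourth
    standardized moment (3 for a Gaussian); entropy/uniformity use a 32-bin
    histogram over the in-mask range with log base 2. A constant ROI has
    variance 0, entropy 0, uniformity 1; skewness/kurtosis are 0 there.
    """
    if mask.voxel_count == 0:
        raise ValueError("histogram features need a non-empty mask")
    x = vol.intensities[mask.labels]
    var = float(x.var())
    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0
    if x.min() == x.max():
        p = np.array([1.0])
    else:
        counts, _ = np.histogram(x, bins=_N_BINS)
        p = counts[counts > 0] / x.size
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "mean": float(x.mean()),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "iqr": float(q75 - q25),
        "energy": float((x**2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "uniformity": float((p**2).sum()),
        "rms": float(np.sqrt((x**2).mean())),
        "mad": float(np.abs(x - x.mean()).mean()),
    }
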