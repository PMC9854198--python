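"""Gray-level co-occurrence matrix (GLCM) texture features.

Co-occurrences are counted at distance 1 over the 13 unique 3-D directions,
each directional matrix is symmetrized and normalized, and the 13 matrices
are averaged into a single rotationally pooled GLCM from which the 22
features are computed. Entropic features use log base 2.
"""

from __future__ import annotations

import numpy as np

from .quantize import QuantizedROI

__all__ = ["GLCM_FEATURE_NAMES", "DIRECTIONS_3D", "glcm_matrix", "glcm_features"]

#: 13 unique distance-1 offsets covering the 26-neighbourhood up to sign
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "inverse_difference",
    "idn",
    "inverse_difference_moment",
    "idmn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
)


def _shifted_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Return (levels_at_p, levels_at_p+offset) for voxel pairs inside the grid."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, levels.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return levels[tuple(sl_a)], levels[tuple(sl_b)]


def glcm_matrix(q: QuantizedROI, directions=DIRECTIONS_3D) -> np.ndarray:
    """Direction-averaged symmetric normalized co-occurrence matrix p(i, j)."""
    ng = q.n_levels
    acc = np.zeros((ng, ng), dtype=np.float64)
    n_used = 0
    for off in directions:
        a, b = _shifted_pairs(q.levels, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        counts = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
        counts = counts + counts.T  # symmetrize
        acc += counts / counts.sum()
        n_used += 1
    if n_used == 0:
        # isolated voxels: no co-occurring pair in any direction
        acc[0, 0] = 1.0
        return acc
    return acc / n_used


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(q: QuantizedROI, directions=DIRECTIONS_3D) -> tuple[dict[str, float], dict]:
    """Compute the 22 GLCM features; returns (features, metadata).

    A single-gray-level ROI is degenerate: homogeneity-type features take
    their uniform limit (IDMN = 1, contrast = 0), entropy-type features 0;
    ``metadata['degenerate']`` flags this.
    """
    p = glcm_matrix(q, directions)
    ng = q.n_levels
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    diff = np.abs(ii - jj)
    # p_{x-y}(k), k = 0..ng-1 and p_{x+y}(k), k = 2..2ng
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.array([p[diff == k].sum() for k in range(ng)])
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in range(2, 2 * ng + 1)])

    joint_entropy = float(-_xlogx(p).sum())
    hx = float(-_xlogx(px).sum())
    pxpy = np.outer(px, px)
    lg = np.zeros_like(pxpy)
    nzm = pxpy > 0
    lg[nzm] = np.log2(pxpy[nzm])
    hxy1 = float(-(p * lg).sum())
    hxy2 = float(-(pxpy * lg).sum())

    if hx > 0:
        imc1 = (joint_entropy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    if sigma_x > 0:
        correlation = float(((ii - mu_x) * (jj - mu_x) * p).sum() / (sigma_x * sigma_x))
    else:
        correlation = 1.0

    inv_var_mask = diff > 0
    da = float((k_diff * p_diff).sum())

    feats = {
        "autocorrelation": float((ii * jj * p).sum()),
        "joint_average": mu_x,
        "cluster_prominence": float(((ii + jj - 2 * mu_x) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu_x) ** 3 * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu_x) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": float(-_xlogx(p_diff).sum()),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": joint_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "inverse_difference": float((p / (1.0 + diff)).sum()),
        "idn": float((p / (1.0 + diff / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "idmn": float((p / (1.0 + diff**2 / ng**2)).sum()),
        "inverse_variance": float((p[inv_var_mask] / diff[inv_var_mask] ** 2).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": float(-_xlogx(p_sum).sum()),
    }
    meta = {"degenerate": ng == 1, "n_levels": ng}
    return feats, meta
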