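"""Gray-level run-length matrix (GLRLM) texture features.

Runs of consecutive equal gray levels are extracted along each of the 13
unique 3-D directions; the 16 features are computed per directional matrix
and averaged across directions. Out-of-mask voxels terminate runs.
"""

from __future__ import annotations

import numpy as np

from .glcm import DIRECTIONS_3D
from .quantize import QuantizedROI

__all__ = ["GLRLM_FEATURE_NAMES", "run_length_matrix", "glrlm_features"]

GLRLM_FEATURE_NAMES = (
    "sre",
    "lre",
    "gln",
    "glnn",
    "rln",
    "rlnn",
    "rp",
    "glv",
    "rv",
    "re",
    "lglre",
    "hglre",
    "srlgle",
    "srhgle",
    "lrlgle",
    "lrhgle",
)


def _lines_along(levels: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Gather all grid lines along direction d into a 0-padded 2-D array."""
    shape = np.array(levels.shape)
    idx = np.indices(levels.shape).reshape(3, -1).T  # (V, 3)
    prev = idx - np.array(d)
    is_start = ((prev < 0) | (prev >= shape)).any(axis=1)
    starts = idx[is_start]  # (S, 3)
    # longest possible line along d
    max_len = 0
    for dk, n in zip(d, levels.shape):
        if dk != 0:
            max_len = max(max_len, n)
    t = np.arange(max_len)
    coords = starts[:, None, :] + t[None, :, None] * np.array(d)  # (S, T, 3)
    valid = ((coords >= 0) & (coords < shape)).all(axis=2)
    cc = np.clip(coords, 0, shape - 1)
    lines = levels[cc[..., 0], cc[..., 1], cc[..., 2]]
    lines[~valid] = 0
    return lines


def _rle(lines: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode rows of a 2-D array; returns (values, lengths), zeros dropped."""
    sep = np.zeros((lines.shape[0], 1), dtype=lines.dtype)
    flat = np.concatenate([sep, lines, sep], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    vals = flat[bounds[:-1]]
    lens = np.diff(bounds)
    keep = vals > 0
    return vals[keep], lens[keep]


def run_length_matrix(q: QuantizedROI, d: tuple[int, int, int]) -> np.ndarray:
    """R(i, j): count of runs of gray level i (rows) and length j (columns)."""
    vals, lens = _rle(_lines_along(q.levels, d))
    max_len = max(q.levels.shape)
    R = np.zeros((q.n_levels, max_len), dtype=np.float64)
    if vals.size:
        np.add.at(R, (vals - 1, lens - 1), 1.0)
    return R


def _features_one_direction(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = R.sum()
    if nr == 0:
        return {k: 0.0 for k in GLRLM_FEATURE_NAMES}
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    p = R / nr
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p > 0
    return {
        "sre": float((R / j**2).sum() / nr),
        "lre": float((R * j**2).sum() / nr),
        "gln": float((R.sum(axis=1) ** 2).sum() / nr),
        "glnn": float((R.sum(axis=1) ** 2).sum() / nr**2),
        "rln": float((R.sum(axis=0) ** 2).sum() / nr),
        "rlnn": float((R.sum(axis=0) ** 2).sum() / nr**2),
        "rp": float(nr / n_voxels),
        "glv": float((p * (i - mu_i) ** 2).sum()),
        "rv": float((p * (j - mu_j) ** 2).sum()),
        "re": float(-(p[nz] * np.log2(p[nz])).sum()),
        "lglre": float((R / i**2).sum() / nr),
        "hglre": float((R * i**2).sum() / nr),
        "srlgle": float((R / (i**2 * j**2)).sum() / nr),
        "srhgle": float((R * i**2 / j**2).sum() / nr),
        "lrlgle": float((R * j**2 / i**2).sum() / nr),
        "lrhgle": float((R * i**2 * j**2).sum() / nr),
    }


def glrlm_features(q: QuantizedROI, directions=DIRECTIONS_3D) -> tuple[dict[str, float], dict]:
    """16 run-length features averaged over the 13 directional matrices."""
    per_dir = [_features_one_direction(run_length_matrix(q, d), q.voxel_count) for d in directions]
    feats = {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURE_NAMES}
    meta = {"degenerate": q.n_levels == 1, "n_levels": q.n_levels}
    return feats, meta
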