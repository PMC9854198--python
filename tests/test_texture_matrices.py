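"""GLCM / GLRLM features against exhaustive brute-force oracles.

The oracles enumerate co-occurring voxel pairs and same-level runs by
explicit python loops and compute each feature from its defining formula,
independently of the vectorized implementation.
"""

import numpy as np
import pytest

from radsurv.features.glcm import DIRECTIONS_3D, glcm_features, glcm_matrix
from radsurv.features.glrlm import glrlm_features, run_length_matrix
from radsurv.features.quantize import QuantizedROI

# ------------------------------------------------------------- oracles ---


def brute_glcm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Naive O(voxels x offsets) pair enumeration, symmetrized, averaged."""
    shape = levels.shape
    acc = np.zeros((n_levels, n_levels))
    n_used = 0
    for d in DIRECTIONS_3D:
        counts = np.zeros((n_levels, n_levels))
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    a = levels[i, j, k]
                    if a == 0:
                        continue
                    ii, jj, kk = i + d[0], j + d[1], k + d[2]
                    if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                        continue
                    b = levels[ii, jj, kk]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
        if counts.sum() > 0:
            acc += counts / counts.sum()
            n_used += 1
    return acc / n_used if n_used else acc


def brute_glcm_features(p: np.ndarray) -> dict:
    ng = p.shape[0]
    f = {k: 0.0 for k in (
        "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
        "cluster_tendency", "contrast", "joint_energy", "joint_entropy",
        "inverse_difference", "idn", "inverse_difference_moment", "idmn",
        "inverse_variance", "maximum_probability", "sum_average", "sum_entropy",
        "difference_average", "difference_entropy", "difference_variance",
        "correlation", "imc1", "imc2",
    )}
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    px = p.sum(axis=1)
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            gi, gj = i + 1, j + 1
            f["autocorrelation"] += gi * gj * v
            f["joint_average"] += gi * v
            f["cluster_prominence"] += (gi + gj - 2 * mu) ** 4 * v
            f["cluster_shade"] += (gi + gj - 2 * mu) ** 3 * v
            f["cluster_tendency"] += (gi + gj - 2 * mu) ** 2 * v
            f["contrast"] += (gi - gj) ** 2 * v
            f["joint_energy"] += v**2
            if v > 0:
                f["joint_entropy"] -= v * np.log2(v)
            f["inverse_difference"] += v / (1 + abs(gi - gj))
            f["idn"] += v / (1 + abs(gi - gj) / ng)
            f["inverse_difference_moment"] += v / (1 + (gi - gj) ** 2)
            f["idmn"] += v / (1 + (gi - gj) ** 2 / ng**2)
            if gi != gj:
                f["inverse_variance"] += v / (gi - gj) ** 2
            p_sum[gi + gj] += v
            p_diff[abs(gi - gj)] += v
    f["maximum_probability"] = p.max()
    f["sum_average"] = sum(k * v for k, v in p_sum.items())
    f["sum_entropy"] = -sum(v * np.log2(v) for v in p_sum.values() if v > 0)
    da = sum(k * v for k, v in p_diff.items())
    f["difference_average"] = da
    f["difference_entropy"] = -sum(v * np.log2(v) for v in p_diff.values() if v > 0)
    f["difference_variance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
    if sigma2 > 0:
        f["correlation"] = sum(
            (i + 1 - mu) * (j + 1 - mu) * p[i, j] for i in range(ng) for j in range(ng)
        ) / sigma2
    else:
        f["correlation"] = 1.0
    hx = -sum(v * np.log2(v) for v in px if v > 0)
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng) if px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * np.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng) if px[i] * px[j] > 0
    )
    f["imc1"] = (f["joint_entropy"] - hxy1) / hx if hx > 0 else 0.0
    f["imc2"] = float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - f["joint_entropy"])))))
    return f


def brute_runs(levels: np.ndarray, d) -> dict:
    """Enumerate maximal same-level runs along direction d by walking lines."""
    shape = levels.shape
    runs: dict[tuple[int, int], int] = {}
    visited = set()
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                prev = (i - d[0], j - d[1], k - d[2])
                if all(0 <= prev[a] < shape[a] for a in range(3)):
                    continue  # not a line start
                # walk the whole line
                pos = (i, j, k)
                line = []
                while all(0 <= pos[a] < shape[a] for a in range(3)):
                    line.append(levels[pos])
                    pos = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
                idx = 0
                while idx < len(line):
                    v = line[idx]
                    ln = 1
                    while idx + ln < len(line) and line[idx + ln] == v:
                        ln += 1
                    if v > 0:
                        runs[(v, ln)] = runs.get((v, ln), 0) + 1
                    idx += ln
    return runs


def _random_qroi(rng, shape=(4, 4, 4), n_levels=4, p_mask=0.8) -> QuantizedROI:
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[0, 0, 0] = True
    levels = np.where(mask, rng.integers(1, n_levels + 1, size=shape), 0).astype(np.int32)
    return QuantizedROI(levels, n_levels, int(mask.sum()))


# --------------------------------------------------------------- tests ---


@pytest.mark.parametrize("seed", range(5))
def test_glcm_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    q = _random_qroi(rng, shape=(5, 4, 3))
    np.testing.assert_allclose(
        glcm_matrix(q), brute_glcm_matrix(q.levels, q.n_levels), atol=1e-12
    )
    feats, _ = glcm_features(q)
    oracle = brute_glcm_features(brute_glcm_matrix(q.levels, q.n_levels))
    assert set(feats) == set(oracle)
    for k in oracle:
        assert feats[k] == pytest.approx(oracle[k], abs=1e-10), k


def test_glcm_2x2_worked_example():
    levels = np.array([[1, 2], [2, 1]], dtype=np.int32).reshape(2, 2, 1)
    q = QuantizedROI(levels, 2, 4)
    feats, _ = glcm_features(q)
    oracle = brute_glcm_features(brute_glcm_matrix(levels, 2))
    for k in oracle:
        assert feats[k] == pytest.approx(oracle[k], abs=1e-12), k


def test_glcm_single_level_degenerate():
    q = QuantizedROI(np.ones((3, 3, 3), dtype=np.int32), 1, 27)
    feats, meta = glcm_features(q)
    assert meta["degenerate"]
    assert feats["idmn"] == 1.0
    assert feats["contrast"] == 0.0
    assert feats["joint_energy"] == 1.0
    assert feats["joint_entropy"] == 0.0


@pytest.mark.parametrize("seed", range(3))
def test_glcm_bounds_and_translation_invariance(seed):
    rng = np.random.default_rng(seed + 100)
    q = _random_qroi(rng, shape=(4, 4, 4))
    feats, _ = glcm_features(q)
    assert 0 < feats["idmn"] <= 1.0 + 1e-12
    assert 0 < feats["maximum_probability"] <= 1.0
    # embed the same ROI elsewhere in a larger grid
    big = np.zeros((10, 10, 10), dtype=np.int32)
    big[3:7, 2:6, 4:8] = q.levels
    q2 = QuantizedROI(big, q.n_levels, q.voxel_count)
    feats2, _ = glcm_features(q2)
    for k in feats:
        assert feats[k] == pytest.approx(feats2[k], abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_glrlm_matches_brute_force(seed):
    rng = np.random.default_rng(seed + 50)
    q = _random_qroi(rng, shape=(4, 5, 3))
    for d in DIRECTIONS_3D:
        R = run_length_matrix(q, d)
        runs = brute_runs(q.levels, d)
        R_oracle = np.zeros_like(R)
        for (lvl, ln), cnt in runs.items():
            R_oracle[lvl - 1, ln - 1] = cnt
        np.testing.assert_array_equal(R, R_oracle)


def test_glrlm_constant_plane_single_runs():
    # 4x4x1 constant ROI: along +x there are 4 runs of length 4
    q = QuantizedROI(np.ones((4, 4, 1), dtype=np.int32), 1, 16)
    R = run_length_matrix(q, (1, 0, 0))
    assert R[0, 3] == 4 and R.sum() == 4
    nr = R.sum()
    j = np.arange(1, R.shape[1] + 1)
    sre = float((R.sum(axis=0) / j**2).sum() / nr)
    lre = float((R.sum(axis=0) * j**2).sum() / nr)
    assert sre == pytest.approx(1 / 16)
    assert lre == pytest.approx(16.0)


def test_glrlm_alternating_levels_rp_one():
    line = np.tile(np.array([1, 2], dtype=np.int32), 8)[:12].reshape(12, 1, 1)
    q = QuantizedROI(line, 2, 12)
    R = run_length_matrix(q, (1, 0, 0))
    assert R[:, 0].sum() == 12  # every run has length 1
    assert float(R.sum() / q.voxel_count) == 1.0


@pytest.mark.parametrize("seed", range(3))
def test_glrlm_runs_partition_voxels(seed):
    rng = np.random.default_rng(seed + 200)
    q = _random_qroi(rng, shape=(5, 5, 4))
    j = np.arange(1, max(q.levels.shape) + 1)
    for d in DIRECTIONS_3D:
        R = run_length_matrix(q, d)
        assert int((R * j[None, :]).sum()) == q.voxel_count


def test_glrlm_feature_names_and_degenerate():
    q = QuantizedROI(np.ones((3, 3, 1), dtype=np.int32), 1, 9)
    feats, meta = glrlm_features(q)
    assert len(feats) == 16
    assert meta["degenerate"]
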