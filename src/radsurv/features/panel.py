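"""Assembly of the full 593-feature radiomic panel per ROI.

Per image set (original + eight wavelet subbands): 14 histogram + 22 GLCM +
16 GLRLM + 12 LBP features, named ``<imageset>_<family>_<feature>``; plus
17 geometry features of the original mask, named ``shape_<feature>``.
9 × 64 + 17 = 593 features in a fixed, deterministic order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..image import Mask
from ..preprocess import IMAGE_SET_NAMES, WaveletBank
from .geometry import GEOMETRY_FEATURE_NAMES, geometry_features
from .glcm import GLCM_FEATURE_NAMES, glcm_features
from .glrlm import GLRLM_FEATURE_NAMES, glrlm_features
from .histogram import HISTOGRAM_FEATURE_NAMES, histogram_features
from .lbp import LBP_FEATURE_NAMES, lbp_features
from .quantize import discretize

__all__ = ["FEATURE_NAMES", "N_FEATURES", "extract_all", "extract_cohort"]


def _build_names() -> tuple[str, ...]:
    names: list[str] = []
    for img in IMAGE_SET_NAMES:
        names += [f"{img}_hist_{f}" for f in HISTOGRAM_FEATURE_NAMES]
        names += [f"{img}_glcm_{f}" for f in GLCM_FEATURE_NAMES]
        names += [f"{img}_glrlm_{f}" for f in GLRLM_FEATURE_NAMES]
        names += [f"{img}_lbp_{f}" for f in LBP_FEATURE_NAMES]
    names += [f"shape_{f}" for f in GEOMETRY_FEATURE_NAMES]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_names()
N_FEATURES: int = len(FEATURE_NAMES)
assert N_FEATURES == 593


def extract_all(bank: WaveletBank, mask: Mask, n_bins: int = 32) -> tuple[dict[str, float], dict]:
    """Extract the full 593-feature vector for one ROI.

    Returns ``(features, metadata)``; metadata records the gray-level bin
    count and any degenerate-ROI flags per image set. Geometry is computed
    once on the original-resolution mask.
    """
    if bank.shape != mask.shape:
        raise ValueError(f"bank grid {bank.shape} != mask grid {mask.shape}")
    feats: dict[str, float] = {}
    meta: dict = {"n_bins": n_bins, "degenerate_texture": [], "degenerate_shape": False}
    for img in IMAGE_SET_NAMES:
        vol = bank[img]
        try:
            hist = histogram_features(vol, mask)
            q = discretize(vol, mask, n_bins)
            glcm, m1 = glcm_features(q)
            glrlm, m2 = glrlm_features(q)
            lbp = lbp_features(vol, mask)
        except ValueError as exc:
            raise ValueError(f"feature extraction failed on image set {img!r}: {exc}") from exc
        if m1["degenerate"]:
            meta["degenerate_texture"].append(img)
        for fam, d in (("hist", hist), ("glcm", glcm), ("glrlm", glrlm), ("lbp", lbp)):
            for k, v in d.items():
                feats[f"{img}_{fam}_{k}"] = v
    geo, gmeta = geometry_features(mask)
    meta["degenerate_shape"] = gmeta["degenerate"]
    for k, v in geo.items():
        feats[f"shape_{k}"] = v
    out = {name: feats[name] for name in FEATURE_NAMES}
    if not all(np.isfinite(list(out.values()))):
        bad = [k for k, v in out.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite features: {bad[:5]}")
    return out, meta


def extract_cohort(banks, masks, patient_ids, n_bins: int = 32) -> pd.DataFrame:
    """Feature matrix for a cohort: rows = patients, 593 feature columns."""
    rows = []
    for pid, bank, mask in zip(patient_ids, banks, masks):
        feats, _ = extract_all(bank, mask, n_bins)
        feats["patient_id"] = pid
        rows.append(feats)
    df = pd.DataFrame(rows).set_index("patient_id")
    return df[list(FEATURE_NAMES)]
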