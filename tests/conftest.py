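import numpy as np
import pandas as pd
import pytest

from radsurv.image import Mask, Volume
from radsurv.synthetic import CohortConfig, simulate_tabular_cohort


@pytest.fixture(scope="session")
def sphere_mask() -> Mask:
    """Digitized ball of radius 10 mm on a 48-voxel 1 mm grid."""
    g = np.indices((48, 48, 48)) - 23.5
    return Mask((g**2).sum(axis=0) <= 100.0)


@pytest.fixture(scope="session")
def cube_mask() -> Mask:
    m = np.zeros((24, 24, 24), dtype=bool)
    m[2:22, 2:22, 2:22] = True
    return Mask(m)


@pytest.fixture(scope="session")
def ellipsoid_mask() -> Mask:
    """Solid ellipsoid with semi-axes (20, 8, 6) mm."""
    g = np.indices((64, 64, 64)) - 31.5
    return Mask((g[0] / 20) ** 2 + (g[1] / 8) ** 2 + (g[2] / 6) ** 2 <= 1.0)


@pytest.fixture(scope="session")
def tabular_cohort():
    """Signal-bearing image-free cohort (n=400) shared by model-level tests."""
    cfg = CohortConfig(n_patients=400, seed=5)
    feats, clin, out, truth = simulate_tabular_cohort(cfg)
    return feats, clin, out, truth


@pytest.fixture(scope="session")
def null_tabular_cohort():
    cfg = CohortConfig(
        n_patients=2000,
        beta_compactness=0.0, beta_texture=0.0, beta_n_stage=0.0,
        beta_m_stage=0.0, beta_histology=0.0, seed=11,
    )
    feats, clin, out, truth = simulate_tabular_cohort(cfg)
    return feats, clin, out, truth


def make_outcomes(times, events) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(len(times))],
            "pfs_months": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
        }
    )
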