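import numpy as np
import pandas as pd
import pytest

from leaflet_smlm import ROI, SceneConfig, gen_clustered_scene, gen_csr


@pytest.fixture(scope="session")
def roi_default() -> ROI:
    return ROI.default()


@pytest.fixture(scope="session")
def roi_small() -> ROI:
    return ROI(0.0, 0.0, 2000.0, 2000.0)


@pytest.fixture(scope="session")
def csr_small(roi_small) -> pd.DataFrame:
    return gen_csr(500, roi_small, seed=11)


@pytest.fixture(scope="session")
def clustered_scene(roi_default):
    """Default-parameter clustered scene with ground truth."""
    config = SceneConfig(seed=5)
    table, truth = gen_clustered_scene(config, roi_default)
    return config, table, truth


@pytest.fixture()
def loc_table() -> pd.DataFrame:
    rng = np.random.default_rng(3)
    n = 40
    return pd.DataFrame(
        {
            "frame": rng.integers(1, 100, size=n),
            "x": rng.uniform(0, 1000, size=n),
            "y": rng.uniform(0, 1000, size=n),
            "uncertainty": rng.uniform(10, 30, size=n),
            "intensity": rng.uniform(100, 5000, size=n),
        }
    )
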