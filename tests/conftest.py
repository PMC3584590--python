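import numpy as np
import pandas as pd
import pytest

from tmaprog import synthetic_data
from tmaprog.preprocessing import load_antibody_panel


@pytest.fixture(scope="session")
def antibody_panel() -> pd.DataFrame:
    return load_antibody_panel()


@pytest.fixture()
def small_cohort():
    """Planted two-group cohort at study-sized dimensions, complete case."""
    matrix, truth = synthetic_data.generate_cohort_matrix(
        n_patients=56,
        n_features=108,
        n_planted=10,
        effect=2.0,
        group_sizes=(19, 37),
        missing_rate=0.0,
        seed=7,
    )
    return matrix, truth


@pytest.fixture()
def separated_blobs():
    """Two well-separated planar point clouds with known membership."""
    rng = np.random.default_rng(3)
    a = rng.normal((0.0, 0.0), 0.3, size=(20, 2))
    b = rng.normal((8.0, 8.0), 0.3, size=(25, 2))
    coords = np.vstack([a, b])
    labels = np.array([1] * 20 + [2] * 25)
    return coords, labels
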