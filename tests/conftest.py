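import numpy as np
import pandas as pd
import pytest

from holosphere.feature_table import FeatureTable
from holosphere.synthetic_data import SimConfig, simulate_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_table():
    """Hand-built 3-feature, 6-sample table (one species, 3 distances × 2)."""
    features = pd.DataFrame(
        {"mz": [301.2721, 448.2097, 150.0500], "rt": [2.0, 5.0, 8.0]},
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
    )
    samples = pd.DataFrame(
        {
            "species": ["Acropora"] * 6,
            "colony": ["c1", "c2"] * 3,
            "distance": [0.0, 0.0, 5.0, 5.0, 50.0, 50.0],
            "health": ["healthy", "diseased"] * 3,
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    intensities = pd.DataFrame(
        [
            [1000.0, 1100.0, 800.0, 900.0, 600.0, 650.0],
            [5000.0, 5200.0, 5100.0, 4900.0, 5050.0, 4950.0],
            [0.0, 0.0, 700.0, 600.0, 0.0, 0.0],
        ],
        index=features.index,
        columns=samples.index,
    )
    return FeatureTable(features=features, samples=samples, intensities=intensities)


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort shared by read-only tests (seed 0)."""
    return simulate_feature_table(SimConfig(seed=0))
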