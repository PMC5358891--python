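import numpy as np
import pandas as pd
import pytest

from lpscourse import ExpressionTable, SimConfig, TimeCourseTensor


@pytest.fixture
def small_config():
    """A small but otherwise default-noise simulation configuration."""
    return SimConfig(n_features=200, n_enhancers=40, seed=42)


@pytest.fixture
def noiseless_config():
    """No donor effects, no cell noise, no counting: tensors equal their
    archetype mean profiles exactly."""
    return SimConfig(
        n_features=60,
        n_enhancers=20,
        donor_noise_cv=0.0,
        donor_effect_cv=0.0,
        count_dispersion=0.0,
        library_size=0,
        spike_rate=0.0,
        seed=7,
    )


@pytest.fixture
def tiny_tensor():
    """3 features x 4 timepoints x 3 donors with constant value 10."""
    values = np.full((3, 4, 3), 10.0)
    return TimeCourseTensor(
        ["a", "b", "c"], np.array([0, 15, 30, 45]), ["d1", "d2", "d3"], values
    )


@pytest.fixture
def design_2x2():
    return pd.DataFrame(
        {
            "sample_id": ["m1", "m2", "k1", "k2"],
            "donor": ["d1", "d2", "d1", "d2"],
            "timepoint_minutes": [None] * 4,
            "condition_group": [
                "unstimulated_monocyte",
                "unstimulated_monocyte",
                "unstimulated_MDM",
                "unstimulated_MDM",
            ],
        }
    )


def make_table(values, features=None, samples=None, unit="tpm"):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionTable(pd.DataFrame(values, index=features, columns=samples), unit)
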