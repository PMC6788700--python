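import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ufa import Dataset, GeneratorConfig, PlantedThresholdSpec, generate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def planted_dataset():
    """n=2000, one strong below-median high-risk threshold at 0.2, two noise vars."""
    cfg = GeneratorConfig(
        n=2000,
        seed=7,
        planted=(
            PlantedThresholdSpec("v1", "below", tail_rate=0.8, cut_quantile=0.2),
        ),
        n_noise=2,
        base_rate=0.2,
    )
    data, truth = generate(cfg)
    return data, truth


@pytest.fixture
def two_sided_dataset():
    """Two variables, each with a below- and an above-median planted effect."""
    cfg = GeneratorConfig(
        n=4000,
        seed=11,
        planted=(
            PlantedThresholdSpec("a", "below", tail_rate=0.7, cut_quantile=0.15),
            PlantedThresholdSpec("a", "above", tail_rate=0.02, cut_quantile=0.85),
            PlantedThresholdSpec("b", "below", tail_rate=0.7, cut_quantile=0.15),
            PlantedThresholdSpec("b", "above", tail_rate=0.02, cut_quantile=0.85),
        ),
        base_rate=0.25,
    )
    data, truth = generate(cfg)
    return data, truth


@pytest.fixture
def tiny_dataset():
    X = pd.DataFrame(
        {
            "u": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8],
            "w": [1.0, np.nan, 3.0, 4.0, 5.0, 6.0, np.nan, 8.0],
        }
    )
    y = pd.Series([1, 0, 0, 1, 0, 1, 0, 1])
    return Dataset(X, y)
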