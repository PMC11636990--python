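import numpy as np
import pytest

from hydrosoil.data import LabeledTable, SyntheticConfig, generate_synthetic_dataset


@pytest.fixture
def separable_table() -> LabeledTable:
    """Well-separated two-class phytohormone panel (5 compounds + 5 noise)."""
    cfg = SyntheticConfig(
        n_samples=400, n_compounds=5, n_noise_features=5, effect_size=3.0, seed=42
    )
    return generate_synthetic_dataset(cfg)


@pytest.fixture
def small_table() -> LabeledTable:
    """Tiny fixed table for exact hand-checkable assertions."""
    features = np.array(
        [[0.0, 5.0], [0.1, 4.0], [1.0, 5.5], [0.9, 4.5]]
    )
    return LabeledTable(
        features, ["a", "b"], np.array(["soil", "soil", "hydroponic", "hydroponic"])
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
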