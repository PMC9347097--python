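from pathlib import Path

import numpy as np
import pytest

from msadta.model import ModelConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def toy_dense_dir() -> Path:
    return DATA_DIR / "toy_dense"


@pytest.fixture
def small_config() -> ModelConfig:
    """A config small enough for second-scale training in unit tests."""
    return ModelConfig(
        l_d=12, l_p=12, e_d=16, e_p=16, n_heads=4, window_sizes=(0, 1, 2, 3),
        L_d=1, L_p=1, ffn_hidden=(64, 64, 32, 1), dropout=0.0,
        learning_rate=1e-3, epochs=5, batch_size=16,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
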