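import numpy as np
import pytest

from iriscap import ARModel


@pytest.fixture
def ar1_model() -> ARModel:
    """AR(1) with alpha=0.5, unit innovation variance (closed forms known)."""
    return ARModel(order=1, coeffs=(0.5,), noise_variance=1.0)


@pytest.fixture
def ar2_model() -> ARModel:
    """AR(2) with alpha=(0.75, -0.5): complex poles, peaked spectrum."""
    return ARModel(order=2, coeffs=(0.75, -0.5), noise_variance=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240427)
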