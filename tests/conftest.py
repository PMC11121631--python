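import numpy as np
import pytest

from n1loc.n1nn_core import N1NNConfig, init_params
from n1loc.records import LocalizationClass, ProteinRecord


@pytest.fixture
def tiny_config():
    """Small network with one hidden kernel, 22-wide input."""
    return N1NNConfig(c=1, gamma=1, n_hidden_kernels=1, input_width=22,
                      kernel_hidden_units=4, state_units=3, fc_hidden_units=4)


@pytest.fixture
def tiny_params(tiny_config):
    return init_params(tiny_config, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def labeled_records():
    classes = list(LocalizationClass)
    return [
        ProteinRecord(id=f"p{i}", sequence="ACDEFGHIKLMNPQRSTVWY" * 2,
                      label=classes[i % len(classes)])
        for i in range(20)
    ]


def random_onehot(rng, n, width=22):
    """Random one-hot rows over the first 21 columns (gap column zero)."""
    x = np.zeros((n, width))
    cols = rng.integers(0, 21, size=n)
    x[np.arange(n), cols] = 1.0
    return x
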