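import numpy as np
import pytest

from fibroquant.io_cli import load_config


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140902)


def random_rgb(rng: np.random.Generator, shape=(32, 32)) -> np.ndarray:
    return rng.integers(0, 256, size=(*shape, 3), dtype=np.uint8)
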