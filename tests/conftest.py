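import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def filled_square():
    return np.ones((64, 64), dtype=bool)


@pytest.fixture
def carpet():
    from fractopath.synthetic import make_sierpinski

    return make_sierpinski(4)  # 81x81, D0 = log 8 / log 3


@pytest.fixture
def random_mask(rng):
    return rng.random((48, 48)) < 0.3
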