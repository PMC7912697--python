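import numpy as np
import pytest

from scanpath_ais.preprocessing import Scanpath
from scanpath_ais.synthetic import MarkovModel


def make_scanpath(symbols, alphabet_size=None, **labels):
    symbols = np.asarray(symbols, dtype=np.int64)
    if alphabet_size is None:
        alphabet_size = int(symbols.max()) + 1
    return Scanpath(symbols=symbols, alphabet_size=alphabet_size, **labels)


@pytest.fixture
def binary_sticky_model():
    """Order-1 binary chain with stay-probability 0.9 (analytic AIS known)."""
    return MarkovModel(
        order=1, alphabet_size=2, transitions=np.array([[0.9, 0.1], [0.1, 0.9]])
    )


@pytest.fixture
def cycle4_model():
    """Deterministic 4-cycle: AIS = 2 bits, transition entropy = 0."""
    t = np.zeros((4, 4))
    for i in range(4):
        t[i, (i + 1) % 4] = 1.0
    return MarkovModel(order=1, alphabet_size=4, transitions=t)


@pytest.fixture
def iid_uniform4_model():
    return MarkovModel(order=0, alphabet_size=4, transitions=np.full(4, 0.25))
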