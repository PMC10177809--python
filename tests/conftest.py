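import numpy as np
import pytest

from m6aminer.sequence_io import SequenceWindow
from m6aminer.synthetic import GeneratorSpec, generate, golden_fixture

ALPHABET = "ACGU"


def random_window(rng: np.random.Generator, length: int, wid: str = "w") -> SequenceWindow:
    bases = "".join(rng.choice(list(ALPHABET), size=length))
    return SequenceWindow(wid, bases)


@pytest.fixture(scope="session")
def golden():
    return golden_fixture()


@pytest.fixture(scope="session")
def poly_a(golden):
    return golden.windows[0]  # 41 A's


@pytest.fixture(scope="session")
def small_signal_dataset():
    """400+400 windows with a strong planted motif: cheap but learnable."""
    return generate(GeneratorSpec(n_pos=400, n_neg=400, effect_size=1.0, seed=11))


@pytest.fixture(scope="session")
def small_signal_xy(small_signal_dataset):
    from m6aminer.encoders import encode_matrix

    X = encode_matrix(small_signal_dataset.windows)
    y = np.array([w.label for w in small_signal_dataset.windows])
    return X, y
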