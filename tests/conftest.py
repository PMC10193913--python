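import numpy as np
import pytest

from seqflex import (
    FlexibilityScale,
    WindowSpec,
    default_window,
    load_flex_scale,
)
from seqflex.seq_io import CANONICAL_RESIDUES


@pytest.fixture(scope="session")
def default_scale():
    return load_flex_scale("default")


@pytest.fixture(scope="session")
def raw_scale():
    return load_flex_scale("vihinen")


@pytest.fixture
def toy_scale():
    """Simple hand-checkable scale: G=3, V=2, everything else 1."""
    values = {aa: 1.0 for aa in CANONICAL_RESIDUES}
    values["G"] = 3.0
    values["V"] = 2.0
    return FlexibilityScale(values=values, provenance="toy")


@pytest.fixture
def window3():
    return default_window()


@pytest.fixture
def window1():
    return WindowSpec(width=1, weights=(1.0,))


@pytest.fixture
def rng():
    return np.random.default_rng(20230517)


def random_sequence(rng, length, alphabet=CANONICAL_RESIDUES):
    return "".join(rng.choice(list(alphabet), size=length))
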