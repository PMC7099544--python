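import numpy as np
import pytest

from icfilt import SyntheticSpec, generate


@pytest.fixture(scope="session")
def sphere64():
    return generate(SyntheticSpec("sphere", size=(64, 64)))


@pytest.fixture(scope="session")
def phantoms():
    """The three theoretical light-source images at desk-test size."""
    return {
        kind: generate(SyntheticSpec(kind, size=(64, 64)))
        for kind in ("sphere", "torus", "ellipse")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
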