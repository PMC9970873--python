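import numpy as np
import pytest

from somapipe.simulate import CohortConfig


@pytest.fixture(scope="session")
def config():
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def reference(config):
    from somapipe.simulate import make_reference

    return make_reference(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
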