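import numpy as np
import pytest

from hatscan.synthetic_data import SimulationConfig, make_screen_dataset


@pytest.fixture(scope="session")
def screen_dataset():
    """The standard synthetic screen dataset: 20 native, 5 foreign,
    3 contaminant transcripts, ingroup divergence 0.05, donor divergence
    0.35, seed 1."""
    return make_screen_dataset(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160725)


def random_dna(length: int, gen: np.random.Generator) -> str:
    return "".join("ACGT"[k] for k in gen.integers(0, 4, size=length))
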