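import numpy as np
import pytest

from trfkit import synth
from trfkit.seqio import collapse_reads


@pytest.fixture(scope="session")
def fixture_refs():
    return synth.build_reference_fixture()


@pytest.fixture(scope="session")
def panel_table(fixture_refs):
    """Collapsed library with every published tRF spiked at its printed
    cloning frequency, no background."""
    spec = synth.panel_library_spec(seed=11)
    return collapse_reads(synth.generate_library(spec, fixture_refs))


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])
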