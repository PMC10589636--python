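import numpy as np
import pytest

from mutscenarios.synthetic_data import GenomeSequence, make_reference

SMALL_CHROMS = {"chr1": 120_000, "chr2": 80_000}


@pytest.fixture(scope="session")
def small_genome() -> GenomeSequence:
    genome, _report = make_reference(SMALL_CHROMS, seed=11)
    return genome


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
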