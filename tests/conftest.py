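import numpy as np
import pytest

from codonusage.genetic_code import SENSE_CODONS, STOP_CODONS
from codonusage.sequence_io import CodingSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_cds(rng, n_codons: int, gene_id: str = "g") -> CodingSequence:
    """A valid random CDS: i.i.d. sense codons plus a terminal stop."""
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    stop = sorted(STOP_CODONS)[rng.integers(3)]
    return CodingSequence(gene_id, "".join(codons) + stop)


@pytest.fixture
def random_panel(rng):
    return [random_cds(rng, 120 + 10 * i, f"g{i}") for i in range(12)]
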