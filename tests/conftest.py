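import numpy as np
import pytest

from methassay.primer_design import DesignConstraints, design_assay
from methassay.seqcore import find_cpg_islands
from methassay.synthfix import LocusSpec, make_locus


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def locus42():
    return make_locus(LocusSpec(seed=42))


@pytest.fixture(scope="session")
def islands42(locus42):
    return find_cpg_islands(locus42.sequence)


@pytest.fixture(scope="session")
def designs42(locus42, islands42):
    return design_assay(locus42, islands42, DesignConstraints())


@pytest.fixture(scope="session")
def small_locus():
    """A compact locus used for the exhaustive pairing oracle."""
    return make_locus(LocusSpec(total_length=1200, island_length=400, seed=7))
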