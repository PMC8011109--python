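import numpy as np
import pytest

from tsplice.data_model import CassetteExon


@pytest.fixture
def toy_genome():
    """Deterministic 2000-nt chromosome of known sequence."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {"chr1": "".join(bases[rng.integers(0, 4, size=2000)])}


@pytest.fixture
def plus_exon():
    return CassetteExon("ex_plus", "chr1", 1000, 1200, "+", "geneA")


@pytest.fixture
def minus_exon():
    return CassetteExon("ex_minus", "chr1", 1000, 1200, "-", "geneA")
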