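import numpy as np
import pytest

from hrc3.codon_null import build_codon_table
from hrc3.hrc_model import ALL_TETRAMERS, TetramerTable
from hrc3.synthetic_data import SyntheticSpec, make_tetramer_table, random_sense_codons


@pytest.fixture(scope="session")
def structured_table():
    """per_offset tetramer table under which codon choice controls periodicity."""
    return make_tetramer_table(SyntheticSpec(seed=11), structured=True)


@pytest.fixture(scope="session")
def random_table():
    """single-dialect i.i.d. tetramer table."""
    return make_tetramer_table(SyntheticSpec(seed=11), structured=False)


@pytest.fixture(scope="session")
def constant_table():
    return TetramerTable("single", {t: 5.0 for t in ALL_TETRAMERS})


@pytest.fixture(scope="session")
def background_codon_table():
    """Codon usage of a seeded synthetic exome (50 CDS x 200 codons)."""
    rng = np.random.default_rng(5)
    cds = ["".join(random_sense_codons(rng, 200)) for _ in range(50)]
    return build_codon_table(cds, scope_id="synthetic-exome")
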