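import numpy as np
import pytest

from gutcrest import synthio
from gutcrest.fixtures import load_fixture_tables


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def small_insertion():
    """A compact homozygous-insertion simulation: 300 kb host, 20 kb
    target-site duplication, 5+5 copies of two 3 kb units (30 kb array),
    30x paired-end coverage."""
    ref = synthio.make_reference(300_000, seed=11)
    units = synthio.default_transgene_units(3000, seed=11)
    allele = synthio.build_insertion_allele(
        ref, 150_000, units, [5, 5], dup_length=20_000
    )
    sim = synthio.simulate_paired_reads([allele, allele], coverage=30.0, seed=12)
    return {
        "ref": ref,
        "units": units,
        "allele": allele,
        "sim": sim,
        "unit_lengths": {u.name: u.length for u in units},
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
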