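import pytest

from promsat import tables
from promsat.haplotypes import Haplotype
from promsat.synthetic_data import PopulationSpec


@pytest.fixture(scope="session")
def variant_table():
    return tables.study_variant_table()


@pytest.fixture(scope="session")
def registry():
    return tables.study_repeat_registry()


@pytest.fixture()
def fresh_registry():
    """A mutable copy of the study registry (naming mutates it)."""
    return tables.study_repeat_registry()


@pytest.fixture(scope="session")
def species_freqs():
    return tables.study_haplotype_freqs_species()


@pytest.fixture(scope="session")
def breed_freqs():
    return tables.study_haplotype_freqs_breeds()


FIVE_HAP_LOCI = ("c.-185", "c.-46", "msat")

FIVE_HAPS = [
    Haplotype(("T", "T", "16*1")),
    Haplotype(("T", "C", "17")),
    Haplotype(("-", "T", "11")),
    Haplotype(("T", "C", "16*2")),
    Haplotype(("T", "T", "18")),
]

FIVE_FREQS = [0.30, 0.30, 0.20, 0.10, 0.10]


def five_hap_spec(n=200, seed=0, **kw) -> PopulationSpec:
    """A five-haplotype dog population over two SNPs and the repeat locus."""
    return PopulationSpec(
        loci=FIVE_HAP_LOCI,
        haplotypes=list(FIVE_HAPS),
        frequencies=list(FIVE_FREQS),
        n_individuals=n,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def make_spec():
    """Factory fixture for the five-haplotype population spec."""
    return five_hap_spec
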