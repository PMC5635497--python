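"""Access to the packaged study tables and a few printed summary constants.

The study genotyped 278 unrelated purebred dogs (102 breeds), 14 gray wolves
and 7 coyotes across the proximal GSTP1 promoter.  Its data are published as
four small tables, shipped here as TSV fixtures: the allele-level variant
table, the 5'UTR microsatellite allele registry, and the species- and
breed-level haplotype frequency tables (both truncated at low frequencies in
print, which matters for diversity recomputation).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .promoter_model import VariantTable, load_variant_table
from .repeat_alleles import AlleleRegistry

#: sampled individuals per population
SAMPLE_SIZES = {"dog": 278, "wolf": 14, "coyote": 7}

#: haplotype diversity values printed with the species table
PRINTED_DIVERSITY_SPECIES = {"dog": 0.859, "wolf": 0.878, "coyote": 0.902}

#: haplotype diversity values printed with the per-breed table
PRINTED_DIVERSITY_BREEDS = {
    "all_dogs": 0.860,
    "afghan_hound": 0.644,
    "basenji": 0.756,
    "siberian_husky": 0.000,
    "chihuahua": 0.911,
    "greyhound": 0.626,
    "boxer": 0.133,
    "labrador_retriever": 0.803,
    "pembroke_welsh_corgi": 0.889,
    "beagle": 0.853,
    "doberman_pinscher": 0.741,
    "golden_retriever": 0.809,
    "german_shepherd": 0.672,
    "standard_poodle": 0.777,
}

FIXTURE_NAMES = (
    "variant_table.tsv",
    "repeat_registry.tsv",
    "haplotype_freqs_species.tsv",
    "haplotype_freqs_breeds.tsv",
)


def fixture_path(name: str):
    """Filesystem path of a packaged fixture table."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}")
    return files("promsat.data").joinpath(name)


def study_variant_table() -> VariantTable:
    """The promoter variant table (18 allele-level rows, 16 loci)."""
    return load_variant_table(fixture_path("variant_table.tsv"))


def study_repeat_registry() -> AlleleRegistry:
    """The 5'UTR microsatellite allele registry (15 named alleles)."""
    return AlleleRegistry.from_tsv(fixture_path("repeat_registry.tsv"))


def study_haplotype_freqs_species() -> pd.DataFrame:
    """Species-level haplotype frequencies (rows truncated below 0.05 in
    print), indexed by haplotype name."""
    return pd.read_csv(
        fixture_path("haplotype_freqs_species.tsv"), sep="\t", index_col=0
    )


def study_haplotype_freqs_breeds() -> pd.DataFrame:
    """Per-breed haplotype frequencies (rows truncated below 0.01 in print),
    indexed by haplotype name."""
    return pd.read_csv(
        fixture_path("haplotype_freqs_breeds.tsv"), sep="\t", index_col=0
    )
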