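"""Genotype tables and single-locus / pairwise population-genetic statistics.

Covers the descriptors used on the promoter data: per-stratum allele
frequencies and MAF, the Hardy-Weinberg chi-squared test (Pearson's test of
observed genotype counts against p^2 / 2pq / q^2 expectations, no continuity
correction), and pairwise linkage disequilibrium D' with a base-10
likelihood-ratio LOD score computed from phased haplotype assignments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

import math

import pandas as pd

MISSING = "./."


class GenotypeFormatError(ValueError):
    """Malformed genotype file cell or header."""


class InsufficientDataError(ValueError):
    """No usable calls in the requested stratum."""


@dataclass(frozen=True)
class Individual:
    id: str
    species: str = "dog"
    breed: str = ""
    sex: str = ""


@dataclass
class GenotypeTable:
    """Diploid calls for individuals x loci.

    ``calls[ind_id][locus]`` is an unordered pair of allele states stored as
    a sorted tuple, or ``None`` for missing.  Allele states are bases for
    SNPs, registry names for the microsatellite locus.
    """

    individuals: list[Individual]
    loci: list[str]
    calls: dict[str, dict[str, tuple[str, str] | None]]

    def __post_init__(self):
        for ind in self.individuals:
            row = self.calls.get(ind.id)
            if row is None:
                raise GenotypeFormatError(f"no calls for individual {ind.id!r}")
            unknown = set(row) - set(self.loci)
            if unknown:
                raise GenotypeFormatError(
                    f"{ind.id!r}: calls at unknown loci {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.individuals)

    def subset(self, species: str | None = None,
               breed: str | None = None) -> "GenotypeTable":
        inds = [
            i for i in self.individuals
            if (species is None or i.species == species)
            and (breed is None or i.breed == breed)
        ]
        return GenotypeTable(
            individuals=inds, loci=list(self.loci),
            calls={i.id: self.calls[i.id] for i in inds},
        )

    def locus_calls(self, locus: str) -> list[tuple[str, str]]:
        """Non-missing calls at a locus, in individual order."""
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        out = []
        for ind in self.individuals:
            call = self.calls[ind.id].get(locus)
            if call is not None:
                out.append(call)
        return out


def allele_frequencies(table: GenotypeTable, locus: str,
                       species: str | None = None,
                       breed: str | None = None) -> dict[str, float]:
    """Observed allele frequencies at a locus, optionally within a stratum.

    Missing calls are excluded from the denominator; frequencies sum to 1
    over the observed alleles.
    """
    calls = table.subset(species=species, breed=breed).locus_calls(locus)
    if not calls:
        raise InsufficientDataError(
            f"no non-missing calls at {locus!r} in the requested stratum"
        )
    counts = Counter(a for call in calls for a in call)
    n = sum(counts.values())
    return {allele: c / n for allele, c in sorted(counts.items())}


def minor_allele_frequency(table: GenotypeTable, locus: str,
                           species: str | None = None) -> float:
    """MAF = 1 - max allele frequency (multi-allelic loci included)."""
    freqs = allele_frequencies(table, locus, species=species)
    return 1.0 - max(freqs.values())


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    testable: bool
    #: True when any expected genotype count is below 5 (asymptotics dubious)
    small_counts: bool = False


def hwe_chisq(table: GenotypeTable, locus: str) -> HWEResult:
    """Pearson chi-squared test of Hardy-Weinberg genotype proportions.

    Biallelic loci use the three genotype classes and df = 1.  Multi-allelic
    loci are tested over all k(k+1)/2 genotype classes with df = k(k-1)/2.
    A monomorphic locus is flagged non-testable with (0, 0).
    """
    calls = table.locus_calls(locus)
    if not calls:
        raise InsufficientDataError(f"no non-missing calls at {locus!r}")
    geno_counts = Counter(tuple(sorted(call)) for call in calls)
    allele_counts = Counter(a for call in calls for a in call)
    alleles = sorted(allele_counts)
    k = len(alleles)
    if k < 2:
        return HWEResult(chi2=0.0, df=0, testable=False)
    n = len(calls)
    two_n = 2 * n
    p = {a: allele_counts[a] / two_n for a in alleles}
    chi2 = 0.0
    small = False
    for a, b in combinations_with_replacement(alleles, 2):
        expected = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
        observed = geno_counts.get((a, b), 0)
        if expected > 0:
            chi2 += (observed - expected) ** 2 / expected
            small = small or expected < 5
    df = k * (k - 1) // 2
    return HWEResult(chi2=chi2, df=df, testable=True, small_counts=small)


@dataclass(frozen=True)
class LocusStats:
    locus: str
    allele_counts: dict[str, int] = field(hash=False)
    maf: float
    hwe_chi2: float
    hwe_df: int


def locus_stats(table: GenotypeTable, locus: str,
                species: str | None = None) -> LocusStats:
    sub = table.subset(species=species) if species else table
    counts = Counter(a for call in sub.locus_calls(locus) for a in call)
    hwe = hwe_chisq(sub, locus)
    total = sum(counts.values())
    maf = 1.0 - max(counts.values()) / total if total else 0.0
    return LocusStats(
        locus=locus, allele_counts=dict(sorted(counts.items())),
        maf=maf, hwe_chi2=hwe.chi2, hwe_df=hwe.df,
    )


@dataclass(frozen=True)
class LDResult:
    dprime: float
    lod: float
    defined: bool


def dprime_from_counts(counts: dict[tuple[str, str], int]) -> LDResult:
    """|D'| and base-10 LOD from two-locus haplotype counts.

    D = p_AB - p_A p_B normalised by its maximum attainable magnitude given
    the margins; LOD is the log10 likelihood ratio of the observed haplotype
    multinomial against the independence model.  Loci must be biallelic;
    a monomorphic locus yields an undefined result.
    """
    alleles_a = sorted({a for a, _ in counts})
    alleles_b = sorted({b for _, b in counts})
    if len(alleles_a) != 2 or len(alleles_b) != 2:
        return LDResult(dprime=math.nan, lod=math.nan, defined=False)
    n = sum(counts.values())
    a1, _ = alleles_a
    b1, _ = alleles_b
    p_a = sum(c for (a, _), c in counts.items() if a == a1) / n
    p_b = sum(c for (_, b), c in counts.items() if b == b1) / n
    p_ab = counts.get((a1, b1), 0) / n
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if d_max == 0 else abs(d) / d_max
    lod = 0.0
    for (a, b), c in counts.items():
        if c == 0:
            continue
        p_obs = c / n
        p_indep = (
            (p_a if a == a1 else 1 - p_a) * (p_b if b == b1 else 1 - p_b)
        )
        lod += c * (math.log10(p_obs) - math.log10(p_indep))
    return LDResult(dprime=dprime, lod=lod, defined=True)


def pairwise_dprime(table: GenotypeTable, locus_a: str, locus_b: str,
                    phased: Iterable) -> LDResult:
    """LD between two loci from phased diplotypes (see the phasing module).

    ``phased`` is an iterable of diplotypes whose haplotype state vectors are
    ordered like ``table.loci``; each resolved diplotype contributes two
    chromosomes to the haplotype counts.
    """
    ia, ib = table.loci.index(locus_a), table.loci.index(locus_b)
    counts: Counter = Counter()
    for dip in phased:
        for hap in dip.haplotypes:
            counts[(hap.states[ia], hap.states[ib])] += 1
    return dprime_from_counts(dict(counts))


# --------------------------------------------------------------------- I/O

def parse_call(cell: str) -> tuple[str, str] | None:
    """Parse an ``X/Y`` genotype cell; ``./.`` (or blank) is missing."""
    cell = (cell or "").strip()
    if cell in ("", MISSING, "."):
        return None
    parts = cell.split("/")
    if len(parts) != 2 or not all(parts):
        raise GenotypeFormatError(
            f"genotype cell {cell!r} is not a diploid 'X/Y' call"
        )
    return tuple(sorted(parts))  # type: ignore[return-value]


def load_genotypes(path, repeat_locus: str | None = None,
                   registry=None) -> GenotypeTable:
    """Load a genotype TSV: id, species, breed, sex, then one column per locus.

    When ``registry`` is given, allele names at ``repeat_locus`` are checked
    against it and unknown names are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    meta_cols = ["id", "species", "breed", "sex"]
    loci = [c for c in df.columns if c not in meta_cols]
    if not loci:
        raise GenotypeFormatError("no locus columns in genotype file")
    individuals, calls = [], {}
    for idx, row in df.iterrows():
        ind = Individual(
            id=str(row["id"]),
            species=str(row.get("species", "dog")) or "dog",
            breed=str(row.get("breed", "")),
            sex=str(row.get("sex", "")),
        )
        row_calls = {}
        for locus in loci:
            try:
                call = parse_call(row[locus])
            except GenotypeFormatError as err:
                raise GenotypeFormatError(
                    f"row {idx + 1} ({ind.id}), locus {locus}: {err}"
                ) from None
            if (
                call is not None and registry is not None
                and locus == repeat_locus
            ):
                for name in call:
                    if name not in registry:
                        raise GenotypeFormatError(
                            f"row {idx + 1} ({ind.id}): unknown repeat "
                            f"allele {name!r} at {locus}"
                        )
            row_calls[locus] = call
        individuals.append(ind)
        calls[ind.id] = row_calls
    return GenotypeTable(individuals=individuals, loci=loci, calls=calls)


def write_genotypes(table: GenotypeTable, path,
                    header_comment: str | None = None) -> None:
    """Canonical genotype TSV writer (inverse of :func:`load_genotypes`)."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(["id", "species", "breed", "sex"] + table.loci) + "\n")
        for ind in table.individuals:
            cells = []
            for locus in table.loci:
                call = table.calls[ind.id].get(locus)
                cells.append(MISSING if call is None else "/".join(call))
            fh.write("\t".join([ind.id, ind.species, ind.breed, ind.sex]
                               + cells) + "\n")
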