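"""Homozygote-anchored haplotype phasing, nomenclature and diversity.

Phasing follows Clark's parsimony idea: haplotypes are first read directly
from unambiguous individuals (homozygous everywhere, or heterozygous at a
single locus), then iteratively subtracted from multi-heterozygous genotypes
until a fixpoint.  Individuals that no known haplotype can explain are
reported unresolved, never guessed.

Names follow the study's scheme ``*<number><letter>(<repeat length>)``: the
number encodes the SNP pattern upstream of the microsatellite region
(upstream of c.-68), the letter the SNP pattern inside the microsatellite,
and the parenthetical the repeat-allele unit count, with the reference
(CanFam3 boxer) pattern designated *1A.  Haplotype diversity uses the
small-sample corrected estimator H = n/(n-1) * (1 - sum p_i^2) over n
chromosomes.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .popgen import GenotypeTable, Individual


@dataclass(unsafe_hash=True)
class Haplotype:
    """Ordered allele states across the promoter loci.

    Equality and hashing consider the state vector only; ``name`` and
    ``support`` are bookkeeping.  ``support`` is ``observed_in_homozygote``
    for haplotypes read directly from an unambiguous individual and
    ``inferred`` for those obtained by subtraction.
    """

    states: tuple[str, ...]
    name: str | None = field(default=None, compare=False)
    support: str = field(default="inferred", compare=False)

    @property
    def state_string(self) -> str:
        return "|".join(self.states)


@dataclass
class Diplotype:
    individual: Individual
    haplotypes: tuple[Haplotype, Haplotype]
    resolution: str  # direct | inferred | unresolved

    def consistent_with(self, genotype: Sequence[tuple[str, str] | None]) -> bool:
        """Check the two haplotypes against an unordered genotype vector."""
        h1, h2 = self.haplotypes
        for a, b, call in zip(h1.states, h2.states, genotype):
            if call is not None and tuple(sorted((a, b))) != call:
                return False
        return True


@dataclass
class PhasingResult:
    haplotypes: list[Haplotype]
    diplotypes: list[Diplotype]
    unresolved: list[str]
    loci: tuple[str, ...]
    counts: dict[tuple[str, ...], int]

    def frequencies(self) -> dict[Haplotype, float]:
        total = sum(self.counts.values())
        return {
            h: self.counts.get(h.states, 0) / total for h in self.haplotypes
        }


def _genotype_vector(table: GenotypeTable, ind_id: str):
    return [table.calls[ind_id].get(locus) for locus in table.loci]


def _het_count(genotype) -> int:
    return sum(1 for call in genotype if call is not None and call[0] != call[1])


def clark_phase(table: GenotypeTable, max_rounds: int = 20,
                seed: int = 0) -> PhasingResult:
    """Clark-style parsimony phasing of a diploid genotype table.

    Deterministic given the input: ties between known haplotypes that could
    be subtracted from an ambiguous genotype are broken by current haplotype
    frequency (most frequent first), then by lexicographic state string.
    ``seed`` is accepted for interface stability but the algorithm draws no
    random numbers.  Individuals with missing calls are left unresolved.
    """
    del seed
    known: dict[tuple[str, ...], Haplotype] = {}
    counts: Counter = Counter()
    diplotypes: list[Diplotype] = []
    pending: list[tuple[str, list]] = []

    def register(states: tuple[str, ...], support: str) -> Haplotype:
        hap = known.get(states)
        if hap is None:
            hap = Haplotype(states=states, support=support)
            known[states] = hap
        elif support == "observed_in_homozygote":
            hap.support = support
        return hap

    # pass 1: unambiguous individuals (heterozygous at <= 1 locus)
    for ind in table.individuals:
        genotype = _genotype_vector(table, ind.id)
        if any(call is None for call in genotype):
            pending.append((ind.id, genotype))
            continue
        if _het_count(genotype) <= 1:
            states_a = tuple(call[0] for call in genotype)
            states_b = tuple(call[1] for call in genotype)
            h1 = register(states_a, "observed_in_homozygote")
            h2 = register(states_b, "observed_in_homozygote")
            counts[states_a] += 1
            counts[states_b] += 1
            diplotypes.append(Diplotype(ind, (h1, h2), "direct"))
        else:
            pending.append((ind.id, genotype))

    individuals_by_id = {i.id: i for i in table.individuals}

    # canonical processing order, independent of input row order: fewest
    # heterozygous loci first, then genotype string, then id
    def _pending_key(item):
        ind_id, genotype = item
        geno_str = ";".join(
            "." if call is None else "/".join(call) for call in genotype
        )
        return (_het_count(genotype), geno_str, ind_id)

    pending.sort(key=_pending_key)

    def complement(hap_states, genotype):
        out = []
        for state, call in zip(hap_states, genotype):
            if state not in call:
                return None
            out.append(call[1] if state == call[0] else call[0])
        return tuple(out)

    # pass 2: iterative subtraction of known haplotypes
    for _ in range(max_rounds):
        progressed = False
        still_pending = []
        for ind_id, genotype in pending:
            if any(call is None for call in genotype):
                still_pending.append((ind_id, genotype))
                continue
            candidates = []
            for states in known:
                comp = complement(states, genotype)
                if comp is not None:
                    candidates.append((states, comp))
            if not candidates:
                still_pending.append((ind_id, genotype))
                continue
            states, comp = min(
                candidates,
                key=lambda sc: (-counts[sc[0]], "|".join(sc[0])),
            )
            h1 = known[states]
            h2 = register(comp, "inferred")
            counts[states] += 1
            counts[comp] += 1
            diplotypes.append(
                Diplotype(individuals_by_id[ind_id], (h1, h2), "inferred")
            )
            progressed = True
        pending = still_pending
        if not progressed or not pending:
            break

    unresolved = [ind_id for ind_id, _ in pending]
    haplotypes = sorted(
        known.values(), key=lambda h: (-counts[h.states], h.state_string)
    )
    return PhasingResult(
        haplotypes=haplotypes, diplotypes=diplotypes,
        unresolved=unresolved, loci=tuple(table.loci), counts=dict(counts),
    )


# ------------------------------------------------------------- nomenclature

_C_POS = re.compile(r"c\.(-\d+)")

#: loci at or upstream of this promoter position set the haplotype *number*;
#: SNPs downstream of it sit inside the microsatellite and set the letter
UPSTREAM_BOUNDARY = -68


def locus_partition(loci: Sequence[str], repeat_locus: str):
    """Split locus labels into (upstream SNPs, microsatellite-internal SNPs)."""
    upstream, internal = [], []
    for locus in loci:
        if locus == repeat_locus:
            continue
        m = _C_POS.search(locus)
        if m is None:
            raise ValueError(f"locus label {locus!r} has no c position")
        (upstream if int(m.group(1)) <= UPSTREAM_BOUNDARY else internal).append(locus)
    return tuple(upstream), tuple(internal)


def _letters():
    from string import ascii_uppercase

    for ch in ascii_uppercase:
        yield ch
    for ch1 in ascii_uppercase:
        for ch2 in ascii_uppercase:
            yield ch1 + ch2


@dataclass
class HaplotypeNameRegistry:
    """Pattern maps behind the *NumberLetter(repeat) naming scheme.

    Unknown patterns allocate the next free number / letter and extend the
    registry, so naming is stable within a session and user-extensible
    across sessions.
    """

    loci: tuple[str, ...]
    repeat_locus: str
    upstream_loci: tuple[str, ...]
    internal_loci: tuple[str, ...]
    numbers: dict[tuple[str, ...], int] = field(default_factory=dict)
    letters: dict[tuple[str, ...], str] = field(default_factory=dict)

    @classmethod
    def from_reference(cls, loci: Sequence[str], repeat_locus: str,
                       reference_states: Mapping[str, str],
                       extra_numbers: Mapping[frozenset, int] | None = None,
                       ) -> "HaplotypeNameRegistry":
        """Seed from reference allele states: the reference upstream pattern
        is number 1 and the reference internal pattern letter A.

        ``extra_numbers`` maps {frozenset of (locus, alt_state)} overrides on
        the reference pattern to reserved numbers, for named haplotypes whose
        defining states are known.
        """
        upstream, internal = locus_partition(loci, repeat_locus)
        reg = cls(
            loci=tuple(loci), repeat_locus=repeat_locus,
            upstream_loci=upstream, internal_loci=internal,
        )
        ref_up = tuple(reference_states[l] for l in upstream)
        ref_in = tuple(reference_states[l] for l in internal)
        reg.numbers[ref_up] = 1
        reg.letters[ref_in] = "A"
        for overrides, number in (extra_numbers or {}).items():
            states = dict(zip(upstream, ref_up))
            for locus, alt in overrides:
                if locus not in states:
                    raise ValueError(
                        f"override locus {locus!r} is not an upstream locus"
                    )
                states[locus] = alt
            reg.numbers[tuple(states[l] for l in upstream)] = number
        return reg

    def _pattern(self, hap: Haplotype, loci_subset: tuple[str, ...]):
        index = {locus: i for i, locus in enumerate(self.loci)}
        return tuple(hap.states[index[l]] for l in loci_subset)

    def number_for(self, pattern: tuple[str, ...]) -> int:
        if pattern not in self.numbers:
            used = set(self.numbers.values())
            n = 1
            while n in used:
                n += 1
            self.numbers[pattern] = n
        return self.numbers[pattern]

    def letter_for(self, pattern: tuple[str, ...]) -> str:
        if pattern not in self.letters:
            used = set(self.letters.values())
            self.letters[pattern] = next(
                ch for ch in _letters() if ch not in used
            )
        return self.letters[pattern]


def repeat_length_from_name(allele_name: str) -> int:
    """Unit count encoded in a repeat-allele name (``"16*2"`` -> 16)."""
    return int(allele_name.split("*")[0])


def name_haplotype(hap: Haplotype, registry: HaplotypeNameRegistry) -> str:
    """Assign (and store) the ``*<number><letter>(<length>)`` name."""
    if any(s == "" for s in hap.states):
        raise ValueError("cannot name a haplotype with missing states")
    number = registry.number_for(registry._pattern(hap, registry.upstream_loci))
    letter = registry.letter_for(registry._pattern(hap, registry.internal_loci))
    repeat_state = hap.states[registry.loci.index(registry.repeat_locus)]
    hap.name = f"*{number}{letter}({repeat_length_from_name(repeat_state)})"
    return hap.name


# ---------------------------------------------------------------- diversity

def haplotype_diversity(freqs: Mapping | Sequence[float],
                        n_chromosomes: int) -> float:
    """Small-sample corrected haplotype diversity over n chromosomes.

    H = n/(n-1) * (1 - sum p_i^2); 0 for a monomorphic sample.
    """
    values = list(freqs.values()) if isinstance(freqs, Mapping) else list(freqs)
    if n_chromosomes < 2:
        raise ValueError("need at least two chromosomes")
    total = sum(values)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {total}, not 1")
    sum_sq = sum(p * p for p in values)
    return n_chromosomes / (n_chromosomes - 1) * (1.0 - sum_sq)


def haplotype_diversity_truncated(freqs: Mapping | Sequence[float],
                                  n_chromosomes: int) -> float:
    """Diversity from a frequency table truncated at low frequencies.

    The missing probability mass is lumped as rare singleton haplotypes of
    frequency 1/n each, the least-assuming completion of a truncated table.
    """
    values = list(freqs.values()) if isinstance(freqs, Mapping) else list(freqs)
    residual = 1.0 - sum(values)
    if residual < -1e-6:
        raise ValueError("visible frequencies exceed 1")
    k = round(max(residual, 0.0) * n_chromosomes)
    sum_sq = sum(p * p for p in values) + k * (1.0 / n_chromosomes) ** 2
    return n_chromosomes / (n_chromosomes - 1) * (1.0 - sum_sq)


# ------------------------------------------------------------ cohort tables

def _hap_label(hap: Haplotype) -> str:
    return hap.name or hap.state_string


def breed_haplotype_table(diplotypes: Iterable[Diplotype],
                          min_breed_n: int = 5):
    """Per-breed haplotype frequency table plus per-breed diversity.

    Breeds with fewer than ``min_breed_n`` individuals are excluded.
    Returns ``(DataFrame breeds x haplotypes, Series of H per breed)``.
    """
    by_breed: dict[str, Counter] = {}
    n_ind: Counter = Counter()
    for dip in diplotypes:
        breed = dip.individual.breed
        n_ind[breed] += 1
        row = by_breed.setdefault(breed, Counter())
        for hap in dip.haplotypes:
            row[_hap_label(hap)] += 1
    breeds = sorted(b for b in by_breed if n_ind[b] >= min_breed_n)
    haps = sorted({h for b in breeds for h in by_breed[b]})
    freq = pd.DataFrame(0.0, index=breeds, columns=haps)
    diversity = pd.Series(0.0, index=breeds, name="H")
    for breed in breeds:
        n_chrom = 2 * n_ind[breed]
        for hap, count in by_breed[breed].items():
            freq.loc[breed, hap] = count / n_chrom
        diversity[breed] = haplotype_diversity(
            freq.loc[breed][freq.loc[breed] > 0], n_chrom
        )
    return freq, diversity


def shared_haplotypes(freq_tables: Mapping[str, Mapping[str, float]]):
    """Presence matrix and pairwise sharing counts across populations.

    A haplotype is present in a population when its frequency is > 0.
    Returns ``(DataFrame haplotype x population of bool, dict pair -> count)``.
    """
    pops = list(freq_tables)
    haps = sorted({h for t in freq_tables.values() for h in t})
    presence = pd.DataFrame(
        {p: [freq_tables[p].get(h, 0.0) > 0.0 for h in haps] for p in pops},
        index=haps,
    )
    sharing = {}
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            sharing[(p1, p2)] = int((presence[p1] & presence[p2]).sum())
    return presence, sharing
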