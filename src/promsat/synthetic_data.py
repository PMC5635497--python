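"""Synthetic genotype populations with known truth, plus fixture export.

The generator emulates the study's sampling design: unrelated diploid
individuals drawing two haplotypes i.i.d. from a specified frequency vector
(Hardy-Weinberg random mating), optional breed labels, and optional
single-unit replication slippage applied independently to each transmitted
microsatellite allele.  The true diplotypes are returned alongside the
genotype table so phasing and frequency-recovery can be scored exactly.

``write_fixtures`` exports the packaged study tables (variant table, repeat
allele registry, species- and breed-level haplotype frequencies) to a
directory, with content checksums, for use outside the package.
"""

from __future__ import annotations

import configparser
import hashlib
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import tables
from .haplotypes import Diplotype, Haplotype
from .popgen import GenotypeTable, Individual
from .recombination import slippage_neighbors
from .repeat_alleles import AlleleRegistry


@dataclass
class PopulationSpec:
    """Study-design parameters for one synthetic population."""

    loci: tuple[str, ...]
    haplotypes: list[Haplotype]
    frequencies: list[float]
    n_individuals: int
    seed: int = 0
    species: str = "dog"
    breeds: dict[str, float] | None = None
    #: optional per-breed haplotype frequency vectors (breed structure)
    breed_frequencies: dict[str, Sequence[float]] | None = None
    repeat_locus: str | None = None
    #: per-transmission probability of a single +/-1-unit repeat change
    slippage_rate: float = 0.0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("one frequency per haplotype required")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if not 0.0 <= self.slippage_rate <= 0.5:
            raise ValueError("slippage_rate must be in [0, 0.5]")
        for hap in self.haplotypes:
            if len(hap.states) != len(self.loci):
                raise ValueError(
                    f"haplotype {hap.states} does not match loci {self.loci}"
                )
        if self.breeds is not None:
            if abs(sum(self.breeds.values()) - 1.0) > 1e-9:
                raise ValueError("breed proportions must sum to 1")
        if self.slippage_rate > 0 and self.repeat_locus is None:
            raise ValueError("slippage requires a repeat locus")
        for vec in (self.breed_frequencies or {}).values():
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError("breed frequency vectors must sum to 1")

    @classmethod
    def from_ini(cls, path) -> "PopulationSpec":
        """Read a flat INI spec: [population] scalars, [loci] order,
        [haplotypes] 'state|state|...' = frequency, optional [breeds]."""
        parser = configparser.ConfigParser()
        parser.optionxform = str  # keep case in state strings
        with open(path) as fh:
            parser.read_file(fh)
        loci = tuple(
            s.strip() for s in parser["loci"]["order"].split(",") if s.strip()
        )
        haps, freqs = [], []
        for key, value in parser["haplotypes"].items():
            haps.append(Haplotype(states=tuple(key.split("|"))))
            freqs.append(float(value))
        pop = parser["population"]
        breeds = None
        if parser.has_section("breeds"):
            breeds = {k: float(v) for k, v in parser["breeds"].items()}
        return cls(
            loci=loci, haplotypes=haps, frequencies=freqs,
            n_individuals=pop.getint("n_individuals"),
            seed=pop.getint("seed", 0),
            species=pop.get("species", "dog"),
            breeds=breeds,
            repeat_locus=pop.get("repeat_locus", None),
            slippage_rate=pop.getfloat("slippage_rate", 0.0),
        )


@dataclass
class SimulationResult:
    table: GenotypeTable
    true_diplotypes: list[Diplotype]
    spec: PopulationSpec
    #: transmitted repeat alleles that slipped (out of 2 * n_individuals)
    n_slipped: int = 0
    registry: AlleleRegistry | None = None

    def true_frequencies(self) -> dict[tuple[str, ...], float]:
        counts: dict[tuple[str, ...], int] = {}
        for dip in self.true_diplotypes:
            for hap in dip.haplotypes:
                counts[hap.states] = counts.get(hap.states, 0) + 1
        total = 2 * len(self.true_diplotypes)
        return {states: c / total for states, c in counts.items()}


def generate_population(spec: PopulationSpec,
                        registry: AlleleRegistry | None = None
                        ) -> SimulationResult:
    """Draw a diploid population under random mating from a haplotype pool.

    Each individual draws two haplotypes i.i.d. from the frequency vector
    (per-breed vectors when breed structure is requested).  With a nonzero
    slippage rate each transmitted repeat allele independently mutates, at
    most once, to a uniformly chosen single-unit slippage neighbour, which
    is named against (and added to) the registry.  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.slippage_rate > 0 and registry is None:
        raise ValueError("slippage requires an allele registry")
    repeat_idx = (
        spec.loci.index(spec.repeat_locus)
        if spec.repeat_locus is not None else None
    )
    breed_labels = list(spec.breeds) if spec.breeds else [""]
    breed_probs = list(spec.breeds.values()) if spec.breeds else [1.0]

    individuals, calls, true_dips = [], {}, []
    n_slipped = 0
    n_haps = len(spec.haplotypes)
    width = len(str(spec.n_individuals))

    def transmit(idx: int) -> Haplotype:
        nonlocal n_slipped
        hap = spec.haplotypes[idx]
        if (
            spec.slippage_rate > 0
            and rng.random() < spec.slippage_rate
        ):
            allele = registry.get(hap.states[repeat_idx])
            neighbors = slippage_neighbors(allele)
            units = neighbors[rng.integers(len(neighbors))]
            new_name = registry.assign_name(units)
            if new_name != hap.states[repeat_idx]:
                n_slipped += 1
                states = list(hap.states)
                states[repeat_idx] = new_name
                return Haplotype(states=tuple(states), support="inferred")
        return hap

    for k in range(spec.n_individuals):
        breed = breed_labels[rng.choice(len(breed_labels), p=breed_probs)]
        freqs = (
            list((spec.breed_frequencies or {}).get(breed, spec.frequencies))
        )
        ind = Individual(
            id=f"S{k:0{width}d}", species=spec.species, breed=breed,
            sex="F" if rng.random() < 0.5 else "M",
        )
        i1, i2 = rng.choice(n_haps, size=2, p=freqs)
        h1, h2 = transmit(i1), transmit(i2)
        row = {
            locus: tuple(sorted((h1.states[i], h2.states[i])))
            for i, locus in enumerate(spec.loci)
        }
        individuals.append(ind)
        calls[ind.id] = row
        true_dips.append(Diplotype(ind, (h1, h2), "direct"))

    table = GenotypeTable(
        individuals=individuals, loci=list(spec.loci), calls=calls
    )
    return SimulationResult(
        table=table, true_diplotypes=true_dips, spec=spec,
        n_slipped=n_slipped, registry=registry,
    )


# ---------------------------------------------------------------- fixtures

def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_fixtures(outdir) -> dict[str, str]:
    """Export the packaged study tables to ``outdir``.

    Returns {filename: sha256 of content}; rewriting is idempotent (the
    copies are byte-identical to the packaged data).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name in tables.FIXTURE_NAMES:
        src = tables.fixture_path(name)
        dst = outdir / name
        shutil.copyfile(src, dst)
        checksums[name] = file_checksum(dst)
    return checksums
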