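"""Trinucleotide tandem-repeat allele decomposition, purity, class and naming.

The 5'UTR microsatellite of the canine GSTP1 promoter is a GCC triplet repeat
(sequences written 5'->3' on the transcript (-) strand) whose alleles differ in
unit count and in internal sequence.  An allele is decomposed into an ordered
list of 3-base units anchored at the first base of the tract; its *purity* is
the per-base identity to a perfect in-frame GCC tract of equal length, and it
is *compound* when it carries units of the interruption motif
GCTGC[C/A]ACTGCTACC (i.e. an ACT or GCA unit), *simple* otherwise.

Alleles are named ``<unit count>`` when a length is unique, and
``<unit count>*k`` when several same-length sequences exist (``16*1`` simple,
``16*2`` compound, ...).  The :class:`AlleleRegistry` maps names to alleles and
assigns names to newly observed sequences.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

CONSENSUS_UNIT = "GCC"
#: units produced by the interruption motif GCTGC[C/A]ACTGCTACC; tracts
#: containing one are classed compound
INTERRUPTION_UNITS = frozenset({"ACT", "GCA"})

_VALID_BASES = frozenset("ACGT")


class ShorthandParseError(ValueError):
    """Malformed repeat shorthand expression."""


class UnsupportedFrameError(ValueError):
    """Operation requires a tract that decomposes into whole units."""


class UnknownAlleleError(KeyError):
    """Allele name not present in the registry."""


def parse_shorthand(expr: str) -> str:
    """Expand repeat shorthand such as ``GCT(GCC)_15`` into a full sequence.

    The grammar is a concatenation of literal base runs and parenthesised
    repeated blocks ``(XXX)_n``.  Trailing underscores after the multiplier
    (as in typeset tables) are tolerated.
    """
    expr = expr.strip().replace(" ", "")
    if not expr:
        raise ShorthandParseError("empty shorthand expression")
    out: list[str] = []
    pos = 0
    token = re.compile(r"([ACGT]+)|\(([ACGT]+)\)_(\d+)_?")
    while pos < len(expr):
        m = token.match(expr, pos)
        if m is None:
            raise ShorthandParseError(
                f"cannot parse shorthand at position {pos}: {expr[pos:pos + 12]!r}"
            )
        if m.group(1) is not None:
            out.append(m.group(1))
        else:
            out.append(m.group(2) * int(m.group(3)))
        pos = m.end()
    return "".join(out)


def decompose(seq: str, unit_length: int = 3) -> tuple[tuple[str, ...], str]:
    """Split a tract into in-frame units plus a (possibly empty) remainder.

    The reading frame is anchored at the first base; no frame search is
    performed.  Returns ``(units, remainder)`` with
    ``"".join(units) + remainder == seq``.
    """
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("cannot decompose an empty sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    if unit_length < 1:
        raise ValueError("unit_length must be >= 1")
    n_units = len(seq) // unit_length
    units = tuple(
        seq[k * unit_length:(k + 1) * unit_length] for k in range(n_units)
    )
    return units, seq[n_units * unit_length:]


def _round_sig(value: float, sig: int = 3) -> float:
    if value == 0:
        return 0.0
    return round(value, sig - 1 - math.floor(math.log10(abs(value))))


def purity(units: Iterable[str], consensus: str = CONSENSUS_UNIT,
           remainder: str = "") -> float:
    """Per-base identity (%) of a tract to a perfect consensus repeat.

    Each base is compared position-wise to a perfect in-frame tract of
    ``consensus`` units of equal length; the result is reported to three
    significant figures.  Tracts with leftover bases outside the unit frame
    are rejected: purity is defined only for whole-unit tracts.
    """
    units = tuple(units)
    if not units:
        raise ValueError("purity requires at least one unit")
    if remainder:
        raise UnsupportedFrameError(
            "purity is undefined for tracts with a partial-unit remainder"
        )
    matches = sum(
        1 for unit in units for a, b in zip(unit, consensus) if a == b
    )
    total = sum(len(u) for u in units)
    return _round_sig(100.0 * matches / total)


def classify(units: Iterable[str]) -> str:
    """Return ``"compound"`` if any unit is an interruption-motif unit."""
    return "compound" if any(u in INTERRUPTION_UNITS for u in units) else "simple"


@dataclass
class RepeatAllele:
    """One microsatellite allele decomposed into 3-base units.

    ``annotations`` carries externally computed per-allele scores (predicted
    repeat variability, RNA hairpin dG) as opaque values; they are stored and
    round-tripped but never recomputed here.
    """

    name: str
    units: tuple[str, ...]
    remainder: str = ""
    freq: dict[str, float] = field(default_factory=dict)
    annotations: dict[str, object] = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return "".join(self.units) + self.remainder

    @property
    def unit_count(self) -> int:
        return len(self.units)

    @property
    def purity(self) -> float:
        return purity(self.units, remainder=self.remainder)

    @property
    def klass(self) -> str:
        return classify(self.units)

    @classmethod
    def from_shorthand(cls, name: str, expr: str, **kw) -> "RepeatAllele":
        units, remainder = decompose(parse_shorthand(expr))
        return cls(name=name, units=units, remainder=remainder, **kw)


def _length_stem(name: str) -> tuple[int, int]:
    """Split ``"16*2"`` into ``(16, 2)``; a bare ``"13"`` is suffix 1."""
    if "*" in name:
        stem, suffix = name.split("*", 1)
        return int(stem), int(suffix)
    return int(name), 1


class AlleleRegistry:
    """Named microsatellite alleles with species frequency annotations.

    Names are unique; distinct same-length sequences carry distinct ``*k``
    suffixes.  Sequences are stored 5'->3' on the transcript (-) strand.
    """

    def __init__(self, alleles: Iterable[RepeatAllele] = (),
                 consensus_unit: str = CONSENSUS_UNIT):
        self.consensus_unit = consensus_unit
        self.entries: dict[str, RepeatAllele] = {}
        self._by_sequence: dict[str, str] = {}
        for allele in alleles:
            self.add(allele)

    def add(self, allele: RepeatAllele) -> None:
        if allele.name in self.entries:
            raise ValueError(f"duplicate allele name {allele.name!r}")
        self.entries[allele.name] = allele
        self._by_sequence.setdefault(allele.sequence, allele.name)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def get(self, name: str) -> RepeatAllele:
        try:
            return self.entries[name]
        except KeyError:
            raise UnknownAlleleError(name) from None

    def lookup_sequence(self, seq: str) -> str | None:
        """Name of the registered allele with this exact sequence, if any."""
        return self._by_sequence.get(seq)

    def assign_name(self, units: Iterable[str],
                    freq: Mapping[str, float] | None = None) -> str:
        """Name a decomposed tract, registering it if novel.

        An exact sequence match returns the existing name.  Otherwise the
        name is the bare unit count when no same-length entry exists, else
        ``<count>*k`` with the next unused suffix; the allele is added to
        the registry either way, so naming is idempotent.
        """
        units = tuple(units)
        seq = "".join(units)
        existing = self.lookup_sequence(seq)
        if existing is not None:
            return existing
        count = len(units)
        used = {
            _length_stem(name)[1]
            for name in self.entries
            if _length_stem(name)[0] == count
        }
        if not used:
            name = str(count)
        else:
            k = 2
            while k in used:
                k += 1
            name = f"{count}*{k}"
        self.add(RepeatAllele(name=name, units=units, freq=dict(freq or {})))
        return name

    def distinct_lengths(self, species: str) -> set[int]:
        """Unit counts of alleles segregating (frequency > 0) in a species."""
        lengths = set()
        seen_species = set()
        for allele in self:
            seen_species.update(allele.freq)
            if allele.freq.get(species, 0.0) > 0.0:
                lengths.add(allele.unit_count)
        if species not in seen_species:
            raise KeyError(f"unknown species {species!r}")
        return lengths

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv(cls, path) -> "AlleleRegistry":
        """Load a registry from a TSV with columns
        name, shorthand, freq_dog, freq_wolf, freq_coyote, varscore, dg."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        registry = cls()
        for _, row in df.iterrows():
            freq = {
                col.removeprefix("freq_"): float(row[col])
                for col in df.columns if col.startswith("freq_")
            }
            annotations = {
                col: (None if row[col] in (".", "", None) else float(row[col]))
                for col in ("varscore", "dg") if col in df.columns
            }
            registry.add(RepeatAllele.from_shorthand(
                row["name"], row["shorthand"], freq=freq,
                annotations=annotations,
            ))
        return registry

    def to_fasta(self, path) -> None:
        """Write expanded allele sequences as FASTA (record id = name)."""
        with open(path, "w") as fh:
            for allele in self:
                fh.write(f">{allele.name}\n{allele.sequence}\n")
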