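"""Unequal crossing-over and replication-slippage moves on repeat alleles.

Unequal crossing-over between two misaligned repeat tracts exchanges whole
repeat units around a breakpoint, producing one expanded and one contracted
product; replication slippage inserts or deletes a single unit within a run
of identical units.  Both operators work on decomposed alleles (breakpoints
restricted to unit boundaries, matching the observed in-frame allele
spectrum) and are used to search for derivations of observed alleles from
parent pairs in the registry.

The crossover of A and B at unit boundaries (i, j) yields products
``A[:i] + B[j:]`` and ``B[:j] + A[i:]``; total unit count is conserved and
an offset i - j of 0 returns the parents unchanged.  Products carry no
flanking sequence, so the downstream terminal units (e.g. the ACCGCC tail)
travel with the suffix parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .repeat_alleles import AlleleRegistry, RepeatAllele, UnsupportedFrameError

Units = tuple[str, ...]


def _require_whole_units(allele: RepeatAllele) -> None:
    if allele.remainder:
        raise UnsupportedFrameError(
            f"allele {allele.name!r} has a partial-unit remainder; "
            "crossover breakpoints are defined at unit boundaries only"
        )


@dataclass(frozen=True)
class CrossoverEvent:
    """One unequal single crossover between two parent alleles."""

    parent_a: RepeatAllele
    parent_b: RepeatAllele
    i: int  # breakpoint after unit i of parent A (0..len(A))
    j: int  # breakpoint after unit j of parent B (0..len(B))
    products: tuple[Units, Units]

    def __post_init__(self):
        lengths = sorted(map(len, self.products))
        expected = sorted(
            [self.parent_a.unit_count, self.parent_b.unit_count]
        )
        total = self.parent_a.unit_count + self.parent_b.unit_count
        assert sum(lengths) == total, "unit-count conservation violated"
        if self.offset == 0:
            assert lengths == expected

    @property
    def offset(self) -> int:
        return self.i - self.j

    @property
    def product_sequences(self) -> tuple[str, str]:
        return tuple("".join(p) for p in self.products)  # type: ignore

    @property
    def product_lengths(self) -> tuple[int, int]:
        return tuple(sorted(map(len, self.products)))  # type: ignore


def enumerate_crossovers(a: RepeatAllele, b: RepeatAllele,
                         max_offset: int | None = None
                         ) -> list[CrossoverEvent]:
    """All unit-boundary single crossovers of two alleles.

    Events are deduplicated by their unordered pair of product sequences
    (the first (i, j) producing a pair is kept); ``max_offset`` bounds
    |i - j|, i.e. the misalignment of the two tracts.
    """
    _require_whole_units(a)
    _require_whole_units(b)
    seen: set[frozenset[str]] = set()
    events = []
    for i in range(a.unit_count + 1):
        for j in range(b.unit_count + 1):
            if max_offset is not None and abs(i - j) > max_offset:
                continue
            p1 = a.units[:i] + b.units[j:]
            p2 = b.units[:j] + a.units[i:]
            key = frozenset({"".join(p1), "".join(p2)})
            if key in seen:
                continue
            seen.add(key)
            events.append(CrossoverEvent(a, b, i, j, (p1, p2)))
    return events


def slippage_neighbors(a: RepeatAllele) -> list[Units]:
    """Single-unit slippage products: one unit inserted into or deleted from
    a run of identical units, deduplicated by sequence."""
    units = a.units
    neighbors: dict[str, Units] = {}
    # runs of identical consecutive units
    runs: list[tuple[int, int]] = []  # (start, length)
    start = 0
    for k in range(1, len(units) + 1):
        if k == len(units) or units[k] != units[start]:
            runs.append((start, k - start))
            start = k
    for start, length in runs:
        unit = units[start]
        expanded = units[:start] + (unit,) * (length + 1) + units[start + length:]
        neighbors.setdefault("".join(expanded), expanded)
        contracted = units[:start] + (unit,) * (length - 1) + units[start + length:]
        if contracted:
            neighbors.setdefault("".join(contracted), contracted)
    neighbors.pop("".join(units), None)
    return list(neighbors.values())


@dataclass(frozen=True)
class Derivation:
    """A single-crossover derivation of a target allele from a parent pair."""

    target: str
    parent_a: str
    parent_b: str
    event: CrossoverEvent
    match_mode: str  # length | sequence
    product_index: int  # which event product matches the target

    @property
    def product(self) -> Units:
        return self.event.products[self.product_index]

    @property
    def complement(self) -> Units:
        return self.event.products[1 - self.product_index]


def derivation_search(target: RepeatAllele, registry: AlleleRegistry,
                      match_mode: str = "length",
                      parents: Iterable[str] | None = None,
                      max_offset: int | None = None) -> list[Derivation]:
    """All single-crossover derivations of ``target`` from registry parents.

    In ``length`` mode a product matches when its unit count equals the
    target's; in ``sequence`` mode its concatenated units must equal the
    target's sequence exactly (so sequence-mode hits are a subset of
    length-mode hits).  Results are deduplicated over parent order and
    sorted by |offset| — the least-misaligned derivation first.
    """
    if match_mode not in ("length", "sequence"):
        raise ValueError(f"unknown match mode {match_mode!r}")
    pool: Sequence[RepeatAllele] = [
        allele for allele in registry
        if (parents is None or allele.name in parents) and not allele.remainder
    ]
    results = []
    seen: set[tuple] = set()
    for ai, a in enumerate(pool):
        for b in pool[ai:]:
            for event in enumerate_crossovers(a, b):
                for idx, product in enumerate(event.products):
                    if match_mode == "length":
                        hit = len(product) == target.unit_count
                    else:
                        hit = "".join(product) == target.sequence
                    if not hit:
                        continue
                    key = (
                        frozenset({a.name, b.name}),
                        frozenset(event.product_sequences),
                        "".join(product),
                    )
                    if key in seen:
                        continue
                    seen.add(key)
                    results.append(Derivation(
                        target=target.name, parent_a=a.name, parent_b=b.name,
                        event=event, match_mode=match_mode,
                        product_index=idx,
                    ))
    results.sort(key=lambda d: (abs(d.event.offset), d.parent_a, d.parent_b))
    return results


def derivation_report(derivations: Iterable[Derivation]):
    """Tabular view of derivations (one row per event)."""
    import pandas as pd

    rows = []
    for d in derivations:
        rows.append({
            "target": d.target,
            "parent_a": d.parent_a,
            "parent_b": d.parent_b,
            "i": d.event.i,
            "j": d.event.j,
            "offset": d.event.offset,
            "product_lengths": "/".join(map(str, d.event.product_lengths)),
            "sequence_exact": d.match_mode == "sequence",
        })
    return pd.DataFrame(rows)
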