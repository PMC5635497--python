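"""Promoter reference frame, coordinate conversion, and the variant table.

Promoter positions use c.-notation: negative integers counted away from the
translation start (there is no c.0).  The gene sits on the minus strand of dog
chromosome 18, so chromosome coordinates *increase* with distance upstream:

    chr_position = anchor_chr + (|c| - |anchor_c|)

The affine constant is derived from two anchor rows of the loaded table and
cross-checked against every row rather than hard-coded.

The variant table holds one row per alternate allele.  A multi-allelic
tandem-repeat locus (the c.-305 GCCCTC repeat) contributes several rows that
share one locus, so allele-level counts and locus-level counts differ; both
are exposed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

POPULATIONS = ("dog", "wolf", "coyote")

VTYPES = ("substitution", "single_base_deletion", "tandem_repeat_length")


class CoordinateRangeError(ValueError):
    """Position outside the mapped promoter interval."""


class VariantTableError(ValueError):
    """Malformed or internally inconsistent variant table."""


@dataclass(frozen=True)
class ReferenceFrame:
    """Affine, bijective mapping between c.-notation and chr18 coordinates."""

    anchor_c: int
    anchor_chr: int
    strand: str = "-"
    valid_c_range: tuple[int, int] = (-619, -1)

    def __post_init__(self):
        if self.anchor_c >= 0:
            raise ValueError("promoter c positions are negative")
        lo, hi = self.valid_c_range
        if not lo <= self.anchor_c <= hi:
            raise ValueError("anchor_c outside valid_c_range")

    def c_to_chr(self, c: int) -> int:
        """Chromosome coordinate of promoter position ``c`` (minus strand)."""
        lo, hi = self.valid_c_range
        if not lo <= c <= hi:
            raise CoordinateRangeError(
                f"c.{c} outside supported range [{lo}, {hi}]"
            )
        return self.anchor_chr + (abs(c) - abs(self.anchor_c))

    def chr_to_c(self, pos: int) -> int:
        """Exact inverse of :meth:`c_to_chr`."""
        c = -(pos - self.anchor_chr + abs(self.anchor_c))
        lo, hi = self.valid_c_range
        if not lo <= c <= hi:
            raise CoordinateRangeError(
                f"chromosome position {pos} maps outside [{lo}, {hi}]"
            )
        return c

    @classmethod
    def from_anchors(cls, c1: int, chr1: int, c2: int, chr2: int,
                     **kw) -> "ReferenceFrame":
        """Derive the frame from two (c, chr) pairs; slope must be exactly 1
        in |c| (minus-strand orientation)."""
        if c1 == c2:
            raise ValueError("anchors must differ in c position")
        if (chr2 - chr1) != (abs(c2) - abs(c1)):
            raise ValueError(
                "anchor pairs are not consistent with a unit-slope "
                "minus-strand mapping"
            )
        return cls(anchor_c=c1, anchor_chr=chr1, **kw)


_C_LABEL = re.compile(r"c\.(-\d+)")


def parse_c_label(label: str) -> int:
    """Extract the signed promoter position from a label like ``c.-46 T > C``."""
    m = _C_LABEL.search(label)
    if m is None:
        raise VariantTableError(f"cannot parse c position from {label!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class VariantRecord:
    """One alternate allele of a promoter variant (one table row)."""

    c_label: str
    c_position: int
    chr_position: int
    vtype: str
    ref_allele: str
    alt_allele: str
    freq: dict[str, float] = field(default_factory=dict, hash=False)
    id: str | None = None

    def __post_init__(self):
        if self.vtype not in VTYPES:
            raise VariantTableError(f"unknown variant type {self.vtype!r}")
        for pop, f in self.freq.items():
            if not 0.0 <= f <= 1.0:
                raise VariantTableError(
                    f"{self.c_label}: frequency {f} for {pop!r} outside [0, 1]"
                )


@dataclass
class VariantTable:
    """Ordered allele-level records, grouped into loci by promoter position."""

    records: list[VariantRecord]
    frame: ReferenceFrame

    @property
    def loci(self) -> dict[int, list[VariantRecord]]:
        """Partition of records into loci keyed by c position (insertion order)."""
        groups: dict[int, list[VariantRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.c_position, []).append(rec)
        return groups

    @property
    def populations(self) -> tuple[str, ...]:
        pops: list[str] = []
        for rec in self.records:
            for p in rec.freq:
                if p not in pops:
                    pops.append(p)
        return tuple(pops)

    def _check_populations(self, *groups):
        known = set(self.populations)
        for group in groups:
            unknown = set(group) - known
            if unknown:
                raise KeyError(f"unknown population name(s): {sorted(unknown)}")

    def population_restricted_variants(
        self, present_in: set[str], absent_in: set[str]
    ) -> list[VariantRecord]:
        """Allele-level records absent (freq 0) in every ``absent_in``
        population and segregating (freq > 0) in >= 1 ``present_in`` one."""
        self._check_populations(present_in, absent_in)
        out = []
        for rec in self.records:
            if all(rec.freq.get(p, 0.0) == 0.0 for p in absent_in) and any(
                rec.freq.get(p, 0.0) > 0.0 for p in present_in
            ):
                out.append(rec)
        return out

    def population_restricted_loci(
        self, present_in: set[str], absent_in: set[str]
    ) -> list[int]:
        """Locus-level analogue: loci where *every* alternate allele is absent
        in ``absent_in`` populations but the locus segregates in ``present_in``."""
        self._check_populations(present_in, absent_in)
        out = []
        for c_pos, recs in self.loci.items():
            absent = all(
                rec.freq.get(p, 0.0) == 0.0 for rec in recs for p in absent_in
            )
            present = any(
                rec.freq.get(p, 0.0) > 0.0 for rec in recs for p in present_in
            )
            if absent and present:
                out.append(c_pos)
        return out

    def count_loci(
        self,
        vtype_filter: set[str] | None = None,
        polymorphic_in: str | None = None,
        repeat_registry=None,
    ) -> int:
        """Count loci (not allele rows) matching a type filter.

        ``polymorphic_in`` restricts to loci with a nonzero alternate-allele
        frequency in that population.  The 5'UTR GCC microsatellite is
        genotyped separately from this table; passing its allele registry as
        ``repeat_registry`` counts it as one extra tandem-repeat locus
        (polymorphic in a population when >= 2 alleles segregate there).
        """
        if polymorphic_in is not None:
            self._check_populations({polymorphic_in})
        n = 0
        for recs in self.loci.values():
            if vtype_filter is not None and recs[0].vtype not in vtype_filter:
                continue
            if polymorphic_in is not None and not any(
                rec.freq.get(polymorphic_in, 0.0) > 0.0 for rec in recs
            ):
                continue
            n += 1
        if repeat_registry is not None and (
            vtype_filter is None or "tandem_repeat_length" in vtype_filter
        ):
            if polymorphic_in is None:
                n += 1
            else:
                segregating = sum(
                    1 for a in repeat_registry
                    if a.freq.get(polymorphic_in, 0.0) > 0.0
                )
                if segregating >= 2:
                    n += 1
        return n

    def to_tsv(self, path) -> None:
        """Canonical, byte-stable TSV writer (frequencies at 3 decimals)."""
        cols = ["id", "chr_position", "c_label", "vtype", "ref", "alt"]
        pops = self.populations
        with open(path, "w", newline="") as fh:
            fh.write("\t".join(cols + [f"freq_{p}" for p in pops]) + "\n")
            for rec in self.records:
                row = [
                    rec.id or ".", str(rec.chr_position), rec.c_label,
                    rec.vtype, rec.ref_allele, rec.alt_allele,
                ] + [f"{rec.freq.get(p, 0.0):.3f}" for p in pops]
                fh.write("\t".join(row) + "\n")


def load_variant_table(path, frame: ReferenceFrame | None = None) -> VariantTable:
    """Load and validate an allele-level variant TSV.

    When no frame is given it is derived from the first two rows at distinct
    positions and then cross-checked against every row; any coordinate /
    c-label mismatch is reported with the offending rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"id", "chr_position", "c_label"}
    missing = required - set(df.columns)
    if missing:
        raise VariantTableError(f"missing required column(s): {sorted(missing)}")
    freq_cols = [c for c in df.columns if c.startswith("freq_")]

    rows = []
    for idx, row in df.iterrows():
        c_pos = parse_c_label(row["c_label"])
        freq = {}
        for col in freq_cols:
            try:
                f = float(row[col])
            except (TypeError, ValueError):
                raise VariantTableError(
                    f"row {idx + 1} ({row['c_label']}): malformed frequency "
                    f"{row[col]!r} in {col}"
                ) from None
            if not 0.0 <= f <= 1.0:
                raise VariantTableError(
                    f"row {idx + 1} ({row['c_label']}): frequency {f} "
                    f"outside [0, 1] in {col}"
                )
            freq[col.removeprefix("freq_")] = f
        rows.append((idx, row, c_pos, freq))

    if frame is None and rows:
        anchors = []
        for _, row, c_pos, _ in rows:
            if not anchors or c_pos != anchors[0][0]:
                anchors.append((c_pos, int(row["chr_position"])))
            if len(anchors) == 2:
                break
        if len(anchors) < 2:
            raise VariantTableError(
                "need two distinct positions to derive the reference frame"
            )
        frame = ReferenceFrame.from_anchors(*anchors[0], *anchors[1])

    records, bad = [], []
    for idx, row, c_pos, freq in rows:
        chr_pos = int(row["chr_position"])
        if frame is not None and frame.c_to_chr(c_pos) != chr_pos:
            bad.append(f"row {idx + 1}: {row['c_label']} vs {chr_pos}")
            continue
        rid = None if row["id"] in (".", "", None) else str(row["id"])
        records.append(VariantRecord(
            c_label=row["c_label"], c_position=c_pos, chr_position=chr_pos,
            vtype=row.get("vtype", "substitution"),
            ref_allele=str(row.get("ref", ".")),
            alt_allele=str(row.get("alt", ".")),
            freq=freq, id=rid,
        ))
    if bad:
        raise VariantTableError(
            "coordinate / c-label mismatch: " + "; ".join(bad)
        )
    if frame is None:  # empty file with header
        frame = ReferenceFrame(anchor_c=-21, anchor_chr=49908119)
    return VariantTable(records=records, frame=frame)
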