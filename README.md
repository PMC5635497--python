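# promsat

Analysis toolkit for a short, densely polymorphic gene promoter genotyped
across domestic dogs and wild canids: the proximal promoter of the canine
glutathione S-transferase pi 1 (*GSTP1*) gene on dog chromosome 18, which
carries a dozen-plus SNPs, a single-base deletion, a GCCCTC repeat, and a
highly polymorphic GCC trinucleotide microsatellite in the 5′UTR.

The package is aimed at researchers working with Sanger-scale promoter
resequencing panels — a few hundred individuals, one locus, printed-table
sized data — who need the analysis to be reproducible and testable rather
than spreadsheet-bound. It provides:

- **Coordinate frame** — exact, affine conversion between promoter
  c.-notation (negative offsets from the translation start on the minus
  strand) and chromosome coordinates: `chr = anchor_chr + (|c| − |anchor_c|)`,
  derived from anchor rows and cross-checked against every loaded row.
- **Variant table** — allele-level records with per-population frequencies,
  population-restriction filters ("present in wolves and coyotes, absent in
  dogs"), and locus-level counts that distinguish allele rows from loci.
- **Repeat alleles** — decomposition of microsatellite tracts into 3-base
  units anchored at the first base; per-base **purity** against a perfect
  GCC consensus tract of equal length; **simple/compound** classification
  by the interruption-motif units (ACT/GCA); and a name registry using the
  `<unit count>*k` scheme (`16*1` simple, `16*2` compound, ...).
- **Population genetics** — allele frequencies and MAF per stratum,
  Hardy–Weinberg χ² (Pearson, no continuity correction), and pairwise
  D′/LOD from phased haplotype counts.
- **Haplotypes** — Clark-style homozygote-anchored phasing with
  deterministic tie-breaking, the `*<number><letter>(<repeat length>)`
  naming scheme, haplotype diversity
  `Ĥ = n/(n−1) · (1 − Σ pᵢ²)` over n chromosomes, per-breed comparison
  tables, and cross-species sharing counts.
- **Recombination engine** — exhaustive enumeration of unit-boundary
  unequal crossovers (`A[:i] + B[j:]` / `B[:j] + A[i:]`), single-unit
  replication-slippage neighbours, and a derivation search that explains
  observed alleles as crossover products of registry parents, in length or
  sequence-exact mode.
- **Synthetic data** — diploid populations drawn from specified haplotype
  frequencies under random mating, with optional breed structure and
  slippage noise, returning the true diplotypes for recovery scoring.

The study's data tables ship as TSV fixtures (variant table, repeat-allele
registry, species- and breed-level haplotype frequencies), so the whole
analysis runs without downloads.

## Worked example

Score the two extreme microsatellite alleles and ask how the common 11-repeat
dog allele could have arisen:

```sh
$ promsat repeat purity --seq '16*1'     # GCT(GCC)15 vs perfect (GCC)16
97.9
$ promsat repeat purity --seq '22*1'
80.3
$ promsat repeat classify --seq '16*2'
compound
$ promsat recomb derive --target 11 --mode sequence --parents '17,16*1'
target  parent_a  parent_b  i  j  offset  product_lengths  sequence_exact
11      16*1      17        0  6  -6      11/22            True
11      17        17        0  6  -6      11/23            True
```

The purities are the per-base identity of each tract to a perfect GCC tract
of equal length: the near-pure simple 16-repeat allele mismatches at a
single base (47/48 = 97.9%), while the compound 22-repeat allele carries
two interruption motifs (53/66 = 80.3%). The first derivation row says a
single unequal crossover between the two most common dog alleles (17 and
16*1), with the tracts misaligned by six units, produces the 11-repeat
allele's exact sequence, with a 22-unit complementary expansion product
(a 17 × 17 self-exchange can also truncate to the same sequence, second
row).

Population-restriction filters on the packaged variant table:

```sh
$ promsat variants --present wolf,coyote --absent dog
c.-82 C > T     49908180
c.-179 G > C    49908277
c.-305 (GCCCTC)_2       49908403
c.-539 C > T    49908637
```

— the four alleles segregating in the wild canids but fixed in dogs.

A full pipeline run (`promsat run --config run.ini`) chains fixture export,
genotype simulation or loading, per-locus statistics, phasing, diversity
tables and a crossover-derivation report into one output directory with
checksummed, byte-reproducible TSVs.

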