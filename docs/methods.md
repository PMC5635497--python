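# Methods

This note documents the models and procedures implemented in `promsat`,
the parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate frame

Promoter positions use c.-notation: negative integers counted upstream from
the translation start, with no position zero. The gene lies on the minus
strand, so chromosome coordinates increase with distance upstream and the
mapping is affine with unit slope, `chr = anchor_chr + (|c| − |anchor_c|)`.
The additive constant is never hard-coded: it is derived from the first two
rows of the loaded variant table and cross-checked against every row, so a
transcription error in either coordinate column of an input table is caught
at load time with the offending rows listed. Coordinates are 1-based
inclusive; the supported c range defaults to the resequenced amplicon
(c.-619 to c.-1).

## Variant table

One row per alternate allele, with per-population frequencies stored as
given (three decimals, no re-normalisation). Rows at the same promoter
position form one locus, which is how a multi-allelic tandem-repeat locus
(the GCCCTC repeat at c.-305, reference four copies, alternate counts 2, 3
and 5) coexists with biallelic SNP rows. Population-restriction filters are
defined at the allele level (frequency 0 in every excluded population, > 0
in at least one included population) with a locus-level analogue, because
"variants absent in dogs" and "loci polymorphic only in dogs" are different
counts on the same table. The 5′UTR microsatellite is genotyped separately
from the variant table, so locus counts accept the allele registry as an
optional extra tandem-repeat locus.

## Repeat-allele model

A microsatellite tract is decomposed into 3-base units with the reading
frame anchored at the first base — no frame search, since allele sequences
are recorded in frame from the tract start. Three statistics follow:

- **Purity** (percent, three significant figures) is the per-base,
  position-wise identity of the tract to a perfect GCC consensus tract of
  equal length. Per-base (rather than per-unit) identity is the definition
  that makes partially matching units such as GCT or ACC count 2/3 rather
  than 0, giving 47/48 = 97.9% for the simple 16-unit allele and
  53/66 = 80.3% for both 22-unit alleles. Purity is undefined (an error)
  for tracts with a partial-unit remainder, such as the gray-fox allele
  carrying a single interrupting base.
- **Class** is *compound* when any unit is ACT or GCA — the units produced
  by the interruption motif GCTGC[C/A]ACTGCTACC — and *simple* otherwise.
  This keeps the 17-, 18- and 19-unit alleles simple even though they
  contain internal GCT and terminal ACCGCC units.
- **Name**: an exact-sequence match returns the registered name; a novel
  sequence takes the bare unit count when the length is new, otherwise
  `<count>*k` with the next unused suffix (a bare name counts as suffix 1).
  Naming registers the allele, so it is idempotent.

External per-allele scores carried in the registry (predicted repeat
variability, RNA hairpin ΔG) are opaque annotations: stored, round-tripped,
never recomputed.

## Population-genetic statistics

Hardy–Weinberg equilibrium is tested with Pearson's χ² of observed genotype
counts against p², 2pq, q² expectations, df = 1 for biallelic loci, with no
continuity correction; multi-allelic loci are tested over all k(k+1)/2
genotype classes with df = k(k−1)/2. Monomorphic loci return (0, 0) flagged
non-testable, and any expected class count below 5 sets a small-counts
flag rather than silently trusting the asymptotics. MAF is 1 − max allele
frequency, so it extends to multi-allelic loci. Missing genotypes (`./.`)
drop an individual from the affected locus only.

Linkage disequilibrium is computed from phased haplotype counts:
D = p_AB − p_A·p_B, normalised by its maximum attainable magnitude given
the margins (D′ ∈ [0, 1], reported unsigned), and a LOD score defined as
the base-10 log likelihood ratio of the observed haplotype multinomial
against independence. Both require biallelic loci; otherwise the result is
flagged undefined.

## Haplotype phasing

Phasing is Clark's parsimony, chosen because the data are homozygote-rich
short-range promoter genotypes and the haplotypes were originally
constructed from homozygous individuals:

1. Individuals heterozygous at ≤ 1 locus are read directly; their
   haplotypes seed the known set with support `observed_in_homozygote`.
2. Remaining individuals are resolved by subtracting a compatible known
   haplotype; the complement joins the known set with support `inferred`.
   Rounds repeat to a fixpoint (bounded by `max_rounds`, default 20).
3. Individuals no known haplotype can explain are reported unresolved,
   never guessed; individuals with missing calls are never phased.

Determinism: subtraction candidates are ranked by current haplotype count
(descending), then lexicographic state string; pending individuals are
processed in a canonical order (heterozygosity, genotype string, id), so
output is invariant to input row order. The `seed` parameter is accepted
for interface stability but no randomness is drawn. EM- or Bayesian-style
phasing and recombination-aware models are deliberately out of scope at
promoter scale.

Names follow `*<number><letter>(<repeat length>)`: the number keys the SNP
pattern upstream of the microsatellite region (positions at or upstream of
c.-68), the letter the SNP pattern inside the microsatellite, the
parenthetical the repeat unit count — so one SNP background associated with
several repeat lengths yields distinct haplotypes sharing a name stem
(*1A(17), *1A(18)). The registry is seeded with the reference (boxer
assembly) pattern as *1A plus the two named patterns whose defining states
are known (*3: the −185 T deletion; *8: the −408 G); unknown patterns
allocate the next free number or letter, keeping the scheme user-extensible
since the study's full pattern map is not published in the main tables.

## Diversity

Haplotype diversity uses the small-sample corrected estimator
Ĥ = n/(n−1)·(1 − Σ pᵢ²) with n = chromosomes (2 × individuals). The
published frequency tables are truncated (below 0.05 at species level,
0.01 at breed level), so recomputation lumps the missing mass as rare
singletons of frequency 1/n each — the least-assuming completion — and the
comparison carries a soft tolerance (0.01 for the dog value, 0.03 for the
small wolf/coyote samples, where truncation bites harder). With this
completion the recomputed values are 0.860 (dogs, from the breed-table
margin, printed 0.859–0.860), 0.878 (wolves, printed 0.878) and 0.890
(coyotes, printed 0.902). Per-breed tables exclude breeds under five
individuals.

## Crossover and slippage engine

Unequal single crossover of decomposed alleles A and B at unit boundaries
(i, j) yields products `A[:i] + B[j:]` and `B[:j] + A[i:]`; unit count is
conserved, offset i − j = 0 leaves identical parents unchanged, and
enumeration over all (i, j) is exhaustive with deduplication by the
unordered product-sequence pair. Two conventions are deliberate:

- Breakpoints are restricted to unit boundaries. Intra-unit breakpoints
  would create frame-shifted tracts not observed in the allele spectrum
  (the single gray-fox oddity aside).
- Products carry no flanking sequence, so the terminal units (the ACCGCC
  tail) travel with the suffix parent. This convention is what makes the
  two observed derivations sequence-exact: 16*2 × 16*2 exchanging four
  units yields the exact 12*2 and 20 allele sequences, and 17 × 16*1
  misaligned by six units yields the exact 11-repeat sequence with a
  22-unit complement.

Replication slippage is modelled as inserting or deleting one unit within
a run of identical units, the classical single-step polymerase-slip move;
it reproduces the ±1-unit ladder among the pure alleles (14/15/16*1).

The derivation search brute-forces all ordered parent pairs and breakpoints
against a target, in *length* mode (unit count matches) or *sequence* mode
(concatenated units match exactly; always a subset of length mode), sorted
by misalignment |i − j|. Length mode is the default reporting mode because
the 22-unit expansion product of 17 × 16*1 matches no observed 22-repeat
sequence — the engine reports it as a length-only derivation, which is the
honest strength of that inference.

## Synthetic data generator

The generator emulates the study's sampling design: unrelated diploid
individuals, each drawing two haplotypes i.i.d. from a frequency vector
(Hardy–Weinberg random mating), with optional breed labels (and optional
per-breed frequency vectors to emulate breed structure) and optional
slippage noise — each transmitted microsatellite allele mutates with the
given per-transmission probability, at most once, to a uniformly chosen
single-unit neighbour, which is then named against the registry. All
randomness flows from a single integer seed through one generator, so runs
are exactly reproducible.

Default test conditions use five haplotypes over two SNPs plus the repeat
locus at frequencies 0.30/0.30/0.20/0.10/0.10 and n = 200 individuals —
a frequency spectrum and sample size comparable to the study's dog panel
(278 dogs; commonest haplotype ≈ 0.26), small enough that the suite runs in
seconds. The generator does **not** emulate: relatedness or pedigree
structure, breed-specific inbreeding, genotyping or base-calling error,
null alleles, or recombination within the promoter. Passing recovery tests
therefore show the phasing and statistics are correct under random mating
with known haplotype pools; they do not certify behaviour under strong
breed stratification or genotyping artefacts, where Clark phasing is known
to be less reliable.

## Numerical choices and degenerate inputs

- Purity is rounded to three significant figures (the table's precision);
  frequencies are carried as printed, three decimals, and never
  re-normalised.
- Frequency-sum validation uses 1e-6 (diversity inputs) and 1e-9
  (generator specs); missing-mass lumping rounds to the nearest whole
  chromosome.
- Monomorphic loci: HWE returns (0, 0) non-testable; D′ is flagged
  undefined; diversity of a single haplotype is exactly 0.
- Empty sequences, non-ACGT characters, unbalanced shorthand, non-diploid
  genotype cells, unknown registry names and out-of-range coordinates all
  raise typed errors naming the offending input.
- Pipeline outputs are TSV with `#`-metadata headers (tool version, seed,
  input checksums) and are byte-identical across reruns with the same
  inputs and seed.

## Known limitations

- Clark phasing can in principle leave individuals unresolved (reported,
  never imputed) and, like all parsimony phasing, can be misled when a true
  haplotype never appears in any near-homozygous individual.
- The crossover engine enumerates single crossovers only; double
  crossovers, gene conversion and multi-generation dynamics are out of
  scope, as is any mutation-rate estimation.
- Diversity recomputed from truncated published tables is necessarily
  approximate; the exact values would require the unpublished full
  haplotype table.
- Sequence-derivation counts depend on the registry contents: a richer
  allele registry yields more sequence-exact derivations, so reports should
  be read relative to the allele set provided.
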