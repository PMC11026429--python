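# Methods

## The estimation target

For two aligned in-frame coding sequences, Ks is the expected number of
synonymous substitutions per synonymous site and Ka its nonsynonymous
counterpart. Because synonymous changes are nearly neutral, Ks accumulates
roughly linearly with time and a cohort of gene pairs created by a single
event (a whole-genome duplication, a species split) shares a common Ks
peak. Converting a peak to an age uses the molecular clock

    T (years) = Ks_peak / (2 μ),

with μ the synonymous substitution rate per site per year; both lineages
accumulate substitutions independently, hence the factor 2. The default
μ = 6.51648×10⁻⁹ /site/year is the Brassicaceae calibration; it is a plain
parameter (`--mu`) and everything downstream scales as 1/μ. Note that with
this μ, Ks values of exactly 0.05 and 0.09 convert to 3.8 and 6.9 Mya;
rounded Ks inputs and rounded published ages generally do not commute
through the formula, so the package always reports formula-exact values and
rounds only for display (half-up to 0.1 Mya).

## NG86 counting

The estimator is Nei–Gojobori (1986) with equal-path weighting:

- **Sites.** Each codon position contributes one site, split into a
  synonymous fraction = (number of the three possible single-nucleotide
  changes preserving the amino acid) / (number of changes not creating a
  stop codon). Stop codons are excluded from the denominator, so s + n = 3
  per codon. Site counts are averaged over the two sequences,
  S = (S₁+S₂)/2.
- **Differences.** For a codon pair differing at k ≤ 3 positions, the
  synonymous/nonsynonymous step classification is averaged over all k!
  orderings of single-nucleotide steps; orderings passing through a stop
  codon are excluded. If every ordering is blocked, the column is skipped.
- **Correction.** pS = Sd/S and pN = Nd/N are corrected for multiple hits
  with Jukes–Cantor, d = −¾·ln(1 − 4p/3), which diverges at p = 0.75; pairs
  at or beyond that are flagged `saturated`. Columns containing gaps,
  ambiguous bases or stops in either sequence are removed pairwise before
  counting; a strict mode rejects pairs with internal stops outright.

NG86 was chosen over ML codon models (yn00-style) because it is fully
specified by enumeration — the test suite checks (S, N, Sd, Nd) against an
independent brute-force enumerator built on Biopython's translation — and
because at the divergences this pipeline targets (Ks ≤ 0.15) the difference
between counting estimators is far below the analysis's rounding. The
standard nuclear genetic code is used throughout.

Flag semantics: `ok` (usable), `saturated` (pS ≥ 0.75), `too_short` (no
usable codon column), `undefined` (no synonymous sites). Downstream
aggregation uses `ok` records only.

## Synthetic allotetraploid generator

The generator produces datasets with the statistical structure the analysis
assumes, so every stage can be tested against known truth.

- **Sequences.** Ancestors are uniform-random sense codons (stop codons
  excluded). Substitution is synonymous-only and event-based: on a branch
  of length ks, the number of events is Poisson(ks × S) with S the NG86
  synonymous site count of the branch's starting sequence, and each event
  picks uniformly among the currently synonymous, stop-avoiding
  single-nucleotide changes. Multiple hits arise naturally; translated
  proteins never change (dN ≡ 0), isolating the quantity being estimated.
- **Triples.** Each gene slot yields one reference-diploid copy and two
  focal homeologs on a three-taxon star tree. The three pairwise targets —
  ref–A = ks_A, ref–B = ks_B, A–B = ks_paralog — determine the branch
  lengths by the triangle decomposition r = (ks_A+ks_B−ks_P)/2, etc.; the
  scenario validator rejects Ks triples violating the triangle inequality.
  Defaults (0.05, 0.09, 0.102) give branches (0.019, 0.031, 0.071).
- **Layout.** Default scenario: 15 chromosomes, eight assigned to
  subgenome A and seven to B (the published membership pattern), 50 genes
  per chromosome, 300 codons per gene. Homeolog partners rotate round-robin
  over the other subgenome's chromosomes; exact per-chromosome equality is
  impossible with an 8/7 split, so B chromosomes carry ⌈8G/7⌉ or ⌊8G/7⌋
  genes.
- **Reads.** The read simulator emits error-free, uniformly placed
  fixed-length reads from a uniform-random genome; expected depth equals
  the requested coverage.

What the generator deliberately omits: codon-usage bias, indels and
alignment error, selection on synonymous sites, GC drift, rate variation
among genes, sequencing errors, repeats and heterozygosity. Passing tests
therefore demonstrate correctness of the estimators and algebra under the
model's assumptions, not robustness to every property of real data —
real-data Ks clouds are wider and k-mer spectra carry error and repeat
structure that the defaults here do not emulate.

## Subgenome phasing

Gene-level ortholog Ks values (focal copy vs reference diploid, `ok` flags
only) are aggregated per chromosome; chromosomes with fewer than
`min_genes` (default 10) usable records are reported unassigned. The
chromosome medians are then split by the exact optimal two-cluster
partition in one dimension: sort, evaluate all n−1 contiguous splits,
minimize total within-cluster SSE. In 1-D the optimum is always contiguous
in sorted order, so this equals the exhaustive optimum over all 2ⁿ⁻¹−1
bipartitions (asserted by brute force in the tests) while being
deterministic and seed-free, unlike iterative 2-means. Medians rather than
means drive the split because medians are robust to the long right tail of
Ks distributions. The lower-Ks cluster is labeled subgenome A.

A separation statistic (gap between cluster median-of-medians divided by
the pooled within-cluster IQR of medians) guards against over-splitting:
when the gap is below 1× the pooled spread the partition is flagged
ambiguous; all-identical medians withhold labels entirely. These defaults
are package additions (the underlying analysis offers no numeric
criterion) and are configurable.

## Karyotype algebra

Chromosomes are ordered strings of signed ancestral genomic blocks from the
22-block crucifer alphabet — A…X with the K–L and M–N associations treated
as single blocks and W split into halves Wa/Wb — plus a centromere
position. Operators:

- **WGD** duplicates every chromosome (ids suffixed `_1`/`_2`).
- **NCI** splices the whole donor chromosome (optionally inverted) into the
  recipient's internal centromere, removing the donor; n drops by one and
  block content is conserved. The donor's centromere survives inside the
  splice.
- **Inversion** reverses a block segment and flips signs; paracentric mode
  refuses segments spanning the centromere.

`match_ancestral` classifies a chromosome as *shared* when its block
content equals an ancestral chromosome's content, comparing order- and
orientation-insensitively (within-chromosome inversions do not break the
shared call; they are a separate, finer-grained signal). A derived
chromosome carries an NCI signature when one ancestral chromosome's full
content appears as a contiguous strictly internal run flanked on both
sides by blocks that together compose a second ancestral chromosome — this
accepts either donor orientation and post-insertion internal inversions.

Presets: `ACK_Cardamineae_n8` encodes the 8-chromosome ancestral
Cardamineae karyotype (AK1: A+B+C; AK2: D+E; AK3: F+G+H; AK4: I+J; AK5:
(K-L)+(M-N); AK6/8: V+Wa+Q+R; AK7: S+T+U; AK8/6: O+P+Wb+X), centromeres
between the two arm compositions. `R_aquatica_n15` encodes the derived
15-chromosome complement: six duplicated pairs, the two unfused AK2/AK8-6
homeologues, and the fusion chromosome O P −E −D Wb X produced by inverted
insertion of an AK2 copy into the AK8/6 centromere (the negative signs
record the donor's reversed orientation). The fine-scale inversion
breakpoints within the fusion chromosome are below block resolution and
not encoded.

## k-mer genome sizing

Size = (total k-mer instances) / (homozygous peak depth). Counting is
strand-canonical (min of forward and reverse-complement 2-bit encodings,
k ≤ 31), vectorized in numpy. Peak picking is automated: 3-bin moving
average over the dense spectrum, argmax over multiplicities above an error
cutoff (default 3); ties resolve toward the larger raw count, then the
lower multiplicity. The numerator excludes mass at or below the cutoff by
default (error k-mers inflate totals); both totals are reported. For exact
tiling inputs the estimator returns L − k + 1 exactly — the inherent small
−(k−1) edge bias relative to L. The peak is an integer multiplicity, so
size estimates carry a ±1/peak discretization; at the test scale
(1 Mb genome, 30× coverage, 100 b reads, k = 21, expected per-k-mer depth
24×) this sits well inside the 5 % recovery check.

## DEG timing and leaf complexity

DEG calling applies strict thresholds (FDR < 0.01, |log₂FC| > 1) to
precomputed contrast tables — the differential-expression statistics
themselves are inputs, not re-derived. Timing classes over the 1 h and 4 d
contrasts are pure set algebra (early = 1 h only, throughout = both,
late = 4 d only), tracked separately for up- and down-regulation. The
Dissection Index DI = perimeter/√area is scale-invariant with the circle
as its minimum 2√π ≈ 3.545.

## Problem sizes and reproducibility

Default test/acceptance problem sizes — 1000 replicate pairs × 300 codons
for estimator recovery, 20 seeds × (750 genes × 3 copies) for phasing
recovery, 1 Mb at 30× for k-mer sizing — were chosen as the smallest scales
at which the stochastic checks are comfortably stable; all complete in a
few minutes on one core. Every random stage consumes a
`numpy.random.Generator`; pipeline stages derive their seeds from one
global seed by hashing the stage name (blake2s, < 2³¹), so a single integer
reproduces an entire run byte-for-byte.

## Known limitations

- NG86 assumes no transition/transversion bias and equal codon usage; real
  Brassicaceae data would shift absolute Ks slightly relative to ML
  estimators (immaterial at the ≤ 0.15 scale targeted here).
- The phaser fits exactly two clusters; higher-ploidy systems and
  mosaic/exchanged chromosomes are out of scope.
- NCI detection works at block granularity; it cannot see rearrangements
  within a block, and it requires donor content to remain contiguous.
- The k-mer sizing module does not model heterozygosity or repeat peaks;
  it reports the simple total/peak ratio.
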