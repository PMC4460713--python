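# Methods

## Coordinates, windows and the pad character

All positions are 1-based, inclusive, in protein space — the convention of
both dbSNP protein links and UniProt feature tables. A window of flank *f*
(default 7) around position *i* is the string of residues *i−f … i+f*,
always of length 2f+1, padded with `-` where it runs past a terminus. The
pad is deliberately distinct from the unknown residue `X`: a pad means *no
sequence exists there* and contributes to neither overlap nor identity
counts, while `X` is real sequence of unknown identity and participates in
alignment as a never-matching residue. Window centers can never be pads, and
pads only occur as a contiguous prefix/suffix.

## Sliding-window offset resolution

`slide_candidates` superposes the SNP window on the PTM window at every
offset k ∈ [−f, +f] (the SNP window's center over PTM-window index
center+k) and counts, over column pairs where both windows carry real
sequence, the overlap and the exact residue identities. Scoring is identity
counting, not matrix-weighted: the procedure asks "is this the same peptide,
possibly shifted?", not "are these homologous?". Candidates must satisfy

* `overlap >= min_overlap` (default 8, a majority of the window must anchor
  the match), and
* `overlap − identities <= max_mismatch` (default 1, tolerating a single
  cross-database sequence discrepancy).

Survivors are ordered by identities descending, then |k| ascending, then
negative before positive k. A unique leader on identities is accepted
(method `slide`). Two or more candidates tied on identities indicate a
sequence repeat; the pair is then re-resolved by global alignment (method
`global_fallback`). If no candidate survives, the pair yields no hit —
detection prefers missing a hit over reporting a wrong offset.

## Global-alignment fallback

`needleman_wunsch` computes the optimal global pairwise alignment under the
affine gap model, with defaults mirroring EMBOSS Needle: BLOSUM62, gap open
10.0, gap extend 0.5 (a gap of length L costs open + (L−1)·extend), and free
end gaps. It is built on Biopython's `PairwiseAligner`; residues outside the
matrix alphabet are scored through the matrix's `X` row, and ties among
co-optimal alignments are broken by taking the first alignment in the
aligner's deterministic enumeration order. Substitution matrices can also be
read from NCBI/EMBOSS-format text files.

`fallback_offset` aligns the full protein sequences when both are available
(preferred — more context disambiguates repeats) and otherwise the de-padded
windows. It locates the alignment columns holding the SNP and the PTM
position and reports the signed number of SNP-side residues between them, so
the offset is measured in SNP-protein residue units and always indexes a
real residue. If either focal residue sits opposite a gap, or the offset
falls outside ±f, the pair yields no hit.

## Detection, classification, de-duplication

Candidate (SNP, PTM) pairs are restricted to accession pairs in the
id-map and to |snp.position − ptm.position| ≤ f + slack (slack default 10),
bounding the cross-database coordinate drift the pipeline will chase.
Stop-gain SNPs are aligned using their reference-allele window — the variant
peptide does not exist — and are retained at any offset in [−f, +f]; a
`truncates_site` flag marks stops at or before the site (offset ≤ 0), which
abolish it outright, versus downstream stops that merely perturb the motif.
A missense SNP whose reference residue disagrees with the PTM window at the
aligned column is still a valid hit within the mismatch budget (databases
disagree — that is the reason alignment exists); the disagreement is logged.

De-duplication keys on (rsID, PTM protein, PTM position, PTM type) and
prefers experimental evidence over predicted, the sliding method over the
fallback, then more identities; the survivor's `n_merged` records how many
records collapsed. The rule is one consistent choice — summary tables built
from multi-source catalogs are sensitive to this order, and alternative
orders produce slightly different marginal counts.

## Ratio conventions

Site-coverage and trait tables print ratios rounded to 3 decimals;
the functional-class enrichment table prints coverage truncated (floored) to
5 decimals. Both conventions are exposed (`coverage_ratio`,
`truncate_ratio`) because the published tables this package reproduces
demonstrably use one in the 3-decimal tables and the other in the 5-decimal
table. One published functional-class row prints a coverage (0.00114) that
is not the quotient of its own printed counts (186/179,325 ≈ 0.00104); the
implementation computes the literal quotient and treats the printed value as
a typo, asserted as a documented discrepancy in the tests. p-values display
with a 2-decimal mantissa in scientific notation (3 decimals when ≥ 0.001)
and are capped at 0.999 for display only; exact values are retained
internally.

## Enrichment statistics

The enrichment test is the one-sided (upper-tail, "greater") Fisher exact
test on the 2×2 table (class vs rest) × (disease-associated vs not), i.e.
P(X ≥ k) for X ~ Hypergeometric(N, K, n). The one-sided upper tail is the
only direction consistent with the published significance pattern: classes
observed below their expectation (introns, frameshifts) come out near 1,
classes above it come out small. Classes may overlap and need not exhaust
the population (the published functional classes sum to more than the SNP
universe), so only the per-row constraints k ≤ n ≤ N and k ≤ K are enforced.

The tail is summed in log space from log-gamma point masses (`gammaln` +
`logsumexp`), which keeps p ≈ 10⁻⁶⁷ tails exact to floating-point precision
for populations up to ~10⁸; the test suite verifies agreement with an exact
rational-arithmetic oracle to relative error 10⁻¹⁰ and with
`scipy.stats.hypergeom.sf` as an independent cross-check. For Table-style
PTM-type enrichment the population is the distinct PTM-SNP rsIDs and
distinctness is counted at the rsID level (one SNP may hit several sites).
No multiple-testing correction is applied.

## GWAS stage

* **QC order.** Sample-level filtering precedes SNP-level filtering;
  per-SNP counts are recomputed in between. Boundary semantics follow the
  stated thresholds exactly: removal at missing rate strictly > 3% (samples)
  and > 1% (SNPs), HWE p ≤ 10⁻⁴ inclusive, MAF strictly < 1%.
* **HWE.** The exact conditional test (not the χ² approximation), computed
  in controls only — the appropriate choice for case/control data where true
  disease association distorts case genotype frequencies. Implementation
  sums, over all heterozygote counts compatible with the observed allele
  totals, the conditional probabilities not exceeding that of the observed
  count; log-factorial arithmetic with a 10⁻¹² relative tolerance on the
  inclusion comparison guards against rounding of mathematically equal
  masses.
* **MAF** is computed pooled across cases and controls (cases-only or
  controls-only are defensible alternatives; pooled is the documented
  choice here).
* **Trend test.** The 1-df Cochran–Armitage statistic with weights (0, 1, 2);
  degenerate variance (every sample one genotype) reports χ² = 0, p = 1 with
  a flag rather than an error. The suite checks the N·r² identity against an
  independent correlation-based computation and the test's type-I error
  calibration.
* **LD pruning is intentionally absent** to preserve candidate SNPs near
  PTM sites; users wanting pruned panels should prune upstream.

## Synthetic data generator

The generator exists to give every pipeline stage inputs with known ground
truth. What it emulates, and its defaults:

* **Proteomes**: 1,000 proteins, lengths uniform on [100, 400], residues
  i.i.d. uniform over the 20 amino acids. Uniform residues rather than
  natural frequencies: motif realism is irrelevant to the mapping logic
  under test, and uniform sequences make spurious window matches rarer, not
  commoner, than reality — the repeat-insertion noise channel exists to
  create the hard cases deliberately.
* **Cross-database noise**: the PTM-database copy of each protein can
  receive (i) an N-terminal extension of up to `coordinate_shift_max` random
  residues (coordinate drift), (ii) a tandem duplication of a
  `repeat_unit_len` unit (repeat ambiguity), and (iii) one point
  substitution per planted PTM window with probability `substitution_rate`.
  The substitution column is chosen so no window receives more than one
  substitution in total, including windows that overlap another site's —
  the noise condition is "at most one discrepancy per window", and the
  guarantee is enforced rather than left to chance. All defaults are 0
  (identical databases).
* **Annotations**: 2,000 PTM sites at interior positions (types drawn from a
  small weighted vocabulary dominated by phosphorylation), 5,000 SNPs of
  which 20% are placed "far" (> 18 residues from every site, outside the
  candidate band) and 3% are stop-gains, matching the stop-gain share of the
  real nsSNP catalog; planted offsets are uniform on [−7, +7] unless a
  distribution is supplied.
* **Disease catalog**: SNP-level Bernoulli status — background rate 2×10⁻⁴,
  PTM-SNPs at the rate implied by an odds ratio of 4.4 (the enrichment
  magnitude the analysis is meant to detect); association p-values
  log-uniform on [10⁻¹², 10⁻⁵).
* **Genotype panels**: controls drawn from Hardy–Weinberg proportions at a
  per-SNP MAF (uniform on [0.05, 0.5]); cases from the additive allelic
  odds model, genotype probabilities ∝ HWE(g)·ORᵍ; 2,000 cases / 2,000
  controls; optional missingness. A separate deterministic constructor
  plants exact violations of each QC threshold for bookkeeping tests.

Every generator output is a pure function of `SimConfig`; each stage derives
an independent stream from the seed.

What passing tests on this generator do **not** show: real proteomes have
compositional bias, homologous families and real tandem repeats, so the
spurious-match and ambiguity rates measured here underestimate reality;
cross-database differences include isoform choices and internal indels, not
just N-terminal shifts; real GWAS panels carry LD structure and population
stratification that the trend-test calibration deliberately omits. The
detection guarantees established on synthetic data are of the form "offsets
recovered are correct; noise causes misses, not wrong answers", and that
asymmetry is the property expected to transfer to real data.

## Problem sizes and numerical choices

The shipped test suite and `scripts/acceptance.py` run at desk scale:
detection recovery on 200-protein / 400-site / 1,200-SNP instances (clean
and noisy), odds-ratio recovery pooled over 10 × 10⁵ SNPs, trend-test
calibration on 10,000 null SNPs and 100 planted-effect seeds. These sizes
give binomial/Woolf intervals tight enough for the assertions made while
keeping runs reproducible in minutes; all scale linearly if increased.
Exhaustive oracle comparisons cover all hypergeometric instances with
N ≤ 60, all Hardy–Weinberg triples with ≤ 60 samples, and all alignment
pairs with combined length ≤ 5 over a 4-letter alphabet, with seeded random
sampling beyond.

## Known limitations

* Trait terms are compared case-insensitively after whitespace
  normalization, with no ontology mapping; synonymous trait strings from
  different catalogs count as different traits.
* The de-duplication preference order is principled but not unique; absolute
  category counts depend on it.
* No local alignment, no vectorized/banded aligner — inputs are desk-scale.
* The GWAS stage has no covariate adjustment, stratification correction or
  imputation, and reads aggregate counts or a simple 0/1/2 sample matrix,
  not binary PLINK filesets.
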