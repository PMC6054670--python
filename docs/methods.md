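# Methods

This note documents the statistical model behind `pnetloh`, the default
parameters and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical/design decisions a maintainer would
want recorded.

## The purity mixture model

All DNA-level inference shares one model. A sequenced tumor sample is a
mixture of a fraction ρ ∈ (0, 1] of tumor cells and 1 − ρ of diploid
stromal cells. At a locus of integer copy number c in the tumor cells:

- expected tumor/normal depth ratio: `f(c, ρ) = (ρ·c + 2(1 − ρ)) / 2`
- expected tumor BAF at a germline het site with a ALT copies in tumor
  cells: `b(a, c, ρ) = (ρ·a + (1 − ρ)) / (ρ·c + 2(1 − ρ))`

Useful closed forms: one-copy loss with the ALT allele retained gives
b = 1/(2 − ρ); copy-neutral LoH gives b = (1 + ρ)/2; an unopposed
germline variant at CN = 1 has tumor ALT:REF = b/(1 − b) = 1/(1 − ρ).
Purity is a per-tumor *input* (default 0.5): joint purity/ploidy
estimation is deliberately out of scope, matching how deep targeted
panels are usually analyzed with an externally estimated or assumed
stromal fraction.

## Germline heterozygote detection

A site is het iff (i) germline BAF lies strictly in (0.4, 0.6),
(ii) depth ≥ `min_depth` (default 50, mirroring the variant-filter depth
floor; no separate threshold is warranted at panel depths), and
(iii) the exact two-sided binomial test of REF:ALT = 1:1 does not reject
at the 1 − α confidence level (α = 0.05). The two-sided p-value sums all
outcome probabilities not exceeding the observed outcome's mass; for the
symmetric p = 0.5 null this equals `min(1, 2·P(X ≤ min(k, n − k)))`.

A "compatibility probability ≥ 0.95" requirement could also be read as
a literal p ≥ 0.95; that reading rejects nearly every true het at high
depth (at depth 100 it accepts only k ∈ {49, 50, 51}), so the
not-rejected-at-95% reading is the default. Both are exposed via the
`criterion` argument.

## Tile log-ratios and segmentation

Tile counts (3 kb windows by default) are processed as: library-size
scaling of tumor to normal totals; `log2((t + 0.5)/(n + 0.5))` with a
0.5 pseudocount so zero tiles stay finite; loess regression of the raw
ratio on log2 normal count (removes intensity-dependent bias;
`frac = 0.3`, `delta` = 1% of the covariate range for speed); masking of
tiles with normal count < 10 or overlapping the mappability blacklist.

**Diploid anchoring.** The residual track is recentered by the median of
per-chromosome medians rather than the plain genome-wide tile median.
With per-tile noise of ~0.4 log2 units, the tile-level distribution of a
heavily aneuploid genome (e.g. ten lost chromosomes) is a blur of
overlapping CN clusters whose global median falls *between* clusters,
shifting every CN call upward; chromosome-level medians are tight
(SE ≈ 0.015 at 1000 tiles), so their median reliably lands on the modal
— diploid — state. This assumes fewer than half of the chromosomes share
a same-direction aberration; a genome that is mostly triploid or mostly
haploid would be mis-anchored (see Limitations).

**Outlier smoothing.** Isolated single-tile spikes deviating > 3 robust
SDs (MAD-based, per chromosome) from their 5-tile rolling median *and*
from both immediate neighbours are shrunk to the window median; requiring
the neighbour condition preserves genuine two-tile micro-segments.

**CBS.** Circular binary segmentation maximizes the two-sample
t statistic between an arc of tiles and its complement (arcs wrapping
the chromosome ends are equivalent, as label partitions, to
complementary interior arcs, so scanning interior arcs with both
endpoints free covers the circular family). A split is accepted when the
permutation p-value (1000 label shuffles, seeded; early termination once
significance is unattainable, which cannot change the decision) is
< α = 0.01 and every resulting piece has ≥ 3 tiles; the procedure
recurses into the pieces. Afterwards adjacent segments are merged while
their means differ by less than `max(merge_tol, undo_sd·σ̂)` with
`merge_tol = 0.05`, `undo_sd = 1` and σ̂ the robust per-tile noise SD
estimated from first differences: amplitude changes below the tile noise
floor are more often permutation-test artifacts than real copy-number
steps, and suppressing them holds the null false-split rate comfortably
below the nominal α (measured ≈ 0.7% at α = 1%). Whole-chromosome
events are unaffected by the merge rule because they produce no
intra-chromosome boundary. Integer CN per segment is the
`argmin_c |r̄ − log2 f(c, ρ)|` over c = 0..8, ties broken toward the
diploid state.

## LoH calling

The LoH statistic is the mirrored BAF deviation d = |b_T − 1/2| averaged
over a segment's het sites — agnostic to which parental allele was
retained, so copy-loss and copy-neutral LoH are treated identically. The
base threshold is θ(ρ) = ½·(1/(2 − ρ) − ½), half the one-copy-loss
deviation: genuine LoH of any kind (deviation ≥ ρ/2) clears it, while
balanced segments at panel depth stay well below (null E[d̄] ≈ 0.04 at
150×, 100 hets).

One adjustment is required beyond the plain threshold: allelic imbalance
is *not* specific to LoH. A trisomic segment carries its hets at 2:1,
deviation (1 + ρ)/(2 + ρ) − ½, which exceeds θ(ρ) for every ρ although
both parental alleles are present. Segments assigned CN ≥ 3 therefore
use a raised threshold — the midpoint between the most-balanced
configuration (a = ⌈c/2⌉) and the fully unopposed one (a = c) — which
separates, e.g., 2:1 trisomy from 3:0 trisomic LoH at all purities.
Without this, unbalanced gains in aneuploid tumors inflate LoH counts
and corrupt the recurrent-set mining.

Segments with < 10 mapped hets inherit the chromosome-level pooled call;
chromosomes with < 10 hets in total get an unknown (NA) flag that is
excluded from LoH counts rather than silently counted as diploid.

Per autosome: dominant CN is the bp-weighted mode of segment CN;
whole-chromosome LoH requires ≥ 80% of covered bp in LoH segments
(partial LoH stays segment-level and marks the chromosome
heterogeneous); a chromosome is heterogeneous when more than one CN
state each covers ≥ 20% of it (the mixed loss/amplification pattern seen
in tumors with strong intra-chromosomal CN variation).

## Variant rules

Post-calling somatic filters (all must hold): tumor depth ≥ 50, normal
depth ≥ 50, tumor ALT ≥ 10, germline ALT ≤ 2, position outside the
mappability blacklist. Every record keeps its full list of fail reasons;
malformed records are rejected with reason `malformed`, never dropped.

Unopposed germline variants: germline BAF in (0.4, 0.6) (a "~1:1" band;
reuses the het-calling interval), locus inside an LoH segment, tumor
ALT:REF ≥ 1.5. The observed ratio is additionally compared with the
purity-expected ratio for the segment's CN with ALT retained; the
result is a `purity_consistent` *flag* (tolerance 1.0 on the ratio), not
a hard filter, because the retained allele at a real locus may be REF.

Biallelic inactivation per gene and tumor: `biallelic` = passing somatic
variant in the gene and LoH over its chromosome; `monoallelic` = variant
without LoH; `loh-only` = LoH without variant; `wild-type` otherwise.

Coding mutation rate = passing coding variants / (bp callable at ≥ 50× /
10⁶).

## Cohort grouping

High-LoH tumors have ≥ 8 LoH chromosomes; the recurrent set is every
chromosome with LoH in ≥ 80% of high-LoH tumors (empty when there are
none — mining is data-driven rather than hard-coding the canonical ten,
which remain available as a constant for comparison). Classification:
tumors without a passing somatic *MEN1* variant are Group 3; *MEN1*-
mutant tumors are Group 1 when they have chr11 LoH and cover ≥ 80% of
the recurrent set, else Group 2 (a *MEN1*-mutant tumor without chr11 LoH
is an anomaly, flagged but still Group 2). The 80% overlap tolerates
noisy dropout of one–two chromosomes from the pattern.

Clinical association uses an exact conditional Fisher test on 2×k
(k ≤ 3) contingency tables — group × (low vs high grade) and group ×
metastasis — with the two-sided p-value defined by the probability-mass
criterion and computed by full enumeration of tables with the observed
margins. Grades are collapsed to low (G1) vs high (G2–3) to keep the
table 2×k. The two tests are pre-specified and reported raw, without
multiplicity correction.

## Dosage-expression analysis

Batch centering subtracts, per gene and per batch (e.g. FFPE vs fresh
frozen), the within-batch mean — an additive batch model; singleton
batches are an error since centering would zero them. Z-scores are
gene-wise (x − mean)/SD across the cohort with sample SD (ddof = 1);
zero-variance genes get Z = 0 plus a flag. Genes map to chromosomes and
segments by midpoint. The per-tumor dosage statistic is the Pearson
correlation across autosomes between dominant CN and mean chromosome
expression; it is undefined (NaN, excluded from histograms) for euploid
tumors rather than recorded as 0. Chromosome-loss comparisons use the
Mann–Whitney U test (exact when the smaller group has ≤ 8 tumors and no
ties, tie-corrected normal approximation otherwise), with loss defined
as dominant CN < 2 and intact as CN = 2 — copy-neutral LoH leaves
dosage, and hence expression, unchanged.

## The synthetic cohort

Defaults describe the study conditions used throughout the tests: 39
tumors (10 Group 1, 16 Group 2, 13 Group 3), a desk-scale genome of 22
autosomes × 3 Mb (1000 × 3 kb tiles, 200 SNP positions, 50 genes each),
150× mean tile and SNP depth, purity uniform on [0.4, 0.8] (the real
cohort's purity distribution is unknown; this range brackets the 50%
working assumption from both sides), negative-binomial tile counts
(size 30, CV ≈ 0.2 at 150×), beta-binomial allele counts (precision
500, the mild overdispersion of a well-behaved deep panel), 50% of
candidate SNP sites heterozygous, 0.2% sequencing-error ALT fraction at
hom sites.

Karyotypes: Group 1 tumors have LoH of the canonical ten chromosomes,
each copy-neutral with probability 0.2 (so callers must handle CN = 2
LoH), plus a somatic *MEN1* hit; Group 2 chr11 monosomy plus *MEN1*;
Group 3 no *MEN1* hit and a per-tumor aberration rate uniform on
[0, 0.35] per chromosome (monosomy 50% / trisomy 40% / copy-neutral LoH
10%), spanning euploid to extensively aneuploid. Variants per tumor:
the *MEN1* hit (VAF consistent with mutation of the retained chr11
copy), two diploid passengers (VAF ρ/2), four artifacts cycling through
low depth, < 10 tumor ALT reads, 3–7 germline ALT reads and a
blacklisted position (to exercise every filter), two unopposed and two
opposed germline hets. Expression: gene baseline N(7, 1), dosage slope
β = 0.5 log2 units per copy, noise SD 0.5, +1.0 additive offset for the
second of two alternating batches. Clinical labels are drawn with
group-dependent probabilities (Group 1 mostly high grade, 40%
metastasis; Group 2 almost all low grade, none; Group 3 mixed).

What the generator does *not* emulate: GC/mappability coverage waves
beyond the masked blacklist, mapping artifacts, subclonal CN states,
correlated noise along the genome, multi-allelic sites, and real probe-
level expression effects. Passing tests therefore demonstrate
correctness of the inference under the stated noise model, not
robustness to every artifact of real capture data.

## Numerical choices and degenerate inputs

- Depth-0 sites are errors for the binomial test; zero-coverage tumor
  loci are skipped (with a warning) by the unopposed-variant rule.
- CN ties break toward diploid; ρ = 1 with c = 0 (no DNA) is an error.
- Permutation p-values use (exceedances + 1)/(permutations + 1); the
  early-stop bound is `ceil(α·(n_perm + 1))` exceedances.
- Chromosome-call NA propagation: unknown-LoH segments are excluded from
  both numerator and denominator of the 80% rule.
- All simulation and segmentation seeds derive from a single user seed
  via `SeedSequence` spawning; tumor-specific streams hash the tumor id
  with CRC32 so results do not depend on processing order.

## Problem sizes

Validation runs use the full 39-tumor desk-scale cohort (858
tumor-chromosome calls), 10⁵ simulated hom sites and 5×10⁴ het sites
for caller calibration, 500 step tracks and 2000 null tracks of 200
tiles for the segmentation calibration, and 20 replicate cohorts for
Mann–Whitney power — sizes at which every reported rate has a standard
error well inside the margins being asserted.

## Known limitations

- Diploid anchoring fails if > 50% of chromosomes are shifted in the
  same direction (near-haploid or near-triploid genomes); such genomes
  would need an external ploidy prior, which is out of scope.
- Sub-noise-floor segmental events (< 1 tile-SD amplitude, e.g. a
  one-copy loss below ~35% purity at panel depth) can be merged away by
  the undo rule; lowering `undo_sd` trades false splits for sensitivity.
- LoH at chromosomes without het coverage is unknowable and reported NA.
- The unopposed-variant consistency check assumes the ALT allele was
  retained; an unlucky phase makes a true unopposed variant fail the
  ALT:REF ≥ 1.5 gate (it is then simply not reported).
- Sex chromosomes are not modelled; all karyotype logic is autosome-only.
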