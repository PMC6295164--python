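# Methods

This note documents the models behind karyoadapt, the choices made where
several reasonable definitions exist, and what the synthetic-data tests
do and do not establish about real data.

## Karyotype calling from read depth

The caller assumes whole-chromosome copy-number changes only: a single
read density summarizes each chromosome, and sub-chromosomal CNVs, GC
bias and mappability variation are out of scope. Reads are counted by
midpoint (each read contributes to exactly one chromosome; the rule is
unambiguous and count-conserving, unlike overlap-fraction schemes).

*Telomere window.* The terminal 15 kb of each chromosome end is
**excluded** from counting (`telomere_exclusion`, bp, default 15 000).
Subtelomeric repeats cross-map between chromosomes and distort densities,
and excluding them from an otherwise full-length count is what makes
densities comparable across chromosomes of different sizes. The opposite
reading — counting *only* the subtelomeric windows — is available as
`subtelomeres_only=True` but would defeat that purpose and is not the
default.

*Baseline.* With chromosomes ranked by density ascending (ties broken by
genome order, stable sort), the baseline is the arithmetic mean density of
rank positions `⌈C/4⌉ < r ≤ ⌈C/2⌉` (the second-lowest quartile; for the
16-chromosome yeast genome, ranks 5–8). This quartile is below the
aneuploid chromosomes of even heavily aneuploid strains (gains push ranks
up) and above dropout artifacts at the very bottom. A median variant
(`baseline_stat="median"`) is provided; with four chromosomes in the
quartile the two rarely differ.

*Integer calls.* `copy` rounds to integer with ties at .5 going **away
from the basal ploidy** (haploid 1.5 → 2; diploid 1.5 → 1, 2.5 → 3), so a
chromosome sitting exactly between states is called aneuploid rather than
silently normalized. Zero-copy calls are emitted (with a warning) rather
than suppressed: nullisomy is lethal in vivo, so such a call nearly always
flags a coverage problem worth seeing.

## Co-occurrence statistics

Aneuploidy events are direction-specific (`chrVIII+` vs `chrIX−`).
Haploid cohorts use gain-only events by default because losses are
lethal; diploid cohorts use both. The significance statistic is the
**hypergeometric point probability** `P(X = k)` at the observed overlap,
computed in log space with `lgamma` (exact to double precision over the
support, symmetric in `K` and `n`). A cumulative one-tailed variant
(`stat="tail"`) is available; the point statistic is the default because
it is the form under which the headline cohort p-values of this analysis
style are reported. No multiple-testing correction is applied — results
are compared against fixed thresholds (0.001, 0.05, 5 × 10⁻⁷ are the
conventional choices at cohort sizes of 10², 25 and several hundred,
respectively), which are left to the caller.

Correlation heatmaps use Pearson r on the **continuous** copy values,
while the inclusion mask (pairs shown at all) and the hypergeometric
tests use the **binarized** calls; this mirrors how the two displays are
used together. Pairs where either chromosome has no observed aneuploidy,
or a constant column, are excluded.

*Pooled karyotype SD* is defined as `sqrt(mean over chromosomes of the
across-strain sample variance (ddof = 1))` of continuous copies — a
homogeneity measure that is 0 for a clonal cohort and scales linearly
with the spread. Pooling per chromosome (rather than per strain) was an
open choice; the per-chromosome form weighs every chromosome equally
regardless of cohort structure.

*DNA-content burden* is `100 · Σ_i |c_i − p| · f_i / p` (percent), with
`f_i` the genome length fraction. Normalizing by `p` makes haploid and
diploid burdens comparable; for a haploid cohort without losses it equals
the simpler signed form `Σ (c_i − 1) f_i`.

## CCNI scoring

The normalization `rel = obs · G / (R_row · C_col)` with arithmetic means
over present cells is exact on interaction-free matrices: any rank-1
multiplicative matrix (single-disome effects times marker effects) maps
to all ones, so everything that survives normalization is pairwise
interaction. Three statistics are offered for `R`, `C`, `G`: arithmetic
mean (default), median (robust to a single outlier cell), and geometric
mean. The geometric variant is the only one *exactly* invariant to
rescaling an individual row or column of a matrix that already contains
interactions (it is row/column mean-centering in log space); the
arithmetic scheme is first-order invariant, which is ample at the ≤ 2×
marker effects seen in practice, and is the default because its values
correspond to the published normalization arithmetic. Scores average the
two marker orientations; single-orientation pairs are flagged rather than
dropped. Missing cells (unmeasurable combinations, e.g. the same
chromosome twice) are excluded from all means.

When planted interactions are recovered in simulation, the benchmark
plants interactions on **disjoint** chromosome pairs: two interactions
sharing a chromosome contaminate each other's row/column effects, and no
row/column scheme can attribute the shared signal — a genuine
identifiability limit of the design, not of the estimator.

## Arm-level tumor karyotypes

Segment values are treated as log2(copy/2) ratios (the GDC convention);
`linear=True` converts linear ratios on input. SEG coordinates are taken
as 0-based half-open by default with a `one_based` flag for 1-based
inclusive dialects. Arm intervals come from cytoband files (p = union of
`p*` bands, q = union of `q*` bands, `acen` bands in neither; acrocentric
chromosomes have no p arm).

Per sample × arm, segments are intersected with the arm and summarized by
the overlap-length-weighted mean and weighted median (tie rule: the lower
value at an exact 50% cumulative-length boundary). Both summaries are
invariant to splitting segments (refinement invariance). A sample is
excluded when **any** arm has |weighted mean − weighted median| > 0.2
(strict): a large gap means a focal amplification/deletion dominates the
mean and the arm call would not reflect an arm-level event. Arm calls are
±1 at |weighted mean| ≥ 0.2 (inclusive), 0 otherwise; the 0.2 call
threshold is a configuration value chosen symmetric with the exclusion
gap (log2 0.2 ≈ a 15% cell-fraction arm gain) — it is not a biologically
derived constant. Samples with fewer than two aberrant arms ("no complex
aneuploidy") are dropped from statistics, and arms aberrant in ≤ 10% of
samples from display. Purity/ploidy correction and focal-event calling
are out of scope.

## Phenotype metrics

Doubling time is `ln 2 / slope` of an ordinary least-squares fit of
ln(OD) against time, using all points (no outlier rejection); R² is
reported so poor exponential fits are visible. qPCR copy number uses a
modified ΔΔC_t: duplicates are averaged, ΔC_t = target − reference primer
within strain, fold = 2^(−ΔC_t), and the test/wild-type fold ratio times
the basal ploidy is the copy number. Because both orderings of the two
differences give the same ratio, the scheme is insensitive to which
difference is labelled "Δ" and to per-strain plate offsets.

## CIN-adaptation simulator

The simulator is the minimal generative model under which the cohort
statistics are well-posed — it is a testbed, not a mechanistic model of
spindle biology.

State: a population of `population_size` karyotypes (integer copies per
chromosome, capped at `max_copy` = 6). Each generation: (1) every
chromosome of every cell gains or loses one copy with probability `m/2`
each (`missegregation_prob` m, per chromosome per division; gains and
losses of one copy only); (2) the next generation is sampled with
replacement with probabilities proportional to multiplicative fitness
`w = Π_i s_i(c_i) · Π_{i<j} ε_ij(c_i, c_j)`, with unlisted copy states
neutral and copy 0 lethal in haploids by default. Missegregation is
applied to the divisions that *produce* a generation, before that
generation's viability selection — so a lineage whose survival requires
an immediate gain (the chromosome-2-like "essential first step"
scenario) can be seeded from a euploid founder. After each of `rounds`
rounds of `generations_per_round` generations the population is
bottlenecked to one cell drawn uniformly (clone picked proportional to
frequency), emulating streaking for single colonies. Replicates that go
fully inviable are restarted with fresh randomness up to `retry_cap`
times and reported.

Defaults: `m = 0.02` (within the 0.5–7.7% per-division missegregation
rates measured for strong CIN mutants), `rounds = 10`,
`generations_per_round = 20` (~200 generations of serial passaging),
`population_size = 200`. The population size is an *effective* size: a
colony grows to ~10⁶ cells, but after repeated single-cell bottlenecks
the dynamics of selection and drift are governed by a far smaller
effective number; 200 keeps selection at s ≈ 1.3 strongly dominant over
drift while making a 100-replicate cohort simulate in about a second.
All randomness flows from one root seed (NumPy `default_rng`);
replicates are vectorized, not independently seeded streams.

What the simulator does **not** emulate: point-mutation co-evolution,
chromosome rearrangements, copy-number jumps > 1 per division,
environment shifts between plate and liquid, or mechanistic missegregation
biases (e.g. size-dependent missegregation). Passing the planted-structure
tests therefore shows the *statistics* behave as designed under the
assumed generative model, not that real cohorts satisfy that model.

The read-count generators condition Poisson counts (or uniform read
positions) on a karyotype at a euploid depth in reads/bp (0.6 reads/bp ≈
30× coverage at 50-bp reads); they model neither GC bias nor mappability.
Colony matrices are `base · g_a · g_b · ε_ab` with lognormal noise
(σ = 0.1 by default, matching replicate colony-size scatter). Segment
tables place 1–5 constant segments per arm with Gaussian noise on the
log2 value and optionally inject a short focal segment (10% of the arm at
+4) sized to trip the mean–median exclusion filter.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to give stable pass/fail
behaviour on one CPU: caller recovery uses 100 Poisson replicates at 30×
on the 16-chromosome genome (count-level, since only per-chromosome
totals enter the caller); exclusivity detection power uses 100 planted
and 100 penalty-free cohorts of 100 strains each at the simulator
defaults; interaction rank-order recovery uses 100 noisy 8 × 8 colony
matrices; the hypergeometric implementation is checked against exact
integer combinatorics for every configuration with N ≤ 20 and against
direct subset enumeration at N = 10.

## Known limitations

- The caller needs ≥ 4 chromosomes and a mostly euploid baseline
  quartile; a genome where more than half the chromosomes are aneuploid
  in the same direction shifts the baseline and biases all copies.
- The point-probability statistic is not a tail test; extremely uneven
  margins can make the point value small for unremarkable overlaps. The
  tail variant exists for sensitivity analyses.
- Arm summaries ignore tumor purity and average over subclones.
- The simulator's bottleneck ignores colony-size differences between
  clones during regrowth (the clone is picked by frequency, not fitness).
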