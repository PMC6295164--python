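# karyoadapt

Analysis of how chromosomally unstable (CIN) cell populations acquire
complex aneuploid karyotypes. The package grew out of experiments in
budding yeast where deletion of chromosomal-passenger-complex genes drives
very high chromosome missegregation rates and populations adapt by
accumulating specific whole-chromosome aneuploidies; the same statistics
apply to arm-level karyotypes of tumor cohorts.

It is aimed at researchers who have (any of): whole-genome sequencing
reads from aneuploid strains, strain-by-chromosome copy-number matrices,
colony-size matrices of engineered double-aneuploid strains, or tumor
copy-number segment tables — and who want to quantify which aneuploidies
co-occur, which exclude each other, and whether those patterns reflect
genetic interactions between chromosomes.

## What it computes

**Karyotype calling from read depth** (`karyoadapt.genome`). Reads (BED
intervals) are assigned to chromosomes by midpoint; the 15 kb closest to
each telomere is excluded (subtelomeric repeats bias mapping); density
`d_i = reads / usable bp`. Chromosomes are ranked by density and the mean
density of the second-lowest quartile is the euploid baseline `b`, robust
both to the aneuploid chromosomes (upper ranks) and to low-coverage
outliers. Continuous copy number is `c_i = p · d_i / b` for basal ploidy
`p`, and integer calls round `c_i` with ties at .5 going away from `p`, so
borderline chromosomes are called aneuploid.

**Cohort co-occurrence statistics** (`karyoadapt.cooccurrence`). For a
strains × chromosomes matrix: per-chromosome aneuploidy frequencies;
DNA-content-change burden `100 · Σ_i |c_i − p| f_i / p` (`f_i` = genome
fraction of chromosome `i`); pooled karyotype SD
`sqrt(mean_i var_s(c_{s,i}))`; Pearson correlations between chromosome
copy numbers; and, for every pair of direction-specific aneuploidy events
(e.g. `chrVIII+`, `chrIX−`), the hypergeometric point probability of the
observed overlap,

```
P(X = k) = C(K, k) · C(N − K, n − k) / C(N, n)
```

with `N` strains, `K` and `n` carriers of each event and `k` carriers of
both — small `P` with `k` below `nK/N` flags mutual exclusivity, above it
co-occurrence. A cumulative-tail variant is available behind a flag.

**CCNI scoring** (`karyoadapt.interactions`). Colony sizes of engineered
double-disomic strains are normalized by row/column effects
(`rel = obs · G / (R_row · C_col)`), which cancels single-disome fitness
and marker effects; the mean of the two marker orientations per pair is
the chromosome copy-number interaction (CCNI) score: < 1 negative
interaction, > 1 positive. Scores can be correlated against cohort
copy-number correlations (Pearson r with a two-tailed t-test).

**Arm-level tumor karyotypes** (`karyoadapt.tumor_arms`). SEG segment
tables + a cytoband file → length-weighted mean/median per chromosome arm;
samples whose arms show a mean–median gap > 0.2 (focal-event
contamination) are excluded; arms are called −1/0/+1 at ±0.2 on the
weighted mean; karyotypes with < 2 aberrations are dropped from statistics
and arms aberrant in ≤ 10% of samples from display; the call matrix feeds
the same co-occurrence test.

**Phenotype metrics** (`karyoadapt.phenotype`): doubling times from
log-linear OD fits; chromosome copy numbers from qPCR C_t tables by a
modified ΔΔC_t scheme.

**Synthetic data** (`karyoadapt.simulate`): a Wright–Fisher-style
simulator of adaptation under CIN (per-chromosome missegregation,
multiplicative fitness with pairwise interaction terms, serial
single-colony bottlenecks), plus generators for Poisson read
counts/BEDs, colony matrices and SEG tables with planted structure.

## Worked example

Call a karyotype from simulated 30× sequencing of a chrVIII disome, then
evolve a 100-strain CIN cohort in which gains of chrVIII and chrX are each
beneficial (s = 1.3) but penalize each other (ε = 0.5), and test the pair:

```python
import numpy as np
from karyoadapt import (SimulationConfig, aneuploidy_frequency, call_aneuploidy,
                        estimate_copy_numbers, pairwise_cooccurrence,
                        simulate_adaptation)
from karyoadapt.simulate import simulate_read_depth_profile, yeast_genome

genome = yeast_genome()
profile = simulate_read_depth_profile(
    np.where(np.arange(16) == 7, 2, 1), genome, depth=0.6, seed=1)
calls = call_aneuploidy(estimate_copy_numbers(profile, genome))
print(calls[["chromosome", "density", "copy", "integer_copy", "aneuploid"]]
      .iloc[[0, 7]].to_string(index=False))

config = SimulationConfig(
    genome=genome,
    fitness_effects={"chrVIII": {2: 1.3}, "chrX": {2: 1.3}},
    interaction_terms={("chrVIII", "chrX"): {(2, 2): 0.5}},
)
cohort = simulate_adaptation(config, replicates=100, seed=1)
print(aneuploidy_frequency(cohort.karyotypes, 1).loc[["chrVIII", "chrX"],
                                                     "gain_frequency"])
tests = pairwise_cooccurrence(cohort.karyotypes, ploidy=1)
print(tests[(tests.event_a == "chrVIII+") & (tests.event_b == "chrX+")]
      [["N", "K", "n", "k", "direction", "p"]].to_string(index=False))
```

Output:

```
chromosome  density     copy  integer_copy  aneuploid
      chrI 0.600056 1.000110             1      False
   chrVIII 1.198095 1.996859             2       True
chrVIII    0.68
chrX       0.66
Name: gain_frequency, dtype: float64
  N  K  n  k   direction        p
100 68 66 35 exclusivity 0.000002
```

The caller recovers the planted disome (copy ≈ 2.0 against a euploid
baseline of ≈ 1.0). In the evolved cohort each beneficial gain reaches
~2/3 of strains, but only 35 strains carry both where independence
predicts ~45 — the planted negative interaction surfaces as mutual
exclusivity at `P ≈ 2 × 10⁻⁶`.

The same operations are exposed on the command line:
`karyoadapt call-karyotypes`, `cooccur`, `burden`, `interactions`,
`tumor-arms`, `growth`, `qpcr`, `simulate` (see `karyoadapt --help`).

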