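# Methods

`digenet` implements a two-stage procedure for mining digenic (two-locus)
signal in genetic case-control data, followed by a network-level
significance test over the resulting list of genotype pairs.

## Data model

Input is PLINK text format: a `.map` file (chromosome, variant id, genetic
distance, base-pair position) and a `.ped` file (six leading columns, then
two allele fields per variant).  Internally a cohort is an
`individuals x variants` matrix of genotype codes 0/1/2 (copies of one
allele at a biallelic SNP) with -1 for missing calls, plus a binary
phenotype.  Only the three genotype categories matter downstream, so the
allele that is counted is arbitrary; the reader fixes it deterministically
(lexicographically second of the observed alleles) so runs are
reproducible.  Half-missing calls ("A 0") are treated as missing.
Phenotypes use the 1 = control / 2 = case convention; anything else drops
the individual with a warning.

## Stage 0 — main-effect screen

Each variant is tested with the Cochran–Armitage trend test (scores 0/1/2;
the squared trend statistic equals the score test of a logistic regression
of phenotype on genotype and is asymptotically chi-square, 1 df).
Family-wise significance uses a max-T permutation test: phenotype labels
are permuted `n_perm` times (default 1,000) and the per-permutation
maximum statistic over variants forms the null; a variant's family-wise p
is the plain proportion of null maxima at least as large as its observed
statistic.  Variants with p ≤ alpha (default 0.05) are removed before the
pair scan — the method targets interactions, and a strong main effect
would dominate every pair it enters.  The screen also assigns each variant
a "GWAS rank" (1 = largest statistic, ties by map order) that is reported
alongside the network results.

Missing genotypes are dropped from a variant's count table, not imputed.
Degenerate tables (no genotype or phenotype variation) give a flagged
not-available statistic and can never be excluded.

## Stage 1 — exhaustive genotype-pair scan

For every pair of variants on *different* chromosomes (a guard against
linkage disequilibrium) and each of the nine genotype combinations, the
scan builds a 2x2 table — cases/controls by pattern present/absent — and
scores it with a two-sided Fisher exact test.  Conventions:

- **Support.** Patterns carried by fewer than `support_min` individuals
  (default 20, cases and controls combined) are skipped and do not count
  toward the number of tests `N`.
- **Missing data.** By default individuals missing either genotype are
  removed from that pair's tables (so different pairs can have different
  totals); `missing_policy="absent"` instead counts them as non-carriers.
- **Two-sided Fisher.** Point-probability convention: p is the sum of
  hypergeometric probabilities of all tables with the observed margins
  whose point probability is at most the observed one, within relative
  tolerance 1e-7 (guarding float equality of tied tables).  Tables with a
  zero row or column margin are uninformative (p = 1).  The implementation
  sums the hypergeometric pmf vector per unique margin triple, normalised
  by its realised mass so full inclusion is exactly 1, and caches lookup
  tables keyed by margins — the scan evaluates thousands of tables that
  share margins.
- **Chi-square transform.** Each p is mapped to the 1-df chi-square value
  with that upper-tail probability, for interpretability; p is floored at
  1e-300 first (logged if the floor binds).
- **Bonferroni.** `p_bon = min(1, N p)` with `N` the number of patterns
  actually tested (support-passing).
- **Ranking.** The top `capacity` patterns (default 100,000) by descending
  chi-square are retained, rank 1 = largest.  Ties are broken by ascending
  (column_a, column_b, genotype_a, genotype_b).  For ranking only,
  chi-square is quantized at 1e-9: mathematically tied p-values computed
  from different margins can differ by an ulp, and without quantization the
  tie-break would not fire.  Ranks feed the network statistic, so this
  determinism matters.
- **Parallelism.** The scan is partitioned over chromosome-block pairs
  (joblib); blocks are fixed by the chromosome partition and the final
  ranking is a global sort, so output is identical for any worker count.

## Stage 2 — the Digenic Network Test

From the ranked list, each unique variant `i` gets a connection count
`c_i` and the rank `r_i` at which it first occurred.  Two readings of
"connection" are implemented: `genotype_pairs` (default) counts pattern
rows the variant participates in; `distinct_partners` counts distinct
partner variants.  They coincide when no variant pair contributes more
than one genotype combination to the list.

The test statistic is `T_i = c_i / r_i`: connectivity weighted by inverse
rank, tying it to association strength.  Significance is by rank
permutation: the observed rank vector (multiset-preserving) is reassigned
to the variants `n_perm` times (default 100,000), recording the maximum T
each time; `p_i` is the proportion of permutation maxima ≥ `T_i` (plain
`b/m`; a `(b+1)/(m+1)` estimator is available via `add_one`).  Variants
with `p ≤ alpha` are the *lead* variants.

Network density over a variant set is summarized by `S1` (sum of the
set's connection counts), `S2` (distinct variant ids among all their
partners, a plain set union — a lead appearing as another lead's partner
counts) and `R = S1/S2 ≥ 1`.  Both the lead-set scope (default, matching
how the published results report the summary) and the all-unique-variants
scope (matching the summary's defining formula) are available.
Per-variant connectivity curves (`Nc` over the top `Npatt` patterns) track
how a variant's connections accumulate down the list.

### Calibration of the rank-permutation null

The permutation null treats ranks as exchangeable against connection
counts.  Under a true null this is only approximately so: a variant that
appears in many retained patterns necessarily tends to appear *early*
(its first-occurrence rank is the minimum over many draws), so `c` and
`r` are negatively coupled and the observed maximum T is stochastically
larger than the permutation maximum.  Consequences, measured with this
package's simulators:

- When the retained list is a small, highly selective slice of the tested
  patterns (the regime of the published full-scale analyses), the test is
  anti-conservative under the null: family-wise rates far above alpha.
  Lead-variant p-values from selective lists should be read as a
  screening/ranking device, not calibrated error rates.
- When the retained list covers most tested patterns (every variant
  appears, connection counts are comparatively homogeneous), the coupling
  is weak and the family-wise rate is close to, and slightly below, alpha.
  The null-calibration test runs the full pipeline at its defaults in this
  regime (200 replicate null cohorts) and checks both the network test and
  the trend screen against the 5% ± 3% band.

## Synthetic data

The cohort simulator emulates the structure of array-genotyped
case-control data: biallelic SNPs in contiguous equal chromosome blocks
(positions at 10 kb multiples), per-variant allele frequency uniform on a
configurable range (default 0.1–0.5, common array variants),
Hardy–Weinberg genotypes independent across variants, binary phenotype.
Disease risk is multiplicative on the probability scale — baseline
(default 0.1) times per-genotype main-effect multipliers times digenic
multipliers applied when an individual carries both genotype codes of a
planted cross-chromosome effect.  Configurations whose maximal attainable
risk reaches 1 are rejected at validation (no silent clamping).
Individuals are drawn by rejection until the requested case and control
counts accrue (default 200 + 200 at 100 SNPs on 4 chromosomes), with a
draw cap that turns unreachable configurations into an explicit error.
Missing calls are sprinkled independently at `missing_rate` (default 0).

Deliberately not modelled: linkage disequilibrium, population structure,
relatedness, sex chromosomes, genotyping-batch artefacts.  Passing tests
on these cohorts therefore demonstrate algorithmic correctness and
statistical calibration under idealized sampling, not robustness to the
confounders of real genotype data.

`simulate_ranked_list` builds ranked lists directly (uniform random
cross-chromosome pairs, strictly decreasing chi-square, optional forced
hub with distinct partners) so the network test can be exercised without
a scan.

## Problem sizes and defaults

Defaults follow the published analysis where it states values: support
s = 20, retention Npairs = 100,000, rank permutations Nperm = 100,000,
alpha = 0.05.  The screen's permutation count (1,000) and its alpha
(0.05, family-wise) are package choices — the source analysis removed a
small number of strong main-effect variants but did not print its
threshold.  Tests and the calibration studies use scaled-down sizes
(hundreds of individuals, 50–100 SNPs, 500–2,000 permutations) chosen so
the full suite runs in a few minutes on one CPU while keeping every rate
estimate's Monte-Carlo error well inside the asserted bands.

## Known limitations

- The anti-conservatism of the rank-permutation null for selective lists,
  discussed above.
- Bonferroni-corrected pattern p-values are conservative under the strong
  dependence among the nine patterns of a pair and among overlapping
  pairs.
- Chromosomes are compared as string labels; no special handling of X/MT
  genotypes.
- The scan materializes all support-passing patterns per chromosome-block
  pair; at genuinely genome-wide scale (10^5+ variants) it would need the
  block-wise streaming prune (already implemented per block) plus more
  aggressive chunking than this desk-scale implementation has been tuned
  for.
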