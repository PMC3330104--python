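# Methods

`popeqtl` implements a multi-population cis-eQTL analysis for expression
microarray data: normalization, confounder removal, permutation-calibrated
Spearman association mapping, expression/genetic differentiation statistics,
and cross-population sharing analyses. A first-class synthetic-data
generator provides multi-population studies with known ground truth so that
every stage is testable without access to controlled human data.

## The association model

For a probe (gene expression phenotype) and a SNP within 1 Mb of the gene's
transcription start site (closed interval, signed distance = SNP position −
TSS irrespective of strand), association is tested by Spearman rank
correlation: the Pearson correlation of mid-ranks (average ranks for ties),
with a two-sided p-value from the t-approximation on n − 2 degrees of
freedom. Individuals with a missing genotype call are dropped pairwise; at
least 10 paired observations are required. The t-approximation is used
rather than an exact permutation p because the per-gene permutation
threshold calibrates any monotone p-value, and exact enumeration is
impractical at n ≈ 80–140.

**Multiple testing.** Per gene, the expression phenotype is permuted across
individuals (default 10,000 permutations; per-gene independent streams from
one seeded generator, with an optional shared-permutation mode that
preserves cross-gene correlation) and all cis SNPs are retested; the
minimum nominal p per permutation is recorded. The per-gene threshold at
level α is the ⌊α·n_perms⌋-th order statistic (1-based) of these minima —
the strict empirical quantile, no interpolation — and a gene is significant
only when its observed minimum p is *strictly below* the threshold. The
permutation retest is exact: for SNPs with missing calls the permuted
phenotype is re-ranked within each SNP's non-missing subset (implemented by
counting value-group occurrences per permutation, which avoids any
per-permutation sorting and matches a brute-force per-permutation Spearman
to ~1e-15).

**FDR.** Two estimators: (i) expected-count FDR = (genes tested × α) /
(genes significant), capped at 1; (ii) replication FDR = 1 − (genes whose
best SNP-probe pair reaches nominal p < 0.005 with the same rho sign in at
least one other population) / (significant genes). Genes whose best SNP is
untyped or filtered in every other population count as non-replicated and
are tallied separately.

**Stepwise conditional mapping.** For each gene significant at α = 0.01
with ≥ 2 significant cis SNPs: declare the most-significant SNP independent
(ties broken by smaller p, then smaller |distance to TSS|, then snp_id),
regress its additive dosage (mean-imputed where missing) out of expression
by least squares, re-test the remaining initially-significant SNPs on the
residuals, keep those strictly below the *original* permutation threshold,
and repeat until none pass. A SNP perfectly collinear with a declared one
can never re-enter. Re-using the original threshold follows the observation
that per-step thresholds change nothing.

## Preprocessing

1. **Quantile normalization within individual**: each individual's
   replicate hybridizations are mapped to the mean of their order
   statistics (rank k → mean of k-th smallest values across replicates),
   then averaged into one column per individual. Collapsing to one column
   is our choice — all downstream analyses are per-individual. Note this
   mapping can create exact ties across individuals at the median rank;
   all rank-based code handles ties by mid-ranks.
2. **Median normalization across all individuals** of all populations:
   each column is shifted (additively, log2 scale) so its median equals
   the grand median of per-sample medians. Quantile + median normalization
   is idempotent to 1e-10.
3. **Probe selection**: eligible probes map to exactly one gene, lie on an
   autosome, and have coordinates. Probes overlapping a common SNP are
   *kept* but flagged, so SNP-in-probe artifacts can be examined rather
   than silently excluded.
4. **Stratification correction** (admixed populations): expression is
   residualized per probe on the top 10 principal components of the
   population's standardized dosage matrix (SNPs filtered to MAF > 5%,
   missingness < 20%, mean-imputed). Residuals are orthogonal to every
   axis; collinear axes are absorbed by the pseudoinverse.
5. **REDUCED data**: per population, a variational Bayesian factor
   analysis with per-factor automatic-relevance-determination (ARD) Gamma
   priors on loading precisions. Known covariates (gender; optionally
   population indicators in a pooled run) are removed first by per-probe
   OLS — with flat priors, Bayesian regression and OLS coincide, and the
   sequential fit keeps the hidden-factor loop simple while honoring the
   residual contract (input − covariate effects − factor reconstruction).
   Defaults: 32 hidden factors offered; ARD prior Gamma(shape = probe
   count, rate = 0.022). Because the posterior rate is dominated by the
   data term, this prior sets regularization strength relative to matrix
   size; ARD drives unneeded factors' precisions to very large values,
   switching them off. Convergence: relative improvement of the expected
   reconstruction error < 1e-6, or 1000 iterations (best iterate returned
   with a warning). Initialization from the truncated SVD; factor count
   reported as those carrying > 1e-4 of total variance.

## Differentiation statistics

**V_ST** for a probe and a population pair: (V_T − V_S)/V_T with V_S =
(V₁n₁ + V₂n₂)/(n₁+n₂). Variances use the denominator-n (maximum-likelihood)
convention so identical populations give exactly 0 under this weighting;
values are clamped to [0, 1] (the unbiased convention can go negative) and
V_T = 0 is defined as 0. "Top differentiated" probes for enrichment are the
top 5% ranked by V_ST per pair, ties broken by probe id — the statistic has
no separate significance test.

**F_ST**: the Hudson estimator, chosen for its low sample-size bias. With
haploid sample sizes the per-SNP numerator is (p₁−p₂)² − p₁(1−p₁)/(n₁−1) −
p₂(1−p₂)/(n₂−1) and the denominator p₁(1−p₂) + p₂(1−p₁); estimates are
ratio-of-averages within windows of consecutive SNPs (default 10,000),
then averaged across windows. SNPs monomorphic in both populations are
skipped; negative genome averages are floored at 0 when used as distances.

**Term enrichment**: one-sided Fisher exact tests of {in top set} ×
{annotated to term} over the eligible-probe universe, combined across
population pairs by Fisher's method (X = −2Σln p against chi-square with 2k
df; zero p-values clamped to the smallest positive float). Population
specificity filters out terms whose combined p over pairs *not* involving
the focal population is also significant. The gene→term map is an arbitrary
external input; tests use synthetic maps.

## Sharing analyses

Before any cross-population comparison, dosages are harmonized to count the
alphabetically smaller allele everywhere; SNPs whose allele pair differs
between files are dropped with a log entry. Direction concordance is the
fraction of SNP-probe pairs significant in both populations with the same
rho sign (rho = 0 excluded). Effect size is the homozygote fold-change
|median(expr | dosage 2) − median(expr | dosage 0)| on the log2 scale,
requiring ≥ 2 individuals per homozygote class (medians of singletons are
noise). pi1 = 1 − pi0 with pi0 = #{p > λ}/((1−λ)m), λ = 0.5, clamped to
[0, 1]. Multi-gene clusters are groups of ≥ 2 genes sharing an identical
best eQTL SNP within a population; replicated clusters appear in ≥ 2
populations, and cluster-SNP |TSS distances| are compared to single-gene
distances by a one-sided rank-sum test.

**Parsimony sharing.** The population tree is built by neighbour joining
from the pairwise F_ST matrix and midpoint-rooted, which makes "smallest
covering clade" well defined (the node-level sharing rule in the original
description is terse; smallest-covering-clade is our reading and is
implemented as such). Each gene contributes one association — a random
discovery population at α = 0.01 (fixed seed) — extended by every
population where the gene passes a lenient per-gene permutation threshold
recomputed at α = 0.1. The gene's population set is assigned to the
smallest clade covering it (leaf for singletons, root if nothing smaller
covers it); node counts are compared to 100 randomizations, either
permuting leaf labels or redrawing each gene's set at fixed size, and a
node is flagged enriched when its observed count exceeds the null's 95th
percentile. Assignment conserves the gene count across nodes.

## The synthetic-data generator

The generator emulates the 8-population design at its real sample sizes
(CEU 109, CHB 80, GIH 82, JPT 82, LWK 82, MEX 45, MKK 138, YRI 108).

* **Allele frequencies**: Balding–Nichols drift — a population at
  divergence F draws frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F) around
  its ancestral frequency p ~ U(0.05, 0.95). Three continental pools
  (EUR, EAS, AFR at drift 0.06/0.08/0.02 from a shared ancestral pool)
  give the tree structure (CHB+JPT clade, African clade) that the
  parsimony analysis expects; each population drifts a further 0.005 from
  its pool. Under the frequency-level Hudson estimator two populations at
  drift F each show F_ST ≈ F (Monte-Carlo verified; E[numerator] =
  2Fp(1−p), E[denominator] = 2p(1−p)).
* **Admixture**: admixed populations (GIH, LWK, MEX, MKK) mix pool
  frequencies per individual with Dirichlet(10 × mixture weights), i.e.
  ancestry-proportion sd ≈ 0.15 — enough structure for the genotype PCA
  correction to be meaningful, comparable to real admixed panels.
* **Genotypes**: Binomial(2, freq) per SNP; missing calls masked uniformly
  at 1% by default (the study's filter allows up to 20%).
* **Expression**: per probe, baseline U(6, 12) log2 units + planted
  genetic effects + hidden global factors (default 5 factors, loadings
  N(0, 0.5²), scores N(0, 1) per individual — a generic stand-in for
  batch/passage effects, for which no quantitative model exists) +
  individual noise N(0, 0.25²) + two replicate hybridizations with
  N(0, 0.10²) each.
* **Planted cis-eQTLs** (default 50): signed TSS distance with |d| ~
  Exp(50 kb) capped at 1 Mb, snapped to the nearest simulated SNP; |β| =
  1.5 · 2^(−|d|/20 kb), floored at 0.25, random sign. The 20 kb
  half-distance reproduces the qualitative tightening of eQTLs around the
  TSS with increasing sharing; it is a modeling choice, not an estimated
  law. Sharing sets are drawn to respect the tree (singletons 45%, pool
  clades 35%, all populations 20%) or uniformly at random.
* **Absence modes**: by default a population outside the sharing set has
  the causal SNP's frequency driven below 5% (non-replication by allele
  frequency, the study's favored explanation); a config switch instead
  zeroes the effect there. A planted SNP monomorphic in a carrier
  population is an error naming the SNP.
* **SNP-in-probe artifacts**: 6.4% of probes are flagged; a common SNP
  near the probe shifts measured intensity by −0.4 log2 units per allele
  copy in every population, mimicking hybridization loss.
* **Proxy SNPs**: an optional clone of each causal SNP (exact copy, or
  per-individual redraw with probability 1 − r for approximate correlation
  r) supports the stepwise collinearity tests. Realistic LD beyond this is
  out of scope, as are sex chromosomes.

What passing tests on this generator do **not** show: performance under
realistic LD (thresholds here are calibrated per gene, so LD mainly affects
which SNP is "best", not calibration), array-specific intensity artifacts
beyond the additive SNP-in-probe model, related individuals, or non-Gaussian
expression noise.

## Problem sizes used by the test suite and acceptance script

Chosen to keep a complete run on one CPU comfortable while leaving the
statistical checks well powered: null calibration uses 200 genes × 1,000
permutations (the threshold's rejection rate is k/(n_perms+1), so 1,000
permutations resolve α = 0.01 exactly); planted-eQTL recovery uses the full
8-population design at n = 80 per population, 50 planted effects with
|β| ≥ 1, 1,000 permutations; the replicate-stability suite runs 20
two-population simulations on complete genotype data (the missing-data
permutation path is verified exactly against brute force in its own test);
the REDUCED-power comparison uses two populations, 100 probes, 8 strong
hidden confounders, 16 offered factors, 500 permutations. Statistics
reported in percent are rounded to the precision the corresponding
published table prints.

## Known limitations

* The ARD prior's exact parameterization in the original factor-analysis
  software is ambiguous; Gamma(shape, rate) with probe-count scaling
  reproduces the regularization strength's order of magnitude, not
  bit-identical residuals. Both numbers are exposed in config.
* Per-population factor fits cannot include a population indicator
  (constant within a run); gender is the within-population known covariate,
  and a pooled mode accepts population indicators explicitly.
* The convergence monitor is the expected reconstruction error, not the
  full evidence lower bound; with ARD both stabilize together in practice,
  and the iterate at stopping is returned either way.
* `fdr_replication`'s denominator includes genes untestable in every other
  population (reported separately); excluding them is a one-line change
  whose correct choice the original description leaves open.
* The permutation threshold uses the strict order statistic; interpolated
  quantiles would shift thresholds by O(1/n_perms).
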