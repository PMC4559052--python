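# Methods

`colonystruct` analyzes codominant (microsatellite) genotypes of workers
sampled from social-insect colonies: it classifies colony breeding
systems, quantifies hierarchical genetic structure, tests for spatial
pattern, and infers population clusters. Because such studies rarely
deposit raw genotypes, the package ships a colony-pedigree simulator that
reproduces the statistical structure the analyses assume; every method is
validated against that generator and against independent brute-force
oracles.

## Data model

A `GenotypeDataset` holds diploid individuals grouped into colonies and
genotyped at a shared locus panel. Genotypes are unordered allele pairs
stored in canonical (sorted) order; allele codes are opaque integers
(nominally fragment sizes in bp — no repeat-unit structure is assumed).
Missing data are supported (GENEPOP `000`); every statistic excludes
missing gene copies locus-wise. Colonies carry planar coordinates in
meters and an optional maternally inherited haplotype label; a helper
projects lon/lat via an equirectangular projection at the mean latitude
for regional extents. I/O covers the 2- and 3-digit GENEPOP dialects
(one `pop` block per colony; writers emit 3-digit) and a
`colony_id,x,y[,haplotype]` CSV.

## Synthetic colony pedigrees

The generator's defaults encode the emulated sampling design: 52 colonies
x 10 workers x 6 loci with allele-count template (13, 3, 3, 2, 3, 4),
two spatial clusters at divergence theta = 0.14, and a 38.5 / 61.5 %
simple/extended family mixture with g = 3 neotenic generations.

**Cluster frequencies.** Ancestral frequencies are Dirichlet(1) draws per
locus (within-population spectra are a modeling choice, not a
reconstruction); cluster frequencies follow the Balding–Nichols
construction, Dirichlet(p_anc * (1 - theta)/theta), whose across-cluster
variance of p is theta * p(1 - p). With only 6 loci and 2 clusters the
*realized* divergence of a single draw scatters widely around theta
(per-locus drift has r - 1 = 1 degree of freedom), so by default draws
are rejection-sampled until the parametric large-sample Weir–Cockerham
divergence of the drawn vectors is within `divergence_tol = 0.01` of the
target: the clusters are *at* the design divergence, not merely centered
on it. Setting `divergence_tol=None` restores unconditioned draws.

**Colony pedigrees.** Simple families are Mendelian offspring of one
outbred pair drawn from the local pool under Hardy–Weinberg proportions.
Extended families model neotenic succession as `neotenic_pairs = 3`
*parallel* full-sib lineages seeded from the founder sibship; each
lineage continues with a full-sib pair of its own offspring for g rounds.
Every worker's ancestry is then a pure full-sib-mating chain, so its
pedigree inbreeding equals the recurrence
F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4 (0.25, 0.375, 0.5, ...) exactly,
while independent lineage fixation produces the multi-reproductive
genotype signature (extra genotype classes, three or more homozygous
classes, distorted Mendelian ratios) that distinguishes extended from
simple families. A single-lineage variant was rejected at design time
because single-pair offspring are provably Mendelian-consistent —
no classifier could detect them — and because one lineage bottleneck
erases within-colony diversity. Three pairs is a conservative count;
real extended colonies hold several to hundreds of neotenics. Mixed
families draw each worker's parents from distinct pairs among m >= 3
unrelated founders. Founder gene copies carry unique identity-by-descent
tags propagated through the pedigree, so realized autozygosity is
measurable directly. Loci are unlinked and mutation-free (study-scale
timescales). Each colony consumes an independent child RNG stream of the
root seed, so changing the colony count never reshuffles earlier
colonies.

**What the generator does not emulate:** genotyping error and allelic
dropout, colony budding/fusion spatial dynamics, selection, linkage,
overlapping worker generations, and real within-population allele-
frequency spectra. Passing tests therefore demonstrate correctness of
the estimators and the internal consistency of the workflow under the
stated model — not robustness to those real-data features.

## Breeding-system classification

Per colony, ordered rules: (1) any locus with more than four alleles ->
**mixed** (no single pair can produce five alleles); (2) any locus where
no parental pair has positive Mendelian probability for every observed
genotype class -> **extended** (this subsumes "more than four genotype
classes" and "three or more homozygous classes"); (3) a combined-locus
G-test against the best-fitting pair's Mendelian expectations with
p < alpha (default 0.05) -> **extended**; (4) otherwise **simple**.
Colonies with fewer than `min_workers = 5` genotyped workers are reported
as `insufficient_data`, never silently simple.

The pair enumeration considers the observed alleles plus at most
4 - n_observed "wildcard" alleles (unobserved parental alleles; never
required to explain an observed class — unobserved offspring classes are
legitimate finite-sampling outcomes). The per-locus expected frequencies
use the maximum-likelihood compatible pair; ties break deterministically
(fewer wildcards, then genotype order). G_l = 2 * sum O ln(O/E) over
observed classes; df_l = (positive-probability classes) - 1; per-locus G
and df are summed and referred to the upper chi-square tail. No Williams
correction is applied. Loci whose best pair yields a single offspring
class contribute nothing. The choice of the ML pair when several pairs
are compatible is a documented convention; it makes the test slightly
conservative (measured false-extended rate ~0.05-0.07 at alpha = 0.05
with 10 workers).

## Classical estimators and tests

**Heterozygosity.** H_O is the observed heterozygote fraction; H_E is
Nei's unbiased estimator (2n/(2n-1)) (1 - sum p^2).

**F-statistics.** Weir & Cockerham (1984) per-allele variance components
a (among groups), b (among individuals within groups), c (within
individuals); multi-locus estimates are ratios of components summed over
alleles and loci, never means of per-locus ratios. With a single group
the single-population form of b applies and F_IS = 1 - c/(b + c).
Significance: F_IS by permuting gene copies among individuals within
groups (one-sided toward deficiency), F_ST by permuting individuals
among groups (one-sided toward differentiation); pairwise cluster F_ST
uses 1000 randomizations by default. All permutation p-values use
(1 + hits)/(1 + reps).

**Heterozygote-deficiency tests.** Conditional on observed allele
counts, the p-value is P(heterozygote count <= observed) under random
pairing of gene copies: computed exactly by enumerating genotype tables
with Levene's conditional probabilities when the table space fits a
budget (k <= 6 alleles, n <= 40, <= 2x10^5 visited nodes), else by Monte
Carlo re-pairing (default 10^4 shuffles). Being an exact test on a
discrete statistic, its null p-values are *valid* (super-uniform,
P(p <= a) <= a) but not uniform — an atom at p = 1 is expected; the
calibration tests check validity, which is the guarantee exact
conditional tests provide. The score-statistic variant of the classical
software is not implemented — a recorded divergence.

**Linkage disequilibrium.** G statistic on the two-locus genotype
contingency table; null by permuting one locus's genotypes across
individuals (within groups when given); the all-pairs scan applies
Bonferroni correction over the 15 pairs of a 6-locus panel.

**AMOVA.** Gene-copy mismatch distance (an F_ST-analogue; allele-size
differences deliberately not used — switchable by distance matrix if
needed), three nested levels: among colonies / among individuals within
colonies / within individuals. Components come from the standard nested
ANOVA expectations with unequal sizes; the among-individual component is
legitimately negative for full-sib colonies (copies within an individual
are *less* related than copies across siblings). Significance: among-
colony by permuting individuals among colonies (statistic Phi_CT);
within-individual by permuting gene copies among individuals within
colonies (statistic b/(b + c)).

## Spatial structure

**Isolation by distance.** Edwards' angular distance
D = sqrt(1 - (1/L) sum_l sum_a sqrt(p q)) between colony frequency
profiles (loci with zero copies in either group are dropped), against
Euclidean geographic distance; Mantel correlation over lower-triangle
entries with simultaneous row/column permutation (999 by default,
one-sided positive). The pairwise scatter's 2-D Gaussian product-kernel
density (per-axis normal-reference bandwidth sigma m^(-1/6),
configurable) distinguishes a continuous cline from discrete patches.

**Spatial PCA.** Input is the colonies-x-alleles frequency matrix
(one-individual-per-colony genotypes work as the degenerate {0, 1/2, 1}
case), column-centered internally. The connection network is K-nearest-
neighbor (K = 10 by default; ties broken by node order), row-normalized
*before* symmetrization — this makes sum(W) = n so each eigenvalue of
H = (1/n) X' ((W + W')/2) X factorizes exactly as
lambda_i = var(score_i) * I(score_i) (checked to 1e-10). Loadings are
squared eigenvector components labeled `loc<i>.<allele>`. Global/local
significance uses the extreme-eigenvalue permutation statistics (largest
positive; largest-magnitude negative) under row permutation of colony
profiles over locations (9999 permutations by default). These share the
null and the global/local logic of the classical sPCA tests but are not
claimed to be formula-identical to them; outputs are labeled with the
statistic used. On a complete graph the criterion degenerates to
-variance/(n - 1): plain-PCA axes reappear as the largest-|lambda|
(negative) axes — the non-spatial sanity link.

## Bayesian clustering

The standard admixture model for unlinked codominant loci: cluster
allele frequencies have Dirichlet(1) priors; individual admixture
vectors q_i ~ Dirichlet(alpha) with alpha fixed at 1.0 (sampling a
weakly identified hyperparameter at 6 loci adds noise; configurable).
A Gibbs sweep updates copy origins, frequencies, and q from full
conditionals. Retained sweeps are relabeled online against the running
frequency-profile average (Hungarian matching) before averaging — without
this, within-chain label switching biases posterior-mean q toward
uniformity. lnL = ln P(X | P, Q) is recorded per retained sweep;
L(K) = mean - var/2. Scaled-down defaults (5,000 burn-in + 10,000
sweeps, thinning 10) suit the 52-individual scale; study-scale settings
(50,000 + 100,000, K up to 10, 5 replicate runs each on a different
one-per-colony resample) are available via `study_preset()`. The
ambiguous historical phrasing "100,000 repetitions with 10 iterations"
is interpreted as replicate runs, not thinning. Replicate runs are
aligned by greedy frequency-profile matching (exhaustive over K!
available as a cross-check); Evanno's
delta-K = |mean L(K-1) - 2 mean L(K) + mean L(K+1)| / sd(K) selects K,
undefined when all second differences vanish or sd = 0.

## Pipeline

`run_study` sequences the workflow under one root seed (per-stage child
streams): 20 one-per-colony resamples; per-resample pooled H/HWE/F_IS
and Mantel IBD; an LD scan on the first few resamples (all 15 pairs);
AMOVA on all workers (the one stage where sibship is the signal, not a
nuisance); sPCA on colony frequencies; clustering across a K range with
delta-K and a consensus assignment; per-cluster F_IS, pairwise F_ST
(1000 randomizations) and within-cluster Mantel; breeding-system
classification with per-cluster proportions. Stage failures are caught
and recorded by name; the partial report survives. Reports are
JSON-serializable and byte-reproducible under fixed seeds.

The package is a library: the importable API plus the `examples/`
scripts are the interface (no shell entry points — the workflow is
driven from Python).

## Problem sizes and numerical choices

Defaults were chosen so the full validation suite runs on a single CPU:
calibration checks use 500 null replicates with reduced permutation
counts (199-499), recovery checks 10-50 seeded replicates, classifier
operating characteristics 500 colonies per condition, and MCMC recovery
10 seeds x (4 + 6) runs at the scaled-down chain length. Permutation
p-values are never zero by construction; ties in nearest-neighbor
distances, likelihoods and label matching all break deterministically;
degenerate inputs (monomorphic loci, empty groups, constant vectors)
are flagged or raise rather than returning silent numbers.

## Known limitations

- The W&C F_ST estimate from 2 x 30 individuals x 6 template loci has
  sampling SD ~0.029; single-replicate estimates routinely fall outside
  [0.10, 0.18] even when the pools are exactly at theta = 0.14.
- The extended-family classifier's power depends on within-colony
  allelic diversity; with fewer neotenic lineages or less polymorphic
  panels it degrades toward the type-I rate.
- The sPCA global/local tests are permutation analogues, not the
  original statistics; p-values may differ in finite samples.
- The admixture sampler assumes unlinked loci and a fixed alpha; it is
  not a general replacement for full-featured clustering software.
- AMOVA treats missing data by pairwise-complete mismatch counts, which
  can bias components under heavy, non-random missingness.
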