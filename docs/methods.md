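# Methods

This note documents the statistical procedures, parameter defaults, and the
design decisions taken where conventions in the field genuinely differ. The
organism-scale context throughout is a small insular SSR study: a handful of
populations of ~10 diploid individuals genotyped at ~9 microsatellite loci.

## Data model

Genotypes are unordered pairs of positive integer allele codes (fragment
sizes in bp, or arbitrary codes), stored sorted for determinism. Missing
data is a dataset-level sentinel, never 0, so 0 stays ineligible as an
allele code; a half-scored cell is treated as missing by the parsers and
flagged as a violation by the validator. Population order is
first-appearance order and every downstream matrix uses it. GenePop files
may use 2- or 3-digit allele coding; mixed widths in one file are rejected.
Missing genotypes are excluded pairwise per locus (gene counts vary by
locus), never imputed — except in the dosage matrix for PCA/DAPC, where
locus-mean imputation keeps the decomposition defined (see below).

## Diversity statistics

*Gene diversity* He = 1 − Σp² per locus; the unbiased small-sample
correction 2n/(2n−1) (Nei 1978) is on by default because the motivating
samples are ~10 individuals per island. The *global* He is reported under
both conventions in circulation — the mean over loci of pooled-sample gene
diversity, and the mean over loci of the across-population average Hs —
because published per-archipelago values rarely state which was used; both
appear in every output.

*F_IS* per population is the multilocus ratio-of-averages 1 − ΣHo/ΣHs over
loci (Hs unbiased). Populations with ΣHs = 0 report NaN rather than a
value. The sign of F_IS always matches the sign of Hs − Ho.

*Rarefied allelic richness* uses hypergeometric rarefaction,
Rs = Σ_alleles [1 − C(N−Nᵢ, g)/C(N, g)], at a common gene count g
defaulting to the minimum across all (population, locus) cells, so every
cell supports the depth. Rs is non-decreasing in g and equals Na at g = N.

*Private alleles* are (locus, allele) pairs observed in exactly one
population; both per-population counts and the fraction of all distinct
pairs are reported. A single-population dataset warns that privacy is
trivial.

### Hardy–Weinberg exact test

The probability test follows Guo & Thompson (1992) in substance: the
p-value is the probability mass, conditional on the observed allele counts,
of genotype tables no more probable than the observed one, where
P(table) ∝ 2^H / Π n_ij!. The chain itself runs on an equivalent but
simpler state space: assignments of the 2n gene copies to ordered
within-individual slots. Conditional on allele counts, every such
arrangement is equally likely under HWE, so the move — swap two random gene
copies between two random individuals — is symmetric and always accepted,
and genotype tables are automatically visited with the correct
probabilities (we verified the visit frequencies against full enumeration;
a naive table-space Metropolis with table-weight acceptance does *not* have
this stationary law). Defaults match the classic Markov-chain settings:
dememorization 1000, 100 batches of 1000 iterations; the standard error is
the spread of per-batch estimates, and the running table weight is
re-anchored each batch so float drift cannot accumulate. Raw per-locus
p-values are reported (a Bonferroni-corrected column is a trivial
post-processing step for the caller; the pipeline emits raw values as the
source of truth). Monomorphic loci are not-applicable rather than errors.

### Null alleles and the ENA correction

Null-allele frequency r is estimated per (locus, population) by EM under
the model that apparent homozygotes for allele i are a mixture of true
homozygotes (pᵢ²) and i/null heterozygotes (2pᵢr). Two refinements matter
in practice. First, fully null individuals are unobservable (they appear
missing), so the E-step imputes their expected count n·r²/(1−r²); without
this the estimator is biased low by roughly the null-homozygote mass.
Second, EM approaches the r = 0 boundary only geometrically, so after
convergence (Δ < 1e−8, cap 10 000 iterations) the boundary fit (raw
frequencies, r = 0) is compared by conditional likelihood and reported
exactly when it is no worse — exactly-HWE data then returns r = 0 rather
than a small positive remnant. Initialization is uniform visible
frequencies with r = 0.05. On simulated data with injected r = 0.2
(n = 200) the estimate is within 0.05.

The ENA-corrected F_ST recomputes the Weir–Cockerham components with each
population's allele frequencies replaced by the EM-corrected visible
frequencies (which sum to 1 − r), excluding the null class from the sums
over alleles while keeping the observed heterozygote terms. With r = 0
everywhere this reduces exactly to the uncorrected estimator. Corrected and
uncorrected per-locus values are compared by a two-sided paired t-test; a
zero-variance difference vector reports t = 0, p = 1 by convention.

## Differentiation

*Weir–Cockerham θ* (1984) is computed per allele per locus from the a, b, c
variance components and combined as the ratio of summed components across
alleles and loci. Negative estimates are reported as computed (truncation
is an option, used for PCoA input); note that two *identical* samples give
a deterministic θ ≈ −1/(n−1), the estimator's known behavior, while random
splits of one panmictic pool scatter around 0.

*AMOVA* is one-level (among/within populations) on squared inter-individual
distances defined as the number of allele mismatches per locus (0/1/2,
multiset intersection), summed over loci scored in both individuals — the
standard default for codominant data. Variance components come from the
method-of-moments equations; the among component is truncated at 0 for
percentage reporting with the raw value also emitted. Significance
permutes individuals among populations (sizes preserved), p = (1 + #{Φ*
≥ Φ}) / (n_perm + 1), observed included.

*Mantel test*: Pearson r on off-diagonal upper triangles; with ≤ 7 labels
all n! − 1 non-identity permutations are enumerated (4 populations give the
23 permutations familiar from small island studies), otherwise random
permutations. One-sided (greater) by default, matching vegan.

*Directional relative migration* follows the pooling idea of Sundqvist et
al.: for the ordered pair (i → j), a hypothetical migrant pool with the
mean allele frequencies of i and j is formed per locus, the chosen
differentiation statistic (Nm from G_ST, G_ST, or Jost's D) is computed
between the *recipient* j and the pool, and converted to a migration-like
value (Nm directly; 1/stat for the others). A deme receiving many migrants
resembles the pool — elevated diversity lowers its differentiation from the
pool — producing the directional signal. The matrix is normalized by its
maximum, so the strongest edge is 1 and the network is invariant to
rescaling the underlying values. Optional bootstrap over individuals
reports, per ordered pair, the fraction of replicates with m[i→j] > m[j→i].
Nm is the default statistic.

## Clustering and ordination

The dosage matrix codes each (locus, allele) column as 0/1/2 copies;
missing cells are locus-mean imputed (2 × pooled frequency) and individuals
with no scored locus are dropped with a warning.

*find_clusters* runs k-means (k-means++ seeding, 10 restarts, best WSS) on
PC scores for K = 1..max_K and selects K by BIC(K) = n·ln(WSS/n) + K·ln(n),
smallest K on ties. All principal components are retained by default:
truncating at a variance fraction discards signal and, with this BIC, makes
the criterion over-fragment small noisy samples — the behavior contract
(correct K on separable data, K = 1 on panmictic data) is met with full
retention. Numeric parity with any particular implementation of the BIC
curve is *not* a goal; the behavior is.

*DAPC* is LDA on PCs retaining ≥ 90% variance by default (the retained
count is a report field), with at most K − 1 discriminant axes, posterior
memberships summing to 1, and per-axis discriminant variance fractions.

*PCoA* is classical metric scaling: eigendecomposition of the
double-centered −½D², coordinates scaled by √λ on positive axes, negative
eigenvalues reported as-is. Verified against scikit-bio to 1e−8 and against
Procrustes reconstruction of planted configurations.

## Trees

Nei's standard distance D = −ln I with I = J_xy/√(J_x J_y), J terms averaged
over shared loci; the 1978 variant substitutes unbiased within-population J
estimates. nei72 is the default. I = 0 (no shared alleles) yields an
infinite-distance sentinel, capped at twice the maximum finite distance
(with a warning) when a tree is built. UPGMA merges by smallest average
distance with lexicographic tie-breaking (deterministic, label-order
invariant); node height is half the merge distance, so trees are
ultrametric by construction. Bootstrap resamples loci (columns) with
replacement — the standard practice for distance trees over a few SSR loci
— and supports are the percentage of replicates containing each clade of
the full-data tree. Individual-level trees are available by treating each
individual as a population of one. Newick output quotes reserved
characters and stores supports as internal node labels.

## Coalescent simulator and ABC

The simulator is a continuous-time structured coalescent over named demes:
within a deme of diploid size N each pair of gene copies coalesces at rate
1/(2N) per generation; SPLIT moves all of a deme's lineages into its source
(forward in time, an introduction), ADMIXTURE routes each lineage to one of
two sources with probability r, and a BOTTLENECK is a piecewise-constant
size change on [end − duration, end] backward in time, anchored at the
introduction it follows. The continuous-time approximation of a
generation-wise model is asymptotically equivalent for N much larger than
the sample and keeps desk-scale speed. Mutations are Poisson(μ·branch
length) with strict SMM steps (±1 repeat, symmetric, no range constraint);
alleles are emitted around a base size of 200. The simulator's acceptance
surface is its closed forms: E[pairwise TMRCA] = 2N and the stepwise-model
equilibrium gene diversity 1 − 1/√(1+2θ), both reproduced within 3
Monte-Carlo standard errors at 200 loci.

Scenarios may carry symbolic parameters bound from independent priors
(uniform or log-uniform); draws violating event-order constraints are
rejected and redrawn. No published prior table exists for this system, so the package
defaults are its own choices, stated here and overridable:
log-uniform effective sizes (origin 10²–10⁵, islands 10–10⁴), post-intro
bottleneck sizes 2–100 lasting 1–20 generations, uniform introduction times
ordered t1 < t2 < t3 < t4 inside 1–500 generations (the colonization is
historical — decades, not millennia — and a generation is on the order of a
decade for a tree that first seeds at ~12 years, a conversion left to the
caller), and mean SSR mutation rate log-uniform in 1e−4–1e−3.

Summary statistics are per-deme mean allele number, per-deme mean unbiased
gene diversity, and all pairwise Weir–Cockerham F_ST values, computed by the
same diversity/differentiation code paths as the data analysis (single
source of truth). Statistics are standardized by median absolute deviation
(SD fallback). Scenario posteriors use the n_closest reference rows
(default 1% of the table): rejection frequencies, or multinomial logistic
regression on (simulated − observed) differences evaluated at zero.
Parameter posteriors use Beaumont local-linear adjustment with a logit
transform on the prior support so adjusted values stay in range; a singular
regression falls back to the rejection sample. Model checking projects
observed and posterior-predictive statistics into the reference PCA and
reports two-sided per-statistic tail probabilities. Confidence in scenario
choice simulates pseudo-observed datasets per scenario and reports type-I
(own datasets misassigned) and mean type-II (others assigned to the focal
scenario) with min–max ranges.

The scenario catalog ships the three published best-supported invasion
topologies — stage 1: mainland → Floreana and Santa Cruz, Floreana → San
Cristobal, San Cristobal → Isabela; stage 2: two independent mainland
introductions (Santa Cruz, San Cristobal) with San Cristobal → Isabela and
Santa Cruz → Floreana; stage 3: Coast → San Cristobal → the other three
islands — each with post-introduction bottlenecks, plus a serial
stepping-stone chain and a four-independent-introductions alternative per
stage. Larger candidate sets (screening dozens of topologies is common in
invasion-route ABC) load from a YAML catalog.

## Synthetic data

The island fixture draws, per locus, a shared base frequency vector over
2–7 alleles and per-population Dirichlet perturbations with concentration
α = 7 (expected F_ST = 1/(1+α) ≈ 0.125). Nine loci leave substantial spread
around that expectation, so the generator measures the realized pairwise
Weir–Cockerham F_ST of each candidate draw and redraws — deterministically
within the seed's RNG stream — until all pairs lie in [0.05, 0.25]; the
calibration is part of the generator's contract. Missingness is uniform at
random (~3%); the frequency-driven generator adds inbreeding
(P(hom) = p² + F·p(1−p)), null-allele masking (carriers of one null copy
appear homozygous, null homozygotes drop out), and missingness with known
truth. Every generator is a pure function of seed and configuration, and
the JSON truth record regenerates its dataset bit-identically (dict
insertion order is semantic in the record: it fixes RNG consumption order).

What the synthetic data does *not* emulate: genotyping artifacts other than
null alleles (stutter, large-allele dropout), linkage between loci,
selection, and spatially continuous structure. Passing tests on these
fixtures therefore demonstrate estimator correctness under the stated
models, not robustness to every real-data pathology.

## Problem sizes and determinism

Test and acceptance runs use reduced Monte-Carlo scales chosen as package
defaults: reference tables of hundreds of simulations per scenario (full-scale
ABC studies commonly run 10⁶), 25 pseudo-observed datasets for recovery
properties, 1000 AMOVA permutations and 1000 tree bootstraps in the
acceptance script. Recovery thresholds are not relaxed at the reduced
scale. All randomness flows from explicit seeds; the pipeline manifest
records every stage seed, and identical configurations produce identical
manifests (modulo runtimes).

## Known limitations

- The HWE batch standard error ignores between-batch autocorrelation and
  can modestly understate uncertainty for sticky chains.
- The ENA correction keeps observed heterozygote terms while correcting
  frequencies; this matches the "excluding null alleles" description but is
  not a numeric re-implementation of any specific tool.
- The AMOVA is one-level only; regional groupings (hierarchical AMOVA) are
  out of scope.
- Directional migration estimates on pairs with very low differentiation
  are noisy; the bootstrap support matrix is the honest summary there.
- ABC posteriors at desk scale carry n_closest bias; credible-interval
  coverage is approximate (documented in the tests as a ≥ 80% property, not
  an exact 95%).
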