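# Methods

This note documents the statistical models implemented in `strtrace`, the
conventions and defaults chosen where several are in circulation, and what
the synthetic-data generator does and does not emulate.

## Data model

Genotypes are unordered pairs of integer allele labels (fragment lengths in
bp); a genotype is either fully observed or missing. Missing calls are
excluded locus-wise from frequency counts and pairwise comparisons and
skipped in per-individual likelihood products — no imputation anywhere.
Population labels are case-sensitive, whitespace-stripped strings. GenePop
files are read with 2- or 3-digit allele codes (auto-detected by token
width) and written with 3-digit codes; per GenePop convention a population
block is labelled by its first individual's identifier. Allele labels are
required to be integers throughout: STR alleles are fragment sizes, the
interchange formats encode them numerically, and R_ST is undefined without
them; delimited tables with non-numeric allele cells are rejected with an
explicit error rather than carried in a degraded mode.

## Per-locus diversity

Expected heterozygosity uses Nei's unbiased estimator
He = (2n/(2n−1))(1 − Σpᵢ²), matching the pedigree software conventions this
package is meant to be comparable with; the uncorrected gene diversity is
available via `unbiased=False`. PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ², computed
with the algebraic identity Σ_{i<j}2pᵢ²pⱼ² = (Σpᵢ²)² − Σpᵢ⁴.

### Hardy–Weinberg exact test

The test is the Markov-chain Monte-Carlo approximation to the multi-allele
exact (conditional) test. The chain state keeps each individual's two
allele copies in *ordered slots*; a step swaps the contents of two
uniformly chosen slots of two individuals. The number of slot-states
realising a genotype table {n_ab} is 2^h · n!/Π n_ab! (h = heterozygotes),
which is exactly proportional to the conditional probability of the table
given the allele counts — so the uniform distribution over slot-states has
the right table marginal and uniformly random swaps need no
Metropolis-Hastings correction. The p-value is the post-burn-in fraction of
steps whose table probability is ≤ the observed table's, *including* ties
(the standard exact-test convention; ties matter in small tables, and the
convention makes the test conservative rather than anti-conservative). The
chain is batched (defaults: dememorization 5000, 100 batches of 1000
iterations, the values customary in the field) and the standard error is
the batch-mean standard deviation / √batches. A monomorphic locus returns
p = 1 by convention. The test is validated against full enumeration of the
biallelic conditional distribution and by type-I calibration on simulated
HWE samples; the chain seed is an explicit argument, so results are
reproducible.

## Exclusion powers

All three exclusion statistics assume Hardy–Weinberg genotype proportions
in the reference population and are exact functions of the allele
frequencies — no sampling, no approximation:

* **PE-1P** = Σ pₐ²(1−pₐ)² + Σ_{a<b} 2pₐp_b(1−pₐ−p_b)²: the probability a
  random individual carries neither allele of a random offspring.
* **PE-2P**: probability a random *ordered couple* is Mendelian-incompatible
  with a random offspring, i.e. no assignment of the two candidates to
  sire/dam can produce the genotype. For offspring aa the couple is
  compatible with probability [1−(1−pₐ)²]²; for ab it is
  2[1−(1−pₐ)²][1−(1−p_b)²] − (2pₐp_b)² by inclusion–exclusion.
* **PE-SI** = 1 − Σ_{couples} P(couple) Σ_g T(g|couple)²: the probability
  two full siblings (independent transmissions from one random couple)
  differ in genotype, computed by exact enumeration over parent-genotype
  pairs.

Several inequivalent "exclusion power" definitions circulate in the
parentage literature (notably the dam-known trio exclusion for two-parent
cases). The pair-exclusion PE-2P and sib-non-identity PE-SI semantics used
here are the ones consistent with the packaged reference table: on its only
biallelic locus (whose frequencies can be recovered exactly by inverting
the published unbiased He = 0.372 at n = 114, giving p = 0.7546) they
reproduce the published 0.237 and 0.319, whereas the trio-based two-parent
definition gives 0.151. Each closed form is verified in the test suite
against an independent brute-force enumeration oracle to 1e-12 and against
Mendelian simulation at 20 000 trios/sib pairs.

Matching probability defaults to the observed-genotype convention (sum of
squared genotype relative frequencies) because that is what the standard
forensic software reports from raw genotypes; the HWE-expected mode
(Σ P_HWE(g)²) is the one computable from a frequency spectrum alone.

## Panel combination and minimal panels

CMP = Π MPₗ and CPE = 1 − Π(1−PEₗ) across loci, computed in full double
precision with no intermediate rounding (CMP is also exposed as a
scientific-notation string since 30-locus values underflow casual
formatting). Both trajectories are monotone in panel size, so the minimal
panel for a threshold is the first prefix reaching it. The default ordering
ranks loci by the chosen metric (descending for exclusion powers, ascending
for MP) with ties broken by input order; the Stockmarks 11 and ISAG core 12
commercial panels are shipped as named fixed orders. An unreachable
threshold is reported as `minimal_size=None`, never silently truncated.

## Differentiation

F_ST is the Weir & Cockerham (1984) θ: per locus and allele the a/b/c
variance components are computed from sample sizes, allele frequencies and
heterozygote frequencies; estimates combine across alleles and loci as a
ratio of summed components (never a mean of per-locus ratios, which would
up-weight uninformative loci). θ can legitimately be slightly negative in
undifferentiated data; pairwise *distance* outputs clamp at 0 while the raw
estimate is retained in the scalar API. Populations with missing data at a
locus drop out of that locus; a locus informative in fewer than two
populations of a pair contributes nothing to that pair.

R_ST contrasts copy-weighted within-population allele-size variance with
the pooled variance, (S_T − S_W)/S_T, combined across loci as a ratio of
summed components. Reynolds distance is computed from pairwise θ as
D = −ln(1−θ) (linear in divergence time under pure drift); since the
software behind the published distance matrices does not document which
Reynolds variant it applies, the linearised θ/(1−θ) form is available as an
option and the choice is explicit in the API.

## Phylogeny

Neighbor joining follows the Saitou–Nei Q-criterion. Determinism: Q ties
are broken by the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest leaf). Negative branch-length estimates
are clamped to zero with the deficit moved to the sister branch, preserving
the pair sum. NJ is exact on additive inputs — the suite verifies topology
and branch-length recovery on randomly generated 4–8-taxon trees and
path-metric equality to 1e-9.

The individual-level tree uses the allele-sharing distance
D = 1 − shared/(2·loci compared) with multiset sharing semantics
({a,b} vs {a,a} shares one allele); it is the natural individual-level
distance for unlinked STRs, chosen because no individual-level analogue of
R_ST is defined. Locus-bootstrap support (resampling loci with replacement,
100 replicates by default) is available but not part of tree construction.

## Assignment

The frequency score is the log HWE likelihood of the multi-locus genotype
under reference frequencies with zero-frequency substitution 0.01 (the
default of the classic assignment software; configurable). The Bayesian
score is the Rannala–Mountain posterior-predictive probability under a
symmetric Dirichlet prior with total mass 1 over the K alleles at the locus
(1/K each, K counting any allele the test individual carries that the
reference lacks, so the score is always finite), in sequential-draw form
with a factor 2 for heterozygotes; it converges to the frequency score as
reference counts grow, which the suite asserts.

Self-assignment is leave-one-out: the test individual's two copies are
removed from its own population's counts before scoring (populations of
size one cannot be left out and keep their counts). Exact score ties go to
the first population label and are flagged ambiguous.

The exclusion test simulates N HWE genotypes (default 1000) from the
reference frequencies at the individual's typed loci and reports
p = (1 + #{simulated ≤ observed})/(N+1) — the permutation convention that
never returns 0; the default decision threshold is 0.001. This makes the
test conservative: its type-I error is at most the nominal level up to the
1/(N+1) granularity, verified by calibration over 2000 replicates.

Cross-validation draws, per iteration, a balanced training sample of the
requested size from each population, ranks loci by training-data-only
Weir–Cockerham θ (ties by input order), and assigns every held-out
individual with the frequency score on training frequencies, for every
(training size, top-m loci) grid cell. The classifier is deliberately the
genotype-likelihood scorer rather than a generic machine-learning model:
it keeps the procedure self-contained, assumption-explicit and exactly
reproducible given the seed. Accuracies are reported per population as
mean and variance across iterations (default 100).

## Synthetic data

The generator produces data with the statistical structure the estimators
assume, under the Balding–Nichols model: each population's allele
frequencies at each locus are Dirichlet(p_anc(1−F)/F) draws around a
common ancestral spectrum, so E[p_pop] = p_anc and the expected θ equals F.
Ancestral spectra default to flat-Dirichlet draws with allele counts
uniform in [2, 12] — the allele-count range of the packaged reference
table — on a dinucleotide-style 2-bp ladder starting at 100 bp. The default
design is three populations of 114, 13 and 21 individuals at F = 0.12,
mirroring the reference study's breed sample sizes and its overall
differentiation (0.1195). Trio and sib-pair generators implement exact
Mendelian transmission from HWE parents. For R_ST behaviour a deliberately
simple stepwise divergence model is provided: each population accumulates a
±1-repeat-unit random walk offset per locus, so between-population size
variance grows with divergence time while within-population variance stays
flat.

What the generator does **not** emulate: linkage between markers, null
alleles and genotyping error, mutation (beyond the R_ST size walk),
admixture and migration, family structure inside population samples, and
ascertainment of highly polymorphic markers. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions —
they do not certify behaviour on real herd-book data, where null alleles
and relatedness are the common complications.

## Numerical and testing choices

Frequency spectra must sum to 1 within 1e-9; Dirichlet draws are floored at
1e-12 and renormalised to keep spectra valid. Enumeration-vs-closed-form
agreement is asserted at 1e-12; simulation-vs-analytic agreement at 3
binomial standard errors; estimator recovery (θ vs the Balding–Nichols F)
at ±0.02 on the 50-seed mean for F ∈ {0.05, 0.12, 0.2}. Simulation sizes
in the suite (20 000 trios/sib pairs, 2000 exclusion-calibration
replicates, 150 HWE-calibration replicates, 50 θ-recovery seeds, 20
cross-validation iterations) were chosen so that the statistical tolerances
above are meaningful while the whole suite stays fast enough to run on
every change. All random processes take explicit seeds and are
reproducible bit-for-bit.

## Known limitations

* The Hardy–Weinberg chain is a plain swap sampler; for loci with many
  rare alleles its mixing is slower than specialised proposals, which is
  why the default chain is long.
* Likelihood-ratio paternity indices (PI/CPI) and mutation-aware parentage
  models are out of scope; the exclusion framework treats any Mendelian
  mismatch as exclusionary.
* Permutation significance for F_ST/R_ST matrices is not implemented; the
  distance outputs are point estimates.
* The Bayesian assignment prior is fixed at symmetric Dirichlet 1/K;
  hierarchical or correlated-frequency priors are not provided.
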