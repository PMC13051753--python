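# Methods

This note documents the statistical model behind `msatkin`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Data model

Genotypes are unordered diploid allele pairs over named loci. Allele
labels are opaque positive integers — fragment lengths under the
full-length encoding, categorical codes under the sequence-based
encodings — and nothing downstream assumes an ordering or a stepwise
mutation model: every statistic in the package is allele-identity based.
`0` is the missing-data code in files (the GenAlEx convention) and the
missing sentinel in memory; a genotype is either two alleles or fully
missing, and half-filled pairs are rejected at parse time.

Four allele-encoding schemes map annotated allele sequences to labels:
total sequence length (*FullLength*), target-repeat length
(*RepeatFocused*), the tuple of all annotated repeat lengths (*SSRs*), and
the full sequence string (*CAT*). The last two are coded categorically per
locus in first-appearance order, which keeps files stable across runs.
CAT refines FullLength by construction: sequences with equal CAT labels
have equal lengths.

The missing-data filter removes loci above the threshold first, then
recomputes individual missingness on the retained loci and removes
individuals. This order means an individual is never penalized for data
missing at loci that were discarded anyway; the converse order is
available via a flag. The filter is idempotent.

## Diversity statistics

Expected heterozygosity uses Nei's small-sample-unbiased estimator
(2n/(2n−1))(1 − Σpᵢ²) with allele frequencies estimated as plain sample
proportions over non-missing genotypes. The uncorrected 1 − Σp² form is
visibly different at n ≈ 20 (0.0444 vs 0.0455 at a 43:1 biallelic locus),
which is what pins the estimator choice.

The Hardy–Weinberg test is the conditional exact test: given the observed
allele counts, the p-value is the total probability of all genotype
configurations at most as probable as the observed one, with

    P(config | counts) = n! · 2^H · Πᵢ aᵢ! / ((2n)! · Π g_ij!)

where H is the heterozygote count. Configurations are enumerated row by
row in allele order; because rows below allele *i* never consume allele
*i*, each row's remainder must hit zero at the row's end, which prunes the
walk to the set of valid tables and forces each row's final cell. When
more than 10⁶ tables would be visited the test switches to Monte-Carlo:
the pooled allele vector is randomly re-paired and the p-value is the
add-one estimator (b+1)/(N+1), which can never return 0. Observed and
simulated probabilities are compared with a 10⁻⁹ relative slack so that
ties (the observed configuration itself) are always counted. Monomorphic
loci return p = 1 with a degeneracy flag rather than an error.

Linkage disequilibrium between two loci is the log-likelihood-ratio G of
the two-locus genotype contingency table, with the null distribution
obtained by permuting one locus's single-locus genotypes among
individuals; the p-value is again add-one. Bonferroni adjustment delegates
to statsmodels.

## Panel power

Exclusion probabilities are computed from the power sums aₖ = Σpᵢᵏ.
The default case is the random parental-pair exclusion

    Q = 1 + 4a₄ − 4a₅ − 3a₆ − 8a₂² + 8a₂a₃ + 2a₃²,

i.e. the probability that a random HWE couple is genetically incompatible
as the parents of a random offspring. This is the case that reproduces the
reference panel's published per-locus Q values; the one-parent-known
polynomial gives 0.0217 instead of 0.0420 at the panel's rare-allele
locus, which is how the default was pinned. The classical
one-parent-known and no-known-parent (shares-no-allele) polynomials are
available behind a flag. All three closed forms are treated as derived
conveniences: the normative definition is the brute-force enumeration over
offspring × candidate genotype combinations, and the property tests
require agreement to 10⁻¹⁰.

Identity is I = Σ P(G)² over HWE genotype probabilities. Joint values are
QC = 1 − Π(1 − Q_l) and IC = Π I_l. Frequencies feeding Q and I carry no
small-sample correction — again pinned by exact agreement with the
published per-locus values. Minimal-panel selection is greedy (decreasing
Q or increasing I, ties in input order), which reproduces the published
four-locus subset and scales; an exhaustive mode exists for ≤ 15 loci.

## Pairwise kinship

The per-locus likelihood of an unordered genotype pair given IBD
coefficients k = (k0, k1, k2) is k0·S0 + k1·S1 + k2·S2, with S0 the
product of the two HWE genotype probabilities, S2 the probability of the
shared genotype (zero unless identical), and S1 the joint probability of
the pair sharing exactly one allele identical by descent
((aa,aa) → pₐ³, (aa,ab) → pₐ²p_b, (ab,ab) → pₐp_b(pₐ+p_b),
(ab,ac) → pₐp_bp_c, no shared allele → 0). For every k these S-mixtures
sum to 1 over all ordered pairs of unordered genotypes, which the tests
verify by enumeration. Log-likelihoods are summed over jointly typed loci;
loci missing in either member are skipped pairwise. An impossible
configuration is carried as −∞, which loses every comparison and never
propagates NaN. Under PO the likelihood is −∞ exactly when some jointly
typed locus shares no allele — one mismatching locus excludes
parent–offspring outright.

Allele frequencies for all likelihoods are estimated from the complete
filtered dataset, including the focal pair. This is the common usage for
small cohorts and keeps results reproducible, but it means the reference
sample must not be dominated by the pair's own relatives: frequencies
estimated from a four-member family alone make the shared alleles look
common and wash out the signal. The analysis and tests therefore embed
families in a larger cohort, as a real study does.

**Estimation.** k̂ is found on a 0.01-step grid over the simplex followed
by a 0.001-step local refinement; the search is deterministic, boundary
solutions are reported exactly (hence r̂ = 0.5000 for pairs estimated
exactly at PO), and ties — including the flat likelihood of fully
monomorphic data — resolve to the least-related point, so degenerate input
yields k̂ = (1,0,0), r̂ = 0. Ties between canonical hypotheses resolve in
the order U > HS > FS > PO, consistent with the package's generally
conservative stance. Because estimates are truncated at r = 0, the mean
r̂ of truly unrelated pairs is positively biased (≈ 0.05–0.06 with 10
loci of 8 equifrequent alleles); this is a property of the estimator, not
an implementation artifact.

**Confidence sets.** For each candidate hypothesis R, the observed
statistic is λ_obs = lnL(best candidate) − lnL(R); n_sim pairs are
simulated under R at the pair's jointly typed loci and frequencies, each
re-maximized over the candidates, and R stays in the set iff
p_R = (#{λ_sim ≥ λ_obs}+1)/(n_sim+1) > α. The re-maximizing construction
(rather than fixing the observed pair's best hypothesis) was adopted
because it makes λ_sim ≥ 0 always, so the best-supported hypothesis is
always a member and the set is never empty. The add-one estimator makes
coverage conservative; simulated coverage of the true relationship at
α = 0.05 runs ≈ 95–96%.

**Classification and disambiguation.** Related iff U is outside the 95%
set; unrelated iff the set is exactly {U}; ambiguous otherwise. Each
ambiguous pair's best hypothesis is then tested against every alternative
in its set: simulate under the alternative (as null), reject it if the
Bonferroni-adjusted p falls below α. The Bonferroni factor is the total
number of tests across all ambiguous pairs of the run (per-pair scope is
available behind a flag). Note the arithmetic this implies: with m tests
the rejection threshold is α/m, and a simulation p-value cannot fall below
1/(n_sim+1), so n_sim must comfortably exceed m/α for the correction to be
satisfiable at all — the analysis driver uses a deeper n_sim for the
disambiguation pass than for the confidence sets for exactly this reason.
Even then, most ambiguous pairs remain ambiguous: pairs stay ambiguous
precisely because their likelihood ratio against the retained alternative
is modest, so this stage mainly documents that the ambiguity is real
rather than resolving it. That matches the behavior of this class of
analysis on real cohorts.

All Monte-Carlo machinery draws pairs from a single sampling engine
(`simdata.simulate_pairs`), so the distribution being simulated is
provably the one the likelihood assumes — a cross-module test compares
empirical genotype-pair frequencies against the S-mixture at 3 Monte-Carlo
standard errors for every canonical hypothesis.

## Synthetic data

The generator emulates the statistical structure of a small captive
cohort, not its biology:

* **Frequency profiles** (`table1_like_frequencies`): ten loci with 2–8
  alleles (mean 4.4, matching the reference panel's allele counts),
  Dirichlet(0.5)-skewed frequencies floored at 0.5% and redrawn
  (deterministically under the seed) until the across-locus mean gene
  diversity lies in 0.35–0.55, the band around the reference panel's mean
  unbiased H_E of 0.45. Allele labels are plausible fragment lengths
  (locus size stepped by motif length).
* **Founders** are mutually unrelated, non-inbred HWE draws. Offspring
  receive one uniformly chosen allele per parent per locus; parental
  missingness propagates. Pedigrees are declared as founders plus matings;
  the derived truth table labels pairs PO/FS/HS and everything else U.
* **Pairs under IBD coefficients**: the IBD-allele count per locus is
  drawn from (k0,k1,k2), the first genotype is HWE, the second copies the
  IBD alleles and fills the rest from the frequencies.
* **Missing data** is injected independently per genotype. The analysis
  driver uses a 2% rate: with ten loci, the 10% per-locus/per-individual
  filter threshold sits exactly at "one missing genotype", so small rate
  changes flip many individuals across the threshold; 2% reproduces a
  retained dataset in which most loci and individuals survive, as in the
  study cohort this emulates.

Not emulated: mutation (no stepwise model), genotyping artifacts (stutter,
null alleles, allelic dropout), inbreeding, and population structure.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own model assumptions — they do not show robustness to
null alleles or Wahlund-type heterozygote deficits, which real
microsatellite panels must screen for upstream.

## Problem sizes used in the checks

The statistical guarantees are exercised at sizes chosen to make the
Monte-Carlo bands tight enough to be meaningful: confidence-set coverage
on 400 simulated pairs at n_sim = 1,000; LRT size on 200 replicates at
n_sim = 1,000; relatedness recovery on 200 pairs per hypothesis at 10
loci × 8 equifrequent alleles; family-topology recovery on a
two-parent/two-offspring family embedded among 16 unrelated founders. The
package defaults (n_sim = 100,000) are for production use.

## Known limitations

* No inbreeding or null-allele extension to the pair likelihood; the four
  canonical hypotheses assume non-inbred individuals with unrelated
  parents. When parents are themselves related, PO and FS become
  statistically confoundable (r̂ > 0.5 pairs can swap labels); the
  conservative rule still flags such pairs as related, which is the
  decision that matters for pairing.
* Q and I assume HWE frequencies; loci with strong HWE deviations feed
  biased power estimates.
* The relatedness point estimate is boundary-truncated and should be read
  together with its confidence set, never alone.
* Exact HWE enumeration is exponential in allele count; highly polymorphic
  loci at large n silently use the (seeded) Monte-Carlo path, reported in
  the result's `method` field.
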