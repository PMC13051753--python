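"""Per-locus diversity statistics and tests.

Observed heterozygosity, Nei's unbiased expected heterozygosity, the
conditional exact Hardy-Weinberg test (full enumeration or Monte-Carlo
re-pairing of the pooled allele vector), a permutation G-test for genotypic
linkage disequilibrium, and Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .genotype_io import MISSING, GenotypeTable, LocusFrequencies, allele_frequencies

#: Configurations enumerated before the exact HWE test falls back to Monte-Carlo.
ENUMERATION_LIMIT = 10**6

_LOG2 = np.log(2.0)
_PROB_TOL = 1e-9  # relative slack when comparing conditional log-probabilities


def observed_heterozygosity(table: GenotypeTable, locus: str) -> float:
    """Fraction of non-missing genotypes that are heterozygous."""
    j = table.locus_index(locus)
    col = table.alleles[:, j, :]
    typed = col[col[:, 0] != MISSING]
    if typed.size == 0:
        raise ValueError(f"locus {locus!r} is entirely missing")
    return float(np.mean(typed[:, 0] != typed[:, 1]))


def expected_heterozygosity_unbiased(freqs: LocusFrequencies) -> float:
    """Nei's unbiased gene diversity, (2n/(2n-1)) (1 - sum p_i^2)."""
    n = freqs.n_genotyped
    if n < 2:
        raise ValueError("unbiased expected heterozygosity needs n_genotyped >= 2")
    p = freqs.freq_array()
    two_n = 2 * n
    return float(two_n / (two_n - 1) * (1.0 - np.sum(p * p)))


# ---------------------------------------------------------------------------
# Conditional exact HWE test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HweResult:
    """Exact-test outcome: p-value, method actually used, degeneracy flag."""

    p_value: float
    method: str  # "enumeration", "monte-carlo", or "degenerate"
    degenerate: bool = False


def _log_config_prob(het: int, log_fact_g: float, const: float) -> float:
    # log P(G | allele counts) = const + H log2 - sum log g_ij!
    return const + het * _LOG2 - log_fact_g


def _enumerate_pvalue(
    allele_counts: np.ndarray, n: int, const: float, cutoff: float, limit: int
) -> float:
    """Total conditional probability of all genotype-count tables with the
    given allele margins whose log-probability is <= ``cutoff``; raises
    OverflowError once more than ``limit`` tables have been visited.

    Genotype cells are filled row by row in allele order.  Rows below i never
    touch allele i, so allele i's remaining count must hit zero by the end of
    row i — which both prunes infeasible branches early and forces each row's
    last cell, making the walk proportional to the number of valid tables.
    """
    from math import exp

    K = len(allele_counts)
    lf = gammaln(np.arange(2 * n + 2)).tolist()  # lf[g] = log g! at index g+... (lf[g+1])
    rem = allele_counts.astype(int).tolist()
    state = [0, 0.0]  # visited count, accumulated probability

    def row(i: int, j: int, het: int, log_fact: float) -> None:
        if i == K:
            state[0] += 1
            if state[0] > limit:
                raise OverflowError
            lp = const + het * _LOG2 - log_fact
            if lp <= cutoff:
                state[1] += exp(lp)
            return
        if j == K - 1:  # last cell of row i is forced by allele i's remainder
            if i == K - 1:
                if rem[i] % 2 == 0:
                    g = rem[i] // 2
                    row(K, K, het, log_fact + lf[g + 1])
            else:
                g = rem[i]
                if g <= rem[K - 1]:
                    rem[K - 1] -= g
                    row(i + 1, i + 1, het + g, log_fact + lf[g + 1])
                    rem[K - 1] += g
            return
        gmax = rem[i] // 2 if i == j else min(rem[i], rem[j])
        for g in range(gmax + 1):
            if i == j:
                rem[i] -= 2 * g
                row(i, j + 1, het, log_fact + lf[g + 1])
                rem[i] += 2 * g
            else:
                rem[i] -= g
                rem[j] -= g
                row(i, j + 1, het + g, log_fact + lf[g + 1])
                rem[i] += g
                rem[j] += g

    row(0, 0, 0, 0.0)
    return state[1]


def hwe_exact_test(
    table: GenotypeTable,
    locus: str,
    method: str = "auto",
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> HweResult:
    """Conditional exact test of Hardy-Weinberg proportions at one locus.

    The p-value is the total conditional probability (given the observed
    allele counts) of all genotype configurations at most as probable as the
    observed one.  ``method`` is ``"enumeration"``, ``"monte-carlo"``, or
    ``"auto"`` (enumerate when the configuration count is manageable, else
    Monte-Carlo re-pairing of the pooled allele vector with the add-one
    p-value estimator (b + 1)/(reps + 1)).
    """
    if method not in ("auto", "enumeration", "monte-carlo"):
        raise ValueError(f"unknown method {method!r}")
    j = table.locus_index(locus)
    col = table.alleles[:, j, :]
    typed = col[col[:, 0] != MISSING]
    n = len(typed)
    if n < 2:
        raise ValueError(f"locus {locus!r}: need >= 2 non-missing genotypes")
    labels, counts = np.unique(typed.ravel(), return_counts=True)
    if len(labels) == 1:
        return HweResult(1.0, "degenerate", degenerate=True)
    K = len(labels)
    idx = {a: i for i, a in enumerate(labels)}
    geno = np.array([[idx[a], idx[b]] for a, b in typed])
    het_obs = int(np.sum(geno[:, 0] != geno[:, 1]))
    cell_codes = geno[:, 0] * K + geno[:, 1]
    _, cell_counts = np.unique(cell_codes, return_counts=True)
    log_fact_obs = float(np.sum(gammaln(cell_counts + 1)))

    const = float(gammaln(n + 1) + np.sum(gammaln(counts + 1)) - gammaln(2 * n + 1))
    logp_obs = _log_config_prob(het_obs, log_fact_obs, const)
    cutoff = logp_obs + _PROB_TOL * max(1.0, abs(logp_obs))

    if method in ("auto", "enumeration"):
        try:
            total = _enumerate_pvalue(counts, n, const, cutoff, ENUMERATION_LIMIT)
            return HweResult(min(total, 1.0), "enumeration")
        except OverflowError:
            if method == "enumeration":
                raise ValueError(
                    f"locus {locus!r}: more than {ENUMERATION_LIMIT} configurations; use Monte-Carlo"
                ) from None

    rng = np.random.default_rng(seed)
    pool = geno.ravel()  # allele indices, so the pair codes below cannot collide
    lf = gammaln(np.arange(n + 2))
    b = 0
    done = 0
    while done < mc_reps:
        chunk = min(5_000, mc_reps - done)
        keys = rng.random((chunk, 2 * n))
        perm = pool[np.argsort(keys, axis=1)].reshape(chunk, n, 2)
        perm.sort(axis=2)
        het = np.sum(perm[:, :, 0] != perm[:, :, 1], axis=1)
        codes = perm[:, :, 0] * K + perm[:, :, 1]
        cell = np.zeros((chunk, K * K), dtype=np.int64)
        np.add.at(cell, (np.repeat(np.arange(chunk), n), codes.ravel()), 1)
        lp = const + het * _LOG2 - lf[cell + 1].sum(axis=1)
        b += int(np.sum(lp <= cutoff))
        done += chunk
    return HweResult((b + 1) / (mc_reps + 1), "monte-carlo")


# ---------------------------------------------------------------------------
# Genotypic linkage disequilibrium (permutation G-test)
# ---------------------------------------------------------------------------

def _g_statistic(counts: np.ndarray) -> float:
    # log-likelihood-ratio G of a two-way table; zero cells contribute 0
    n = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / n
        terms = counts * np.log(counts / expected)
    return float(2.0 * np.nansum(terms))


def ld_test(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    permutations: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for genotypic association between two loci.

    The statistic is the log-likelihood-ratio G of the two-locus genotype
    contingency table; the null distribution permutes one locus's single-locus
    genotypes among individuals; p = (b + 1)/(permutations + 1).
    """
    ja, jb = table.locus_index(locus_a), table.locus_index(locus_b)
    A = table.alleles[:, ja, :]
    B = table.alleles[:, jb, :]
    both = (A[:, 0] != MISSING) & (B[:, 0] != MISSING)
    A, B = A[both], B[both]
    if len(A) < 5:
        raise ValueError("fewer than 5 individuals jointly non-missing at the two loci")

    def codes(G: np.ndarray) -> tuple[np.ndarray, int]:
        uniq, inv = np.unique(G, axis=0, return_inverse=True)
        return inv, len(uniq)

    ca, ka = codes(A)
    cb, kb = codes(B)
    if ka < 2 or kb < 2:
        raise ValueError("both loci must be polymorphic among the jointly typed individuals")

    def table_of(cb_perm: np.ndarray) -> np.ndarray:
        return np.bincount(ca * kb + cb_perm, minlength=ka * kb).reshape(ka, kb).astype(float)

    g_obs = _g_statistic(table_of(cb))
    rng = np.random.default_rng(seed)
    b = 0
    perm = cb.copy()
    for _ in range(permutations):
        rng.shuffle(perm)
        if _g_statistic(table_of(perm)) >= g_obs - 1e-12:
            b += 1
    return (b + 1) / (permutations + 1)


def bonferroni_adjust(pvalues) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="bonferroni")[1]


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Per-locus diversity table plus panel means (arithmetic over loci)."""

    per_locus: pd.DataFrame  # index: locus; columns n, n_alleles, ho, he, p_hwe
    means: pd.Series  # means of n_alleles, ho, he


def diversity_summary(
    table: GenotypeTable,
    hwe_method: str = "auto",
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> DiversitySummary:
    """Number of alleles, H_O, unbiased H_E and exact-HWE p per locus."""
    rows = {}
    for loc in table.locus_names:
        freqs = allele_frequencies(table, loc)
        rows[loc] = {
            "n": freqs.n_genotyped,
            "n_alleles": freqs.n_alleles,
            "ho": observed_heterozygosity(table, loc),
            "he": expected_heterozygosity_unbiased(freqs),
            "p_hwe": hwe_exact_test(table, loc, method=hwe_method, mc_reps=mc_reps, seed=seed).p_value,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return DiversitySummary(per_locus=df, means=df[["n_alleles", "ho", "he"]].mean())
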