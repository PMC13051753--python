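"""Exclusion and identity power of a microsatellite panel.

Per-locus probability of parental exclusion (Q) and of genetic identity (I)
from allele frequencies, their joint combinations across loci
(QC = 1 - prod(1 - Q_l), IC = prod I_l), a brute-force enumeration oracle for
the exclusion polynomials, and greedy minimal-panel selection.

Three exclusion cases are supported.  ``parent_pair`` — the probability that
a random candidate couple (both drawn under HWE) is genetically incompatible
as the parental pair of a random offspring — is the default: it is the case
that reproduces the published per-locus Q values.  ``one_parent_known``
(exclude a candidate second parent given a known true parent) and
``no_known_parent`` (a lone candidate parent is excluded iff it shares no
allele with the offspring) use the classical Jamieson-Taylor polynomials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, LocusFrequencies, all_frequencies

PARENT_PAIR = "parent_pair"
ONE_PARENT_KNOWN = "one_parent_known"
NO_KNOWN_PARENT = "no_known_parent"
CASES = (PARENT_PAIR, ONE_PARENT_KNOWN, NO_KNOWN_PARENT)

#: Enumeration bound for the brute-force oracle.
BRUTEFORCE_MAX_ALLELES = 8


def _freq_vector(freqs) -> np.ndarray:
    if isinstance(freqs, LocusFrequencies):
        return freqs.freq_array()
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def power_moments(freqs, k: int) -> float:
    """k-th power sum of the allele frequencies, a_k = sum_i p_i^k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = _freq_vector(freqs)
    return float(np.sum(p**k))


def exclusion_probability(freqs, case: str = PARENT_PAIR) -> float:
    """Closed-form per-locus exclusion probability for the given case."""
    p = _freq_vector(freqs)
    a2, a3, a4, a5, a6 = (float(np.sum(p**k)) for k in range(2, 7))
    if case == PARENT_PAIR:
        q = 1 + 4 * a4 - 4 * a5 - 3 * a6 - 8 * a2**2 + 8 * a2 * a3 + 2 * a3**2
    elif case == ONE_PARENT_KNOWN:
        q = 1 - 2 * a2 + a3 + 3 * (a2 * a3 - a5) - 2 * (a2**2 - a4)
    elif case == NO_KNOWN_PARENT:
        q = 1 - 4 * a2 + 2 * a2**2 + 4 * a3 - 3 * a4
    else:
        raise ValueError(f"unknown exclusion case {case!r}; expected one of {CASES}")
    # clip the tiny negative round-off a monomorphic locus can produce
    return float(min(max(q, 0.0), 1.0))


def _genotypes(K: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(K) for j in range(i, K)]


def _gprob(g: tuple[int, int], p: np.ndarray) -> float:
    a, b = g
    return p[a] * p[a] if a == b else 2 * p[a] * p[b]


def _mendel_compatible(c1: tuple[int, int], c2: tuple[int, int], off: tuple[int, int]) -> bool:
    return any(
        (min(x, y), max(x, y)) == off for x, y in itertools.product(c1, c2)
    )


def exclusion_probability_bruteforce(freqs, case: str = PARENT_PAIR) -> float:
    """Exact enumeration over genotype combinations; the normative definition
    the closed-form polynomials are checked against."""
    p = _freq_vector(freqs)
    K = len(p)
    if K > BRUTEFORCE_MAX_ALLELES:
        raise ValueError(f"brute force limited to {BRUTEFORCE_MAX_ALLELES} alleles, got {K}")
    G = _genotypes(K)
    total = 0.0
    if case == PARENT_PAIR:
        for off in G:
            po = _gprob(off, p)
            if po == 0.0:
                continue
            excl = sum(
                _gprob(c1, p) * _gprob(c2, p)
                for c1 in G
                for c2 in G
                if not _mendel_compatible(c1, c2, off)
            )
            total += po * excl
    elif case == ONE_PARENT_KNOWN:
        # true parents M, F under HWE; offspring Mendelian; candidate C under
        # HWE is excluded as the second parent iff (M, C) cannot produce it
        for M in G:
            pm = _gprob(M, p)
            for F in G:
                pf = _gprob(F, p)
                for x, y in itertools.product(M, F):
                    off = (min(x, y), max(x, y))
                    excl = sum(_gprob(C, p) for C in G if not _mendel_compatible(M, C, off))
                    total += pm * pf * 0.25 * excl
    elif case == NO_KNOWN_PARENT:
        for off in G:
            po = _gprob(off, p)
            excl = sum(_gprob(C, p) for C in G if not set(C) & set(off))
            total += po * excl
    else:
        raise ValueError(f"unknown exclusion case {case!r}; expected one of {CASES}")
    return float(total)


def identity_probability(freqs) -> float:
    """Probability two random HWE individuals share a genotype at the locus:
    I = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2 = sum_G P(G)^2."""
    p = _freq_vector(freqs)
    a2 = float(np.sum(p**2))
    a4 = float(np.sum(p**4))
    # sum_{i<j} (2 p_i p_j)^2 = 2 ((sum p^2)^2 - sum p^4)
    return float(a4 + 2.0 * (a2**2 - a4))


def combine_exclusion(per_locus_q: Sequence[float]) -> float:
    """Joint exclusion probability QC = 1 - prod(1 - Q_l)."""
    q = np.asarray(list(per_locus_q), dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("per-locus Q values must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - q))


def combine_identity(per_locus_i: Sequence[float]) -> float:
    """Joint identity probability IC = prod I_l."""
    i = np.asarray(list(per_locus_i), dtype=float)
    if np.any((i < 0) | (i > 1)):
        raise ValueError("per-locus I values must lie in [0, 1]")
    return float(np.prod(i))


@dataclass
class PanelSelection:
    """A locus subset chosen by minimal_panel with its achieved joint values."""

    loci: list[str]
    qc: float
    ic: float


def minimal_panel(
    per_locus_metrics: Mapping[str, tuple[float, float]] | pd.DataFrame,
    criterion: str,
    threshold: float,
    exhaustive: bool = False,
) -> PanelSelection:
    """Smallest locus subset meeting a joint power criterion.

    ``per_locus_metrics`` maps locus -> (Q, I) (or is a DataFrame with
    ``q_exclusion``/``i_identity`` columns).  ``criterion`` is ``"qc"``
    (require QC >= threshold, greedy by decreasing Q) or ``"ic"`` (require
    IC <= threshold, greedy by increasing I).  Ties keep input order.  With
    ``exhaustive=True`` (panels of <= 15 loci) all subsets are searched and
    the smallest satisfying subset with the best joint value is returned.
    """
    if isinstance(per_locus_metrics, pd.DataFrame):
        items = [(loc, (float(r["q_exclusion"]), float(r["i_identity"])))
                 for loc, r in per_locus_metrics.iterrows()]
    else:
        items = [(loc, (float(q), float(i))) for loc, (q, i) in per_locus_metrics.items()]
    if criterion not in ("qc", "ic"):
        raise ValueError(f"criterion must be 'qc' or 'ic', got {criterion!r}")

    def joint(sub: list[tuple[str, tuple[float, float]]]) -> tuple[float, float]:
        return (
            combine_exclusion([m[0] for _, m in sub]),
            combine_identity([m[1] for _, m in sub]),
        )

    def satisfied(qc: float, ic: float) -> bool:
        return qc >= threshold if criterion == "qc" else ic <= threshold

    if exhaustive:
        if len(items) > 15:
            raise ValueError("exhaustive search limited to 15 loci")
        for size in range(1, len(items) + 1):
            best = None
            for combo in itertools.combinations(items, size):
                qc, ic = joint(list(combo))
                if satisfied(qc, ic):
                    score = qc if criterion == "qc" else -ic
                    if best is None or score > best[0]:
                        best = (score, list(combo), qc, ic)
            if best is not None:
                return PanelSelection([loc for loc, _ in best[1]], best[2], best[3])
        qc, ic = joint(items)
        raise ValueError(f"criterion unattainable; best achievable QC={qc:.4f}, IC={ic:.3e}")

    # greedy: stable sort keeps input order on ties
    order = sorted(
        items,
        key=(lambda kv: -kv[1][0]) if criterion == "qc" else (lambda kv: kv[1][1]),
    )
    chosen: list[tuple[str, tuple[float, float]]] = []
    for item in order:
        chosen.append(item)
        qc, ic = joint(chosen)
        if satisfied(qc, ic):
            return PanelSelection([loc for loc, _ in chosen], qc, ic)
    raise ValueError(f"criterion unattainable; best achievable QC={qc:.4f}, IC={ic:.3e}")


@dataclass
class PanelPowerReport:
    """Per-locus Q and I plus joint QC/IC for a locus subset."""

    per_locus: pd.DataFrame  # index locus; columns q_exclusion, i_identity
    qc: float
    ic: float
    loci: list[str]
    case: str


def panel_power_report(
    table: GenotypeTable,
    loci: Sequence[str] | None = None,
    case: str = PARENT_PAIR,
) -> PanelPowerReport:
    """Compute Q/I per locus from a genotype table and combine across loci."""
    freqs = all_frequencies(table)
    use = list(loci) if loci is not None else table.locus_names
    rows = {
        loc: {
            "q_exclusion": exclusion_probability(freqs[loc], case),
            "i_identity": identity_probability(freqs[loc]),
        }
        for loc in use
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return PanelPowerReport(
        per_locus=df,
        qc=combine_exclusion(df["q_exclusion"]),
        ic=combine_identity(df["i_identity"]),
        loci=use,
        case=case,
    )
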