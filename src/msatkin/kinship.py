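"""Maximum-likelihood pairwise relatedness for codominant loci.

For a pair of non-inbred diploids, the per-locus likelihood of observing the
unordered genotype pair (g1, g2) given IBD coefficients k = (k0, k1, k2) is

    L = k0 * S0 + k1 * S1 + k2 * S2

where S0 is the product of the two HWE genotype probabilities, S2 the HWE
probability of the shared genotype (zero unless g1 = g2), and S1 the joint
probability that the pair shares exactly one allele identical by descent.
Log-likelihoods are summed across jointly typed loci.  On top of this model
the module provides:

* ML point estimation of k (simplex grid plus local refinement) and of the
  relatedness coefficient r = k2 + k1/2;
* classification into the four canonical hypotheses U/HS/FS/PO, breaking
  ties toward the less related hypothesis;
* simulation confidence sets: a hypothesis R stays in the 95% set unless the
  observed likelihood-ratio statistic against R exceeds what re-maximized
  statistics from pairs simulated under R produce;
* the conservative related/unrelated/ambiguous rule (related only if U is
  outside the set; unrelated only if nothing but U is inside);
* specific likelihood-ratio tests and a Bonferroni-corrected disambiguation
  pass over all ambiguous pairs of a run.

Monte-Carlo pairs are drawn by :func:`msatkin.simdata.simulate_pairs`, the
package's single pair-sampling engine, at the focal pair's jointly typed
loci with frequencies estimated from the full dataset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import bonferroni_adjust
from .genotype_io import MISSING, GenotypeTable, LocusFrequencies, all_frequencies
from . import simdata

NEG_INF = float("-inf")


@dataclass(frozen=True)
class RelationshipHypothesis:
    """A named point (k0, k1, k2) in IBD-coefficient space."""

    label: str
    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        k = np.array([self.k0, self.k1, self.k2])
        if np.any(k < 0) or abs(k.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.label}: k must be non-negative and sum to 1")

    @property
    def k(self) -> tuple[float, float, float]:
        return (self.k0, self.k1, self.k2)

    @property
    def r(self) -> float:
        return self.k2 + self.k1 / 2.0


U = RelationshipHypothesis("U", 1.0, 0.0, 0.0)
HS = RelationshipHypothesis("HS", 0.5, 0.5, 0.0)
FS = RelationshipHypothesis("FS", 0.25, 0.5, 0.25)
PO = RelationshipHypothesis("PO", 0.0, 1.0, 0.0)

#: Canonical hypotheses in conservative tie-break order (least related first).
CANONICAL: tuple[RelationshipHypothesis, ...] = (U, HS, FS, PO)
_BY_LABEL = {h.label: h for h in CANONICAL}


def hypothesis(label: str | RelationshipHypothesis) -> RelationshipHypothesis:
    if isinstance(label, RelationshipHypothesis):
        return label
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise KeyError(f"unknown relationship hypothesis {label!r}") from None


# ---------------------------------------------------------------------------
# Per-locus likelihood components
# ---------------------------------------------------------------------------

def _s_components_batch(
    g1: np.ndarray, g2: np.ndarray, p: np.ndarray, index: dict[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """S0/S1/S2 for batches of unordered genotype pairs at one locus.

    ``g1``/``g2`` are (n, 2) arrays of allele labels; ``p`` the frequency
    vector; ``index`` maps label -> position in ``p``.
    """
    lut_max = max(index) + 1
    lut = np.full(lut_max, -1, dtype=np.int64)
    for lab, i in index.items():
        lut[lab] = i
    if np.any(g1 >= lut_max) or np.any(g2 >= lut_max):
        raise ValueError("allele absent from the frequency estimate")
    i1 = lut[g1]
    i2 = lut[g2]
    if np.any(i1 < 0) or np.any(i2 < 0):
        raise ValueError("allele absent from the frequency estimate")
    a, b = p[i1[:, 0]], p[i1[:, 1]]
    c, d = p[i2[:, 0]], p[i2[:, 1]]
    hom1 = i1[:, 0] == i1[:, 1]
    hom2 = i2[:, 0] == i2[:, 1]
    pg1 = np.where(hom1, a * b, 2 * a * b)
    pg2 = np.where(hom2, c * d, 2 * c * d)
    s0 = pg1 * pg2
    s2 = np.where((i1[:, 0] == i2[:, 0]) & (i1[:, 1] == i2[:, 1]), pg1, 0.0)

    # transition t(x -> g2): probability the non-IBD draw completes g2 given
    # the IBD allele is x; zero when x is not in g2
    def trans(x: np.ndarray, px: np.ndarray) -> np.ndarray:
        t_hom = np.where(x == i2[:, 0], c, 0.0)
        t_het = np.where(x == i2[:, 0], d, 0.0) + np.where(x == i2[:, 1], c, 0.0)
        return np.where(hom2, t_hom, t_het)

    s1 = pg1 * 0.5 * (trans(i1[:, 0], a) + trans(i1[:, 1], b))
    return s0, s1, s2


class _PairComponents:
    """Per-locus S0/S1/S2 of one observed pair over jointly typed loci."""

    def __init__(
        self,
        g1: Mapping[str, tuple[int, int] | None] | np.ndarray,
        g2: Mapping[str, tuple[int, int] | None] | np.ndarray,
        freqs_per_locus: Mapping[str, LocusFrequencies],
    ) -> None:
        loci = list(freqs_per_locus)
        r1 = _as_rows(g1, loci)
        r2 = _as_rows(g2, loci)
        typed = (r1[:, 0] != MISSING) & (r2[:, 0] != MISSING)
        self.loci = [l for l, t in zip(loci, typed) if t]
        if not self.loci:
            raise ValueError("no locus is jointly non-missing for this pair")
        s0, s1, s2 = [], [], []
        for l in self.loci:
            f = freqs_per_locus[l]
            idx = {a: i for i, a in enumerate(f.alleles)}
            j = loci.index(l)
            c0, c1, c2 = _s_components_batch(
                r1[j : j + 1], r2[j : j + 1], f.freq_array(), idx
            )
            s0.append(c0[0])
            s1.append(c1[0])
            s2.append(c2[0])
        self.s = np.array([s0, s1, s2])  # shape (3, n_loci)

    def loglik(self, k: Sequence[float]) -> float:
        mix = np.asarray(k, dtype=float) @ self.s
        if np.any(mix <= 0.0):
            return NEG_INF
        return float(np.sum(np.log(mix)))

    def loglik_grid(self, K: np.ndarray) -> np.ndarray:
        """Log-likelihood for many k at once; K has shape (m, 3)."""
        mix = K @ self.s  # (m, n_loci)
        out = np.full(len(K), NEG_INF)
        ok = np.all(mix > 0.0, axis=1)
        out[ok] = np.sum(np.log(mix[ok]), axis=1)
        return out


def _as_rows(g, loci: list[str]) -> np.ndarray:
    if isinstance(g, np.ndarray):
        arr = np.asarray(g, dtype=np.int64)
        if arr.shape != (len(loci), 2):
            raise ValueError(f"genotype array shape {arr.shape} != ({len(loci)}, 2)")
        return np.sort(arr, axis=1)
    arr = np.zeros((len(loci), 2), dtype=np.int64)
    for j, l in enumerate(loci):
        pair = g.get(l)
        if pair is not None:
            arr[j] = sorted(pair)
    return arr


def pair_likelihood(
    g1,
    g2,
    freqs_per_locus: Mapping[str, LocusFrequencies],
    k: Sequence[float] | RelationshipHypothesis,
) -> float:
    """Log-likelihood of an unordered genotype pair under IBD coefficients k.

    Loci missing in either member are skipped; an impossible configuration
    (e.g. no shared allele under k1 = 1) returns ``-inf``.
    """
    if isinstance(k, RelationshipHypothesis):
        k = k.k
    return _PairComponents(g1, g2, freqs_per_locus).loglik(k)


# ---------------------------------------------------------------------------
# ML estimation over the k simplex
# ---------------------------------------------------------------------------

def _simplex_grid(step: float) -> np.ndarray:
    m = round(1.0 / step)
    pts = [
        (i / m, j / m, (m - i - j) / m)
        for i in range(m + 1)
        for j in range(m + 1 - i)
    ]
    K = np.array(pts)  # columns k0, k1, k2
    # order by (r, k2) so ties resolve toward the least related point
    r = K[:, 2] + K[:, 1] / 2.0
    order = np.lexsort((K[:, 2], r))
    return K[order]


_COARSE_GRID = _simplex_grid(0.01)


def _first_argmax(ll: np.ndarray, tol: float = 1e-9) -> int:
    """First index within tolerance of the maximum, so that exact ties (and
    round-off ties) resolve to the least-related grid point."""
    top = float(np.max(ll))
    return int(np.argmax(ll >= top - tol * (1.0 + abs(top))))


def ml_relatedness(
    g1, g2, freqs_per_locus: Mapping[str, LocusFrequencies]
) -> tuple[tuple[float, float, float], float]:
    """Maximum-likelihood IBD coefficients and r = k2 + k1/2 for one pair.

    A 0.01-step grid over the simplex is refined locally at 0.001 steps;
    the search is deterministic and boundary solutions are returned exactly.
    With a flat likelihood (e.g. all loci monomorphic) the tie-break yields
    k = (1, 0, 0), r = 0.
    """
    comp = _PairComponents(g1, g2, freqs_per_locus)
    ll = comp.loglik_grid(_COARSE_GRID)
    best = _COARSE_GRID[_first_argmax(ll)]
    # local 0.001-step refinement around the coarse optimum
    deltas = np.arange(-0.01, 0.0105, 0.001)
    cand = []
    for d0, d1 in itertools.product(deltas, deltas):
        k0, k1 = best[0] + d0, best[1] + d1
        k2 = 1.0 - k0 - k1
        if k0 >= -1e-12 and k1 >= -1e-12 and k2 >= -1e-12:
            cand.append((max(k0, 0.0), max(k1, 0.0), max(k2, 0.0)))
    K = np.array(cand)
    K = K / K.sum(axis=1, keepdims=True)
    r = K[:, 2] + K[:, 1] / 2.0
    order = np.lexsort((K[:, 2], r))
    K = K[order]
    ll = comp.loglik_grid(K)
    k_best = K[_first_argmax(ll)]
    # report boundary solutions exactly: snap round-off dust to 0
    k_best = np.where(k_best < 1e-12, 0.0, k_best)
    k_best = k_best / k_best.sum()
    k_hat = tuple(float(x) for x in k_best)
    return k_hat, float(k_hat[2] + k_hat[1] / 2.0)


def ml_relationship(
    g1,
    g2,
    freqs_per_locus: Mapping[str, LocusFrequencies],
    candidates: Sequence[RelationshipHypothesis] = CANONICAL,
) -> str:
    """Best-supported canonical hypothesis; ties prefer the less related one."""
    comp = _PairComponents(g1, g2, freqs_per_locus)
    best_label, best_ll = None, NEG_INF
    for h in candidates:
        ll = comp.loglik(h.k)
        if best_label is None or ll > best_ll + 1e-12:
            best_label, best_ll = h.label, ll
    return best_label


# ---------------------------------------------------------------------------
# Simulation confidence sets and LRTs
# ---------------------------------------------------------------------------

class ConfidenceSet(frozenset):
    """Subset of hypothesis labels not rejected at level alpha; carries the
    per-hypothesis simulation p-values as ``p_values``."""

    p_values: dict[str, float]

    def __new__(cls, members, p_values):
        obj = super().__new__(cls, members)
        obj.p_values = dict(p_values)
        return obj


def _sim_lambda(
    freqs: Mapping[str, LocusFrequencies],
    null: RelationshipHypothesis,
    candidates: Sequence[RelationshipHypothesis],
    alt: RelationshipHypothesis | None,
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate pairs under ``null`` and return their likelihood-ratio
    statistics: lnL(alt) - lnL(null), with alt = each pair's own best
    candidate when ``alt`` is None."""
    g1, g2 = simdata.simulate_pairs(freqs, null.k, n_sim, rng)
    loci = list(freqs)
    lls = {}
    hyps = set(candidates) | {null} | ({alt} if alt is not None else set())
    per_locus = []
    for j, l in enumerate(loci):
        f = freqs[l]
        idx = {a: i for i, a in enumerate(f.alleles)}
        per_locus.append(_s_components_batch(g1[:, j, :], g2[:, j, :], f.freq_array(), idx))
    for h in hyps:
        tot = np.zeros(n_sim)
        for s0, s1, s2 in per_locus:
            mix = h.k0 * s0 + h.k1 * s1 + h.k2 * s2
            with np.errstate(divide="ignore"):
                tot += np.where(mix > 0.0, np.log(np.where(mix > 0.0, mix, 1.0)), NEG_INF)
        lls[h.label] = tot
    ll_null = lls[null.label]
    if alt is None:
        ll_top = np.max(np.stack([lls[h.label] for h in candidates]), axis=0)
    else:
        ll_top = lls[alt.label]
    return ll_top - ll_null


def confidence_set(
    g1,
    g2,
    freqs_per_locus: Mapping[str, LocusFrequencies],
    n_sim: int = 100_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    candidates: Sequence[RelationshipHypothesis] = CANONICAL,
) -> ConfidenceSet:
    """Simulation confidence set of relationships for one pair.

    For each candidate R the observed statistic is lnL(best candidate) -
    lnL(R); ``n_sim`` pairs are simulated under R at the pair's jointly
    typed loci, each re-maximized over the candidates, and R stays in the
    set iff p_R = (#{lambda_sim >= lambda_obs} + 1)/(n_sim + 1) > alpha.
    The best-supported hypothesis is always a member.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = simdata._rng(seed)
    comp = _PairComponents(g1, g2, freqs_per_locus)
    sub_freqs = {l: freqs_per_locus[l] for l in comp.loci}
    lls_obs = {h.label: comp.loglik(h.k) for h in candidates}
    ll_top = max(lls_obs.values())
    members, pvals = [], {}
    for h in candidates:
        lam_obs = ll_top - lls_obs[h.label]  # +inf when lnL(R) = -inf
        lam_sim = _sim_lambda(sub_freqs, h, candidates, None, n_sim, rng)
        p = (int(np.sum(lam_sim >= lam_obs - 1e-12)) + 1) / (n_sim + 1)
        pvals[h.label] = p
        if p > alpha:
            members.append(h.label)
    return ConfidenceSet(members, pvals)


def lrt_specific(
    g1,
    g2,
    freqs_per_locus: Mapping[str, LocusFrequencies],
    null_r: str | RelationshipHypothesis,
    alt_r: str | RelationshipHypothesis,
    n_sim: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Simulation p-value of the likelihood-ratio test of ``null_r`` against
    ``alt_r``; a small p rejects the null in favor of the alternative."""
    null_h, alt_h = hypothesis(null_r), hypothesis(alt_r)
    if null_h.label == alt_h.label:
        raise ValueError("null and alternative hypotheses must differ")
    rng = simdata._rng(seed)
    comp = _PairComponents(g1, g2, freqs_per_locus)
    sub_freqs = {l: freqs_per_locus[l] for l in comp.loci}
    ll_null = comp.loglik(null_h.k)
    ll_alt = comp.loglik(alt_h.k)
    lam_obs = np.inf if ll_null == NEG_INF else ll_alt - ll_null
    lam_sim = _sim_lambda(sub_freqs, null_h, (null_h, alt_h), alt_h, n_sim, rng)
    return (int(np.sum(lam_sim >= lam_obs - 1e-12)) + 1) / (n_sim + 1)


# ---------------------------------------------------------------------------
# Pair inference and classification
# ---------------------------------------------------------------------------

RELATED, UNRELATED, AMBIGUOUS = "related", "unrelated", "ambiguous"


@dataclass
class PairInference:
    """Complete per-pair result of the relatedness analysis."""

    id1: str
    id2: str
    lnl: dict[str, float]
    k_hat: tuple[float, float, float]
    r_hat: float
    ml_relationship: str
    confidence_set: ConfidenceSet
    classification: str
    lrt_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)
    lrt_adjusted: dict[tuple[str, str], float] = field(default_factory=dict)
    final_classification: str | None = None

    @property
    def resolved(self) -> str:
        return self.final_classification or self.classification


def classify_pair(inference: PairInference) -> str:
    """Conservative rule: related only if U is outside the 95% set; unrelated
    only if the set is exactly {U}; ambiguous otherwise."""
    cs = inference.confidence_set
    if len(cs) == 0:
        raise RuntimeError("empty confidence set: the ML hypothesis must always belong")
    if "U" not in cs:
        return RELATED
    if set(cs) == {"U"}:
        return UNRELATED
    return AMBIGUOUS


def resolve_ambiguous(
    pair_inferences: Sequence[PairInference],
    alpha: float = 0.05,
    n_sim: int = 100_000,
    seed: int | np.random.Generator | None = None,
    freqs_per_locus: Mapping[str, LocusFrequencies] | None = None,
    genotypes: Mapping[str, np.ndarray] | None = None,
    bonferroni_scope: str = "run",
) -> list[PairInference]:
    """Bonferroni-corrected likelihood-ratio disambiguation.

    Every ambiguous pair's best hypothesis is tested against each alternative
    in its confidence set; the Bonferroni factor m is the total number of
    tests across all ambiguous pairs of the run (``bonferroni_scope="pair"``
    uses each pair's own test count instead).  An alternative is eliminated
    iff its adjusted p < alpha; the pair then becomes related if U is gone,
    unrelated if only U survives, and stays ambiguous otherwise.
    """
    if bonferroni_scope not in ("run", "pair"):
        raise ValueError("bonferroni_scope must be 'run' or 'pair'")
    rng = simdata._rng(seed)
    tests: list[tuple[PairInference, str, float]] = []
    for inf in pair_inferences:
        inf.final_classification = inf.classification
        if inf.classification != AMBIGUOUS:
            continue
        top = inf.ml_relationship
        for alt in sorted(set(inf.confidence_set) - {top}, key=lambda l: [h.label for h in CANONICAL].index(l)):
            g1, g2 = genotypes[inf.id1], genotypes[inf.id2]
            p = lrt_specific(g1, g2, freqs_per_locus, null_r=alt, alt_r=top, n_sim=n_sim, seed=rng)
            inf.lrt_pvalues[(alt, top)] = p
            tests.append((inf, alt, p))
    if not tests:
        return list(pair_inferences)
    if bonferroni_scope == "run":
        adj = bonferroni_adjust([t[2] for t in tests])
        for (inf, alt, _), pa in zip(tests, adj):
            inf.lrt_adjusted[(alt, inf.ml_relationship)] = float(pa)
    else:
        for inf in pair_inferences:
            m = len(inf.lrt_pvalues)
            for key, p in inf.lrt_pvalues.items():
                inf.lrt_adjusted[key] = min(1.0, p * m)
    for inf in pair_inferences:
        if inf.classification != AMBIGUOUS:
            continue
        eliminated = {alt for (alt, _), pa in inf.lrt_adjusted.items() if pa < alpha}
        survivors = set(inf.confidence_set) - eliminated
        if "U" not in survivors and survivors:
            inf.final_classification = RELATED
        elif survivors == {"U"}:
            inf.final_classification = UNRELATED
        else:
            inf.final_classification = AMBIGUOUS
    return list(pair_inferences)


def infer_pair(
    id1: str,
    id2: str,
    g1,
    g2,
    freqs_per_locus: Mapping[str, LocusFrequencies],
    n_sim: int = 100_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    candidates: Sequence[RelationshipHypothesis] = CANONICAL,
) -> PairInference:
    """Full single-pair inference: likelihoods, ML k and r, best hypothesis,
    confidence set and conservative classification."""
    comp = _PairComponents(g1, g2, freqs_per_locus)
    lnl = {h.label: comp.loglik(h.k) for h in candidates}
    k_hat, r_hat = ml_relatedness(g1, g2, freqs_per_locus)
    best = ml_relationship(g1, g2, freqs_per_locus, candidates)
    cs = confidence_set(
        g1, g2, freqs_per_locus, n_sim=n_sim, alpha=alpha, seed=seed, candidates=candidates
    )
    inf = PairInference(
        id1=id1,
        id2=id2,
        lnl=lnl,
        k_hat=k_hat,
        r_hat=r_hat,
        ml_relationship=best,
        confidence_set=cs,
        classification="",
    )
    inf.classification = classify_pair(inf)
    return inf


@dataclass
class KinshipConfig:
    """Settings for a full pairwise run."""

    n_sim: int = 100_000
    alpha: float = 0.05
    seed: int | None = None
    candidates: tuple[RelationshipHypothesis, ...] = CANONICAL
    resolve: bool = False
    #: Monte-Carlo depth of the disambiguation LRTs; the Bonferroni-corrected
    #: threshold alpha/m is unreachable unless n_sim well exceeds m/alpha.
    resolve_n_sim: int | None = None
    bonferroni_scope: str = "run"


@dataclass
class PairwiseResult:
    pairs: list[PairInference]
    r_matrix: pd.DataFrame

    def summary_counts(self, final: bool = True) -> pd.Series:
        labels = [p.resolved if final else p.classification for p in self.pairs]
        return pd.Series(labels).value_counts().reindex(
            [UNRELATED, RELATED, AMBIGUOUS], fill_value=0
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "id1": p.id1,
                    "id2": p.id2,
                    "r": round(p.r_hat, 4),
                    "R": p.ml_relationship,
                    "confidence_set": ",".join(
                        sorted(p.confidence_set, key=lambda l: [h.label for h in CANONICAL].index(l))
                    ),
                    "classification": p.classification,
                    "final": p.resolved,
                }
            )
        return pd.DataFrame(rows)


def pairwise_analysis(table: GenotypeTable, config: KinshipConfig | None = None) -> PairwiseResult:
    """Full relatedness analysis over every unordered pair of a table.

    Frequencies are estimated once from the complete table (including each
    focal pair).  Emits one PairInference per pair plus the symmetric r-hat
    matrix with a unit diagonal.
    """
    cfg = config or KinshipConfig()
    if table.n_individuals < 2:
        raise ValueError("pairwise analysis needs at least two individuals")
    freqs = all_frequencies(table)
    rng = np.random.default_rng(cfg.seed)
    ids = table.individual_ids
    rows = {i: table.row(i) for i in ids}
    pairs: list[PairInference] = []
    r_mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        inf = infer_pair(
            a, b, rows[a], rows[b], freqs,
            n_sim=cfg.n_sim, alpha=cfg.alpha, seed=rng, candidates=cfg.candidates,
        )
        pairs.append(inf)
        r_mat.loc[a, b] = r_mat.loc[b, a] = inf.r_hat
    if cfg.resolve:
        resolve_ambiguous(
            pairs,
            alpha=cfg.alpha,
            n_sim=cfg.resolve_n_sim or cfg.n_sim,
            seed=rng,
            freqs_per_locus=freqs,
            genotypes=rows,
            bonferroni_scope=cfg.bonferroni_scope,
        )
    return PairwiseResult(pairs=pairs, r_matrix=r_mat)
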