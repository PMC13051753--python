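"""Synthetic genotype generator mirroring the structure of a small captive
population: HWE founders with skewed multiallelic frequencies, Mendelian
pedigrees, genotype pairs drawn under specified IBD coefficients, and
missing-data injection.

All sampling is driven by an explicit seed (or a ``numpy.random.Generator``),
with no hidden global state.  ``simulate_pair``/``simulate_pairs`` is the
single pair-sampling engine: the kinship module's Monte-Carlo confidence sets
and likelihood-ratio tests draw from it, so the pair model simulated is
exactly the one the likelihood assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeTable, LocusFrequencies


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _locus_arrays(freqs_per_locus: Mapping[str, LocusFrequencies]):
    loci = list(freqs_per_locus)
    alleles = [np.asarray(freqs_per_locus[l].alleles, dtype=np.int64) for l in loci]
    probs = [freqs_per_locus[l].freq_array() for l in loci]
    return loci, alleles, probs


def simulate_founders(
    freqs_per_locus: Mapping[str, LocusFrequencies],
    n: int,
    seed: int | np.random.Generator | None = None,
    id_prefix: str = "F",
) -> GenotypeTable:
    """n unrelated individuals with both alleles drawn independently from the
    locus frequencies (Hardy-Weinberg sampling)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    loci, alleles, probs = _locus_arrays(freqs_per_locus)
    arr = np.empty((n, len(loci), 2), dtype=np.int64)
    for j, (al, p) in enumerate(zip(alleles, probs)):
        arr[:, j, :] = rng.choice(al, size=(n, 2), p=p)
    ids = [f"{id_prefix}{i + 1:02d}" for i in range(n)]
    return GenotypeTable(ids, loci, arr)


def simulate_offspring(
    parent1: np.ndarray,
    parent2: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Mendelian offspring of two parental rows (shape (n_loci, 2)): one
    uniformly chosen allele from each parent per locus; missing in either
    parent propagates to the offspring."""
    p1 = np.asarray(parent1, dtype=np.int64)
    p2 = np.asarray(parent2, dtype=np.int64)
    if p1.shape != p2.shape or p1.ndim != 2 or p1.shape[1] != 2:
        raise ValueError("parents must be (n_loci, 2) arrays over the same loci")
    rng = _rng(seed)
    L = p1.shape[0]
    pick1 = p1[np.arange(L), rng.integers(0, 2, size=L)]
    pick2 = p2[np.arange(L), rng.integers(0, 2, size=L)]
    off = np.sort(np.stack([pick1, pick2], axis=1), axis=1)
    missing = (p1[:, 0] == MISSING) | (p2[:, 0] == MISSING)
    off[missing] = MISSING
    return off


def simulate_pairs(
    freqs_per_locus: Mapping[str, LocusFrequencies],
    k: Sequence[float],
    n: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """n genotype pairs under IBD coefficients k = (k0, k1, k2).

    Per locus and pair, the number of alleles shared identical by descent is
    drawn from (k0, k1, k2); the first genotype is HWE; the second copies the
    IBD alleles (uniformly chosen from the first) and fills the rest from the
    frequencies.  Returns two arrays of shape (n, n_loci, 2); pairs are
    stored sorted within genotype.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (3,) or np.any(k < 0) or abs(k.sum() - 1.0) > 1e-9:
        raise ValueError("k must be three non-negative probabilities summing to 1")
    rng = _rng(seed)
    loci, alleles, probs = _locus_arrays(freqs_per_locus)
    L = len(loci)
    g1 = np.empty((n, L, 2), dtype=np.int64)
    g2 = np.empty((n, L, 2), dtype=np.int64)
    for j, (al, p) in enumerate(zip(alleles, probs)):
        a = rng.choice(al, size=(n, 2), p=p)
        b = rng.choice(al, size=(n, 2), p=p)  # start independent, overwrite IBD slots
        m = rng.choice(3, size=n, p=k)
        # one shared allele: a uniformly chosen allele of g1 replaces b's first slot
        one = m == 1
        if one.any():
            src = rng.integers(0, 2, size=one.sum())
            b[one, 0] = a[one, :][np.arange(one.sum()), src]
        two = m == 2
        if two.any():
            b[two] = a[two]
        g1[:, j, :] = np.sort(a, axis=1)
        g2[:, j, :] = np.sort(b, axis=1)
    return g1, g2


def simulate_pair(
    freqs_per_locus: Mapping[str, LocusFrequencies],
    k: Sequence[float],
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A single genotype pair under IBD coefficients k; see simulate_pairs."""
    g1, g2 = simulate_pairs(freqs_per_locus, k, 1, seed)
    return g1[0], g2[0]


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mating:
    parent_a: str
    parent_b: str
    offspring: tuple[str, ...]


@dataclass
class PedigreeSpec:
    """Founders plus a list of matings; offspring labels must be unique and
    may themselves appear as parents in later matings."""

    founders: list[str]
    matings: list[Mating] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = list(self.founders)
        if len(set(known)) != len(known):
            raise ValueError("duplicate founder labels")
        for m in self.matings:
            for p in (m.parent_a, m.parent_b):
                if p not in known:
                    raise ValueError(f"parent {p!r} not defined before mating")
            for o in m.offspring:
                if o in known:
                    raise ValueError(f"duplicate individual label {o!r}")
                known.append(o)
        self.individuals = known

    def parents_of(self) -> dict[str, tuple[str, str]]:
        out = {}
        for m in self.matings:
            for o in m.offspring:
                out[o] = (m.parent_a, m.parent_b)
        return out


def relationship_truth(spec: PedigreeSpec) -> dict[frozenset, str]:
    """Pairwise relationship labels implied by the pedigree.

    PO for parent-child, FS for same two parents, HS for exactly one shared
    parent; all other pairs (including the mutually unrelated founders) are
    labelled U.  More distant kin produced by multi-generation specs are also
    labelled U — the truth table covers the four canonical hypotheses only.
    """
    parents = spec.parents_of()
    truth: dict[frozenset, str] = {}
    inds = spec.individuals
    for i, a in enumerate(inds):
        for b in inds[i + 1:]:
            pa, pb = parents.get(a), parents.get(b)
            if pa is not None and b in pa or pb is not None and a in pb:
                label = "PO"
            elif pa is not None and pb is not None:
                shared = len(set(pa) & set(pb))
                label = "FS" if set(pa) == set(pb) else ("HS" if shared == 1 else "U")
            else:
                label = "U"
            truth[frozenset((a, b))] = label
    return truth


def simulate_pedigree(
    freqs_per_locus: Mapping[str, LocusFrequencies],
    spec: PedigreeSpec,
    seed: int | np.random.Generator | None = None,
) -> tuple[GenotypeTable, dict[frozenset, str]]:
    """Simulate every individual of a pedigree and return the genotype table
    with the per-pair true relationship labels."""
    rng = _rng(seed)
    loci = list(freqs_per_locus)
    founders = simulate_founders(freqs_per_locus, len(spec.founders), rng)
    rows: dict[str, np.ndarray] = {
        label: founders.alleles[i] for i, label in enumerate(spec.founders)
    }
    for m in spec.matings:
        for o in m.offspring:
            rows[o] = simulate_offspring(rows[m.parent_a], rows[m.parent_b], rng)
    arr = np.stack([rows[i] for i in spec.individuals])
    return GenotypeTable(spec.individuals, loci, arr), relationship_truth(spec)


# ---------------------------------------------------------------------------
# Frequency profiles and missingness
# ---------------------------------------------------------------------------

#: Allele counts of the ten-locus reference panel (2-8 alleles, mean 4.4).
PANEL_ALLELE_COUNTS = (2, 8, 5, 2, 8, 4, 4, 4, 3, 4)
_PANEL_LOCI = ("Hha01", "Hha02", "Hha03", "Hha04", "Hha05", "Hha06", "Hha08", "Hha09", "Hha12", "Hha18")
_PANEL_SIZES = (158, 192, 204, 125, 179, 121, 155, 198, 120, 150)
_PANEL_MOTIF_LEN = (2, 2, 2, 2, 3, 2, 2, 2, 2, 2)

#: Calibration band for the across-locus mean gene diversity of a profile.
MEAN_HE_BAND = (0.35, 0.55)
_DIRICHLET_ALPHA = 0.5


def table1_like_frequencies(
    seed: int | np.random.Generator | None = None,
) -> dict[str, LocusFrequencies]:
    """A ten-locus allele-frequency profile shaped like the reference panel.

    Allele counts per locus follow the panel (2-8, mean 4.4); frequencies are
    Dirichlet(0.5)-skewed, redrawn (deterministically under the seed) until
    the across-locus mean gene diversity 1 - sum p^2 lies in the calibration
    band [0.35, 0.55].  Allele labels are plausible fragment lengths: the
    locus's expected size stepped by its motif length.
    """
    rng = _rng(seed)
    lo, hi = MEAN_HE_BAND
    for _ in range(200):
        profile: dict[str, LocusFrequencies] = {}
        he = []
        for loc, k, size, step in zip(_PANEL_LOCI, PANEL_ALLELE_COUNTS, _PANEL_SIZES, _PANEL_MOTIF_LEN):
            p = rng.dirichlet(np.full(k, _DIRICHLET_ALPHA))
            # Dirichlet mass can collapse below representable frequency in a
            # small sample; floor at 0.5% and renormalize to keep k alleles real
            p = np.maximum(p, 0.005)
            p = p / p.sum()
            labels = tuple(size + step * i for i in range(k))
            profile[loc] = LocusFrequencies(loc, labels, tuple(p), 0)
            he.append(1.0 - float(np.sum(p * p)))
        if lo <= float(np.mean(he)) <= hi:
            return profile
    raise RuntimeError("failed to draw a frequency profile inside the calibration band")


def inject_missing(
    table: GenotypeTable,
    rate: float,
    seed: int | np.random.Generator | None = None,
) -> GenotypeTable:
    """Set each genotype to missing independently with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    rng = _rng(seed)
    arr = table.alleles.copy()
    mask = rng.random((table.n_individuals, table.n_loci)) < rate
    arr[mask] = MISSING
    return GenotypeTable(table.individual_ids, table.locus_names, arr)
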