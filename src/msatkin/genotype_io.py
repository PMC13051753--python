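"""Data model and I/O for multilocus codominant microsatellite genotypes.

The central container is :class:`GenotypeTable`: an individuals x loci matrix
of unordered diploid allele pairs, with ``0`` reserved as the missing-data
code (the GenAlEx convention).  Allele labels are opaque positive integers —
fragment lengths under the full-length encoding scheme, or arbitrary
categorical codes under the sequence-based schemes — and no stepwise-mutation
ordering is assumed anywhere downstream.
"""

from __future__ import annotations

import csv
import io
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

#: File and in-memory code for a missing genotype (both allele slots zero).
MISSING = 0

_VALID_BASES = frozenset("ACGT")


class GenotypeParseError(ValueError):
    """Malformed genotype file; message names the offending row/column."""


@dataclass(frozen=True)
class MarkerDefinition:
    """A microsatellite locus: repeat motif, primer pair, and PCR conditions."""

    name: str
    motif: str
    repeat_count: int
    primer_forward: str
    primer_reverse: str
    expected_size: int
    annealing_temp: float

    def __post_init__(self) -> None:
        for label, primer in (("forward", self.primer_forward), ("reverse", self.primer_reverse)):
            if not (18 <= len(primer) <= 27):
                raise ValueError(f"{self.name}: {label} primer length {len(primer)} outside 18-27")
            if not set(primer) <= _VALID_BASES:
                raise ValueError(f"{self.name}: {label} primer contains non-ACGT characters")
        if not (120 <= self.expected_size <= 300):
            raise ValueError(f"{self.name}: expected size {self.expected_size} outside 120-300 bp")
        if not (57 <= self.annealing_temp <= 63):
            raise ValueError(f"{self.name}: annealing temperature {self.annealing_temp} outside 57-63 C")


@dataclass(frozen=True)
class LocusFrequencies:
    """Sample allele relative frequencies at one locus.

    ``freqs[i]`` is the relative frequency of ``alleles[i]`` estimated as
    allele count / (2 * n_genotyped) over non-missing individuals.
    """

    locus_name: str
    alleles: tuple[int, ...]
    freqs: tuple[float, ...]
    n_genotyped: int

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.freqs) or len(self.alleles) < 1:
            raise ValueError(f"{self.locus_name}: alleles/freqs mismatch or empty")
        arr = np.asarray(self.freqs, dtype=float)
        if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.locus_name}: frequencies must be non-negative and sum to 1")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.alleles, self.freqs))

    def freq_array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)


class GenotypeTable:
    """Individuals x loci matrix of unordered diploid allele pairs.

    Parameters
    ----------
    individual_ids, locus_names:
        Ordered unique labels.
    alleles:
        Integer array of shape ``(n_individuals, n_loci, 2)``.  A genotype is
        missing iff both entries are :data:`MISSING` (0); a half-filled pair
        is rejected.  Pairs are stored sorted, so ``(a, b)`` and ``(b, a)``
        construct equal tables.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        locus_names: Sequence[str],
        alleles: np.ndarray,
    ) -> None:
        ids = list(individual_ids)
        loci = list(locus_names)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus names")
        arr = np.asarray(alleles, dtype=np.int64)
        if arr.shape != (len(ids), len(loci), 2):
            raise ValueError(f"allele array shape {arr.shape} != ({len(ids)}, {len(loci)}, 2)")
        if np.any(arr < 0):
            raise ValueError("allele labels must be positive (0 = missing)")
        half = (arr == MISSING).sum(axis=2) == 1
        if np.any(half):
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for individual {ids[i]!r} at locus {loci[j]!r}: "
                "a genotype has two alleles or is fully missing"
            )
        self.individual_ids = ids
        self.locus_names = loci
        self.alleles = np.sort(arr, axis=2)
        self.alleles.setflags(write=False)

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.alleles, other.alleles)
        )

    def __repr__(self) -> str:
        return f"GenotypeTable({self.n_individuals} individuals x {self.n_loci} loci)"

    # -- access ----------------------------------------------------------
    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def individual_index(self, individual: str) -> int:
        try:
            return self.individual_ids.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def genotype(self, individual: str, locus: str) -> tuple[int, int] | None:
        """Return the unordered allele pair, or None if missing."""
        g = self.alleles[self.individual_index(individual), self.locus_index(locus)]
        if g[0] == MISSING:
            return None
        return int(g[0]), int(g[1])

    def row(self, individual: str) -> np.ndarray:
        """Allele pairs of one individual, shape (n_loci, 2)."""
        return self.alleles[self.individual_index(individual)]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing genotypes."""
        return self.alleles[:, :, 0] == MISSING

    def missing_fraction_per_locus(self) -> pd.Series:
        return pd.Series(self.missing_mask().mean(axis=0), index=self.locus_names)

    def missing_fraction_per_individual(self) -> pd.Series:
        return pd.Series(self.missing_mask().mean(axis=1), index=self.individual_ids)

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        inds = self.individual_ids if individuals is None else list(individuals)
        locs = self.locus_names if loci is None else list(loci)
        ii = [self.individual_index(i) for i in inds]
        jj = [self.locus_index(l) for l in locs]
        return GenotypeTable(inds, locs, self.alleles[np.ix_(ii, jj)])


# ---------------------------------------------------------------------------
# Packaged marker panel (ten retained loci with their published statistics)
# ---------------------------------------------------------------------------

def _panel_frame() -> pd.DataFrame:
    with resources.files("msatkin.data").joinpath("harpy_panel.csv").open() as fh:
        return pd.read_csv(fh)


def load_panel() -> list[MarkerDefinition]:
    """The ten retained harpy eagle loci (motif, primers, size, annealing T)."""
    df = _panel_frame()
    return [
        MarkerDefinition(
            name=r.locus,
            motif=r.motif,
            repeat_count=int(r.repeat_count),
            primer_forward=r.primer_forward,
            primer_reverse=r.primer_reverse,
            expected_size=int(r.expected_size),
            annealing_temp=float(r.annealing_temp),
        )
        for r in df.itertuples()
    ]


def load_panel_statistics() -> pd.DataFrame:
    """Published per-locus summary statistics for the packaged panel.

    Columns: n, n_alleles, ho, he, p_hwe, q_exclusion, i_identity; indexed by
    locus name.  These are the printed reference values that joint panel-power
    summaries are recomputed from.
    """
    return _panel_frame().set_index("locus")[
        ["n", "n_alleles", "ho", "he", "p_hwe", "q_exclusion", "i_identity"]
    ]


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

NATIVE = "native"
GENALEX = "genalex"


def _parse_allele(tok: str, row: int, col: str) -> int:
    tok = tok.strip()
    try:
        val = int(tok)
    except ValueError:
        raise GenotypeParseError(f"row {row}, column {col!r}: allele {tok!r} is not an integer") from None
    if val < 0:
        raise GenotypeParseError(f"row {row}, column {col!r}: negative allele label {val}")
    return val


def _read_native(lines: list[list[str]]) -> GenotypeTable:
    if not lines:
        raise GenotypeParseError("empty file")
    header = [h.strip() for h in lines[0]]
    if header[:1] != ["individual"]:
        raise GenotypeParseError("native header must start with 'individual'")
    allele_cols = header[1:]
    if len(allele_cols) % 2:
        raise GenotypeParseError("odd number of allele columns in header")
    loci = []
    for k in range(0, len(allele_cols), 2):
        a, b = allele_cols[k], allele_cols[k + 1]
        if not (a.endswith("_1") and b.endswith("_2") and a[:-2] == b[:-2]):
            raise GenotypeParseError(f"header columns {a!r}/{b!r} are not a <locus>_1/<locus>_2 pair")
        loci.append(a[:-2])
    ids: list[str] = []
    rows = []
    for rno, row in enumerate(lines[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise GenotypeParseError(f"row {rno}: expected {len(header)} fields, got {len(row)}")
        ident = row[0].strip()
        if ident in ids:
            raise GenotypeParseError(f"row {rno}: duplicate individual id {ident!r}")
        ids.append(ident)
        rows.append(
            [_parse_allele(tok, rno, header[1 + k]) for k, tok in enumerate(row[1:])]
        )
    arr = np.asarray(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    try:
        return GenotypeTable(ids, loci, arr)
    except ValueError as exc:
        raise GenotypeParseError(str(exc)) from None


def _read_genalex(lines: list[list[str]]) -> GenotypeTable:
    # two header rows: "<n_loci>,<n_individuals>" then "individual,<locus>,,<locus>,,..."
    if len(lines) < 2:
        raise GenotypeParseError("GenAlEx-style file needs two header rows")
    counts = [c for c in lines[0] if c.strip()]
    try:
        n_loci, n_ind = int(counts[0]), int(counts[1])
    except (IndexError, ValueError):
        raise GenotypeParseError("first GenAlEx header row must give locus and individual counts") from None
    names_row = lines[1]
    loci = [c.strip() for c in names_row[1::2] if c.strip()]
    if len(loci) != n_loci:
        raise GenotypeParseError(f"header declares {n_loci} loci but names {len(loci)}")
    ids: list[str] = []
    rows = []
    for rno, row in enumerate(lines[2:], start=3):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 1 + 2 * n_loci:
            raise GenotypeParseError(f"row {rno}: expected {1 + 2 * n_loci} fields, got {len(row)}")
        ident = row[0].strip()
        if ident in ids:
            raise GenotypeParseError(f"row {rno}: duplicate individual id {ident!r}")
        ids.append(ident)
        rows.append([_parse_allele(tok, rno, f"allele{k + 1}") for k, tok in enumerate(row[1 : 1 + 2 * n_loci])])
    if len(ids) != n_ind:
        raise GenotypeParseError(f"header declares {n_ind} individuals but file has {len(ids)}")
    arr = np.asarray(rows, dtype=np.int64).reshape(len(ids), n_loci, 2)
    try:
        return GenotypeTable(ids, loci, arr)
    except ValueError as exc:
        raise GenotypeParseError(str(exc)) from None


def read_genotypes(path: str | Path, format: str = NATIVE) -> GenotypeTable:
    """Read a genotype table from a native or GenAlEx-style CSV file."""
    with open(path, newline="") as fh:
        lines = list(csv.reader(fh))
    if format == NATIVE:
        return _read_native(lines)
    if format == GENALEX:
        return _read_genalex(lines)
    raise GenotypeParseError(f"unknown format {format!r} (expected {NATIVE!r} or {GENALEX!r})")


def write_genotypes(table: GenotypeTable, path: str | Path, format: str = NATIVE) -> None:
    """Write a genotype table; missing genotypes become a 0,0 pair."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    if format == NATIVE:
        header = ["individual"]
        for loc in table.locus_names:
            header += [f"{loc}_1", f"{loc}_2"]
        w.writerow(header)
        for i, ident in enumerate(table.individual_ids):
            w.writerow([ident] + [int(a) for a in table.alleles[i].ravel()])
    elif format == GENALEX:
        w.writerow([table.n_loci, table.n_individuals])
        names = ["individual"]
        for loc in table.locus_names:
            names += [loc, ""]
        w.writerow(names)
        for i, ident in enumerate(table.individual_ids):
            w.writerow([ident] + [int(a) for a in table.alleles[i].ravel()])
    else:
        raise GenotypeParseError(f"unknown format {format!r} (expected {NATIVE!r} or {GENALEX!r})")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Allele-encoding schemes over annotated allele sequences
# ---------------------------------------------------------------------------

FULL_LENGTH = "FullLength"
REPEAT_FOCUSED = "RepeatFocused"
SSRS = "SSRs"
CAT = "CAT"
SCHEMES = (FULL_LENGTH, REPEAT_FOCUSED, SSRS, CAT)


@dataclass(frozen=True)
class AlleleSequence:
    """One sequenced allele with its annotated repeat intervals.

    ``target_repeat`` is the (start, end) of the target microsatellite in
    0-based half-open coordinates; ``other_repeats`` lists any additional
    annotated repeat intervals.
    """

    sequence: str
    target_repeat: tuple[int, int]
    other_repeats: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        s, e = self.target_repeat
        if not (0 <= s < e <= len(self.sequence)):
            raise ValueError(f"target repeat interval ({s}, {e}) outside sequence of length {len(self.sequence)}")


def encode_alleles(
    allele_sequences: Mapping[tuple[str, str], Sequence[AlleleSequence]],
    scheme: str,
) -> GenotypeTable:
    """Build a genotype table from allele sequences under one encoding scheme.

    FullLength labels by total sequence length; RepeatFocused by the target
    repeat length; SSRs by the tuple of all annotated repeat lengths (one
    categorical code per distinct tuple, first-appearance order per locus);
    CAT by the full sequence string (repeats, SNPs and indels all distinguish
    alleles), again coded categorically per locus.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    ids: list[str] = []
    loci: list[str] = []
    for ind, loc in allele_sequences:
        if ind not in ids:
            ids.append(ind)
        if loc not in loci:
            loci.append(loc)

    def key(seq: AlleleSequence):
        if scheme == FULL_LENGTH:
            return len(seq.sequence)
        if scheme == REPEAT_FOCUSED:
            return seq.target_repeat[1] - seq.target_repeat[0]
        if scheme == SSRS:
            return tuple(
                e - s for s, e in (seq.target_repeat, *seq.other_repeats)
            )
        return seq.sequence

    arr = np.zeros((len(ids), len(loci), 2), dtype=np.int64)
    for j, loc in enumerate(loci):
        codes: dict[object, int] = {}
        for i, ind in enumerate(ids):
            seqs = allele_sequences.get((ind, loc))
            if not seqs:
                continue
            if len(seqs) == 1:
                seqs = (seqs[0], seqs[0])
            elif len(seqs) != 2:
                raise ValueError(f"({ind}, {loc}): expected one or two allele sequences, got {len(seqs)}")
            labels = []
            for seq in seqs:
                k = key(seq)
                if scheme in (FULL_LENGTH, REPEAT_FOCUSED):
                    labels.append(int(k))
                else:
                    labels.append(codes.setdefault(k, len(codes) + 1))
            arr[i, j] = sorted(labels)
    return GenotypeTable(ids, loci, arr)


def read_allele_sequences(
    fasta_path: str | Path, annotations_path: str | Path
) -> dict[tuple[str, str], list[AlleleSequence]]:
    """Load allele sequences from FASTA plus a repeat-annotation sidecar TSV.

    FASTA record ids are ``<individual>|<locus>|<1|2>``.  The sidecar has
    columns ``record  start  end  motif`` (0-based half-open); the first
    interval listed for a record is its target repeat, any further intervals
    are other annotated repeats.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(annotations_path) as fh:
        for lno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenotypeParseError(f"annotation line {lno}: expected record<TAB>start<TAB>end[<TAB>motif]")
            rec, s, e = parts[0], int(parts[1]), int(parts[2])
            intervals.setdefault(rec, []).append((s, e))
    out: dict[tuple[str, str], list[AlleleSequence]] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise GenotypeParseError(f"FASTA id {record.id!r} is not <individual>|<locus>|<1|2>")
        ind, loc, _ = parts
        ivals = intervals.get(record.id)
        if not ivals:
            raise GenotypeParseError(f"record {record.id!r} has no target-repeat annotation")
        out.setdefault((ind, loc), []).append(
            AlleleSequence(str(record.seq), ivals[0], tuple(ivals[1:]))
        )
    return out


# ---------------------------------------------------------------------------
# Missing-data filtering and allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Loci and individuals removed by the missing-data filter, with their
    missing fractions at removal time."""

    removed_loci: list[tuple[str, float]] = field(default_factory=list)
    removed_individuals: list[tuple[str, float]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.removed_loci and not self.removed_individuals


def filter_missing(
    table: GenotypeTable,
    max_missing: float = 0.10,
    drop_loci_first: bool = True,
) -> tuple[GenotypeTable, FilterReport]:
    """Drop loci then individuals whose missing fraction exceeds ``max_missing``.

    Loci are filtered first and individual missingness is recomputed on the
    retained loci, so an individual is only dropped for data missing at loci
    that survive.
    """
    if not (0 <= max_missing < 1):
        raise ValueError(f"max_missing must be in [0, 1), got {max_missing}")
    report = FilterReport()

    def drop_loci(t: GenotypeTable) -> GenotypeTable:
        frac = t.missing_fraction_per_locus()
        bad = frac[frac > max_missing]
        report.removed_loci.extend(bad.items())
        if len(bad) == t.n_loci:
            raise ValueError("all loci exceed the missing-data threshold")
        return t.subset(loci=[l for l in t.locus_names if l not in bad.index])

    def drop_inds(t: GenotypeTable) -> GenotypeTable:
        frac = t.missing_fraction_per_individual()
        bad = frac[frac > max_missing]
        report.removed_individuals.extend(bad.items())
        if len(bad) == t.n_individuals:
            raise ValueError("all individuals exceed the missing-data threshold")
        return t.subset(individuals=[i for i in t.individual_ids if i not in bad.index])

    if drop_loci_first:
        return drop_inds(drop_loci(table)), report
    return drop_loci(drop_inds(table)), report


def allele_frequencies(table: GenotypeTable, locus: str) -> LocusFrequencies:
    """Sample-proportion allele frequencies at one locus (missing excluded)."""
    j = table.locus_index(locus)
    col = table.alleles[:, j, :]
    typed = col[col[:, 0] != MISSING]
    if typed.size == 0:
        raise ValueError(f"locus {locus!r} is entirely missing")
    labels, counts = np.unique(typed.ravel(), return_counts=True)
    total = counts.sum()
    return LocusFrequencies(
        locus_name=locus,
        alleles=tuple(int(a) for a in labels),
        freqs=tuple(float(c) / total for c in counts),
        n_genotyped=len(typed),
    )


def all_frequencies(table: GenotypeTable) -> dict[str, LocusFrequencies]:
    """Allele frequencies for every locus of the table."""
    return {loc: allele_frequencies(table, loc) for loc in table.locus_names}
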