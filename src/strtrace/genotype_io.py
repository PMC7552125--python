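"""Genotype containers and I/O for diploid STR data.

The central container is :class:`GenotypeMatrix`: individuals x loci diploid
allele calls, with a population label per individual.  Allele labels are
integers (fragment lengths in base pairs, as produced by capillary
electrophoresis binning); a missing genotype is stored as ``(-1, -1)``.

Two interchange formats are supported: the GenePop dialect used by most
population-genetics software, and a plain delimited table with two columns
per locus.  The module also ships, as a packaged fixture, the published
per-locus forensic summary for the Pirenaica cattle reference sample
(n = 114, 30 ISAG-FAO microsatellites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Locus",
    "GenotypeMatrix",
    "AlleleFrequencySpectrum",
    "LocusForensicSummary",
    "read_genepop",
    "write_genepop",
    "read_table",
    "write_table",
    "allele_frequencies",
    "load_pirenaica_table1",
]

logger = logging.getLogger(__name__)

#: sentinel allele value marking a missing call
MISSING = -1


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker and its observed allele labels (bp sizes)."""

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate allele labels at locus {self.name}")
        if any(a <= 0 for a in self.alleles):
            raise ValueError(f"allele labels must be positive at locus {self.name}")


class GenotypeMatrix:
    """Diploid multi-locus genotypes for a set of labelled individuals.

    Parameters
    ----------
    ids, pops:
        Individual identifiers and their population labels (whitespace is
        stripped; labels are case-sensitive).
    loci:
        Locus names, one per column.
    alleles:
        Integer array of shape ``(n_individuals, n_loci, 2)``; a missing
        genotype has both entries equal to :data:`MISSING`.
    """

    def __init__(
        self,
        ids: Sequence[str],
        pops: Sequence[str],
        loci: Sequence[str],
        alleles: np.ndarray,
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.int32)
        if alleles.ndim != 3 or alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if alleles.shape[0] != len(ids) or alleles.shape[1] != len(loci):
            raise ValueError("alleles shape inconsistent with ids/loci")
        if len(ids) != len(pops):
            raise ValueError("ids and pops must have equal length")
        if len(ids) == 0 or len(loci) == 0:
            raise ValueError("need at least one individual and one locus")
        pops = [str(p).strip() for p in pops]
        if any(not p for p in pops):
            raise ValueError("population labels must be non-empty")
        half_missing = (alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("genotypes must have both alleles present or be missing")
        self.ids = list(map(str, ids))
        self.pops = pops
        self.loci = list(map(str, loci))
        self.alleles = alleles

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.pops, dtype=object) == population)
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def genotype(self, individual: int, locus: str | int) -> tuple[int, int] | None:
        j = locus if isinstance(locus, int) else self.locus_index(locus)
        a, b = self.alleles[individual, j]
        if a == MISSING:
            return None
        return (int(min(a, b)), int(max(a, b)))

    def locus(self, name: str) -> Locus:
        j = self.locus_index(name)
        vals = self.alleles[:, j, :].ravel()
        obs = np.unique(vals[vals != MISSING])
        return Locus(name, tuple(int(a) for a in obs))

    def subset(
        self,
        individuals: Iterable[int] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(list(individuals))
        cols = (
            np.arange(self.n_loci)
            if loci is None
            else np.asarray([self.locus_index(l) for l in loci])
        )
        return GenotypeMatrix(
            [self.ids[i] for i in rows],
            [self.pops[i] for i in rows],
            [self.loci[j] for j in cols],
            self.alleles[np.ix_(rows, cols)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if (self.ids, self.pops, self.loci) != (other.ids, other.pops, other.loci):
            return False
        a = np.sort(self.alleles, axis=2)
        b = np.sort(other.alleles, axis=2)
        return bool(np.array_equal(a, b))

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x {self.n_loci} loci, "
            f"{len(self.populations())} populations)"
        )


@dataclass
class AlleleFrequencySpectrum:
    """Per-locus allele relative frequencies with the sample sizes behind them.

    ``counts`` holds the raw allele-copy counts the frequencies were derived
    from (needed by Bayesian assignment scores); ``n`` is the number of
    diploid individuals with a non-missing call at each locus.
    """

    loci: list[str]
    freqs: dict[str, dict[int, float]]
    n: dict[str, int]
    counts: dict[str, dict[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.loci:
            f = self.freqs[name]
            if not f:
                raise ValueError(f"empty spectrum at locus {name}")
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {name} sum to {total}, not 1")
            if any(v <= 0 or v > 1 for v in f.values()):
                raise ValueError(f"frequencies at {name} outside (0, 1]")
            if self.n[name] < 1:
                raise ValueError(f"sample size at {name} must be >= 1")

    def __getitem__(self, locus: str) -> dict[int, float]:
        return self.freqs[locus]


@dataclass(frozen=True)
class LocusForensicSummary:
    """One row of a per-locus forensic report: diversity plus exclusion power.

    All statistics are probabilities in [0, 1]; ``hw_significant`` flags a
    Hardy-Weinberg departure after multiple-test correction.
    """

    locus: str
    k: int
    Ho: float
    He: float
    PIC: float
    MP: float
    PE1P: float
    PE2P: float
    PESI: float
    hw_significant: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("Ho", "He", "PIC", "MP", "PE1P", "PE2P", "PESI"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if (self.He == 0.0) != (self.k == 1):
            raise ValueError("He must be 0 exactly for monomorphic loci")


# ---------------------------------------------------------------------------
# GenePop format


def _detect_code_width(tokens: list[str]) -> int:
    widths = {len(t) for t in tokens if t}
    if widths <= {4}:
        return 2
    if widths <= {6}:
        return 3
    raise ValueError(
        f"cannot detect GenePop allele-code width from token lengths {sorted(widths)}"
    )


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a GenePop file (2- or 3-digit allele codes, auto-detected).

    Population labels are taken from the identifier of the first individual
    in each ``Pop`` block.  The code ``000000`` (or ``0000``) denotes a
    missing genotype.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("GenePop file too short")
    # line 0 is a free-text title
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names: one per line, or comma separated
        loci.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if not loci:
        raise ValueError("no locus names found before first 'Pop'")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[str]] = []
    pop_first_id: str | None = None
    pop_no = 0
    block_rows: list[tuple[str, list[str]]] = []

    def flush_block() -> None:
        nonlocal pop_first_id, block_rows
        if not block_rows:
            return
        label = pop_first_id if pop_first_id else f"pop{pop_no}"
        for ind_id, toks in block_rows:
            ids.append(ind_id)
            pops.append(label)
            rows.append(toks)
        block_rows = []

    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            flush_block()
            pop_no += 1
            pop_first_id = None
            continue
        if "," not in line:
            raise ValueError(f"line {lineno + 1}: expected 'id , genotypes'")
        ind_id, rest = line.split(",", 1)
        ind_id = ind_id.strip()
        toks = rest.split()
        if len(toks) != len(loci):
            raise ValueError(
                f"line {lineno + 1}: {len(toks)} genotype fields for {len(loci)} loci"
            )
        if pop_first_id is None:
            pop_first_id = ind_id
        block_rows.append((ind_id, toks))
    flush_block()
    if not ids:
        raise ValueError("no individuals found")

    width = _detect_code_width([t for r in rows for t in r])
    alleles = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int32)
    for r, toks in enumerate(rows):
        for c, tok in enumerate(toks):
            if len(tok) != 2 * width:
                raise ValueError(
                    f"individual {ids[r]!r}, locus {loci[c]}: bad code {tok!r}"
                )
            a, b = int(tok[:width]), int(tok[width:])
            if a == 0 or b == 0:
                continue  # missing stays (-1, -1)
            alleles[r, c] = (a, b)
    return GenotypeMatrix(ids, pops, loci, alleles)


def write_genepop(matrix: GenotypeMatrix, path: str | Path, title: str = "strtrace export") -> None:
    """Write a GenePop file with 3-digit allele codes."""
    if int(matrix.alleles.max(initial=0)) > 999:
        raise ValueError("allele labels exceed 999; GenePop 3-digit codes overflow")
    out = [title]
    out.extend(matrix.loci)
    for pop in matrix.populations():
        out.append("Pop")
        for i in matrix.pop_indices(pop):
            toks = []
            for j in range(matrix.n_loci):
                a, b = matrix.alleles[i, j]
                if a == MISSING:
                    toks.append("000000")
                else:
                    toks.append(f"{a:03d}{b:03d}")
            out.append(f"{matrix.ids[i]} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Delimited table format


def read_table(path: str | Path, dialect: str = "pair_columns", sep: str = ",") -> GenotypeMatrix:
    """Read a delimited genotype table.

    ``pair_columns``: header ``ID,Pop,LOC_1,LOC_2,...`` with one column per
    allele.  ``slash``: one column per locus holding ``a/b`` cells.  Empty
    cells are missing genotypes.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["ID", "Pop"]:
        raise ValueError("table must start with columns ID,Pop")
    bad = df.index[df.isna().all(axis=1)]
    df = df.drop(index=bad)
    if dialect == "pair_columns":
        cols = list(df.columns[2:])
        if len(cols) % 2:
            raise ValueError("odd number of allele columns")
        loci = []
        for c1, c2 in zip(cols[::2], cols[1::2]):
            base1 = c1.rsplit("_", 1)[0]
            base2 = c2.rsplit("_", 1)[0]
            if base1 != base2:
                raise ValueError(f"allele columns {c1!r}/{c2!r} do not pair")
            loci.append(base1)
        alleles = np.full((len(df), len(loci), 2), MISSING, dtype=np.int32)
        for r, (_, row) in enumerate(df.iterrows()):
            for j in range(len(loci)):
                v1, v2 = row.iloc[2 + 2 * j], row.iloc[3 + 2 * j]
                miss1, miss2 = pd.isna(v1) or v1 == "", pd.isna(v2) or v2 == ""
                if miss1 != miss2:
                    raise ValueError(f"row {row['ID']!r}: half-missing genotype at {loci[j]}")
                if not miss1:
                    try:
                        alleles[r, j] = (int(v1), int(v2))
                    except ValueError:
                        raise ValueError(
                            f"row {row['ID']!r}: non-integer allele at {loci[j]}"
                        ) from None
    elif dialect == "slash":
        loci = list(df.columns[2:])
        alleles = np.full((len(df), len(loci), 2), MISSING, dtype=np.int32)
        for r, (_, row) in enumerate(df.iterrows()):
            for j, loc in enumerate(loci):
                v = row[loc]
                if pd.isna(v) or v == "":
                    continue
                parts = str(v).split("/")
                if len(parts) != 2:
                    raise ValueError(f"row {row['ID']!r}: malformed cell {v!r} at {loc}")
                alleles[r, j] = (int(parts[0]), int(parts[1]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return GenotypeMatrix(list(df["ID"]), list(df["Pop"]), loci, alleles)


def write_table(
    matrix: GenotypeMatrix, path: str | Path, dialect: str = "pair_columns", sep: str = ","
) -> None:
    """Write a genotype table; lossless round trip with :func:`read_table`."""
    data: dict[str, list] = {"ID": matrix.ids, "Pop": matrix.pops}
    if dialect == "pair_columns":
        for j, loc in enumerate(matrix.loci):
            col_a, col_b = [], []
            for i in range(matrix.n_individuals):
                a, b = matrix.alleles[i, j]
                col_a.append("" if a == MISSING else str(int(a)))
                col_b.append("" if a == MISSING else str(int(b)))
            data[f"{loc}_1"] = col_a
            data[f"{loc}_2"] = col_b
    elif dialect == "slash":
        for j, loc in enumerate(matrix.loci):
            col = []
            for i in range(matrix.n_individuals):
                a, b = matrix.alleles[i, j]
                col.append("" if a == MISSING else f"{int(a)}/{int(b)}")
            data[loc] = col
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Allele frequencies


def allele_frequencies(
    matrix: GenotypeMatrix, population: str | None = None
) -> AlleleFrequencySpectrum:
    """Empirical allele frequencies, optionally restricted to one population.

    Frequency = allele-copy count / (2 x individuals with a non-missing call
    at that locus).  Loci with no data in the selection are dropped with a
    warning.
    """
    rows = (
        np.arange(matrix.n_individuals)
        if population is None
        else matrix.pop_indices(population)
    )
    loci: list[str] = []
    freqs: dict[str, dict[int, float]] = {}
    counts: dict[str, dict[int, int]] = {}
    ns: dict[str, int] = {}
    for j, name in enumerate(matrix.loci):
        calls = matrix.alleles[rows, j, :]
        ok = calls[:, 0] != MISSING
        n = int(ok.sum())
        if n == 0:
            logger.warning("locus %s has no calls in selection; excluded", name)
            continue
        vals, cnt = np.unique(calls[ok].ravel(), return_counts=True)
        loci.append(name)
        counts[name] = {int(v): int(c) for v, c in zip(vals, cnt)}
        freqs[name] = {int(v): float(c) / (2 * n) for v, c in zip(vals, cnt)}
        ns[name] = n
    if not loci:
        raise ValueError("every locus is entirely missing in the selection")
    return AlleleFrequencySpectrum(loci, freqs, ns, counts)


# ---------------------------------------------------------------------------
# Packaged reference summary


def load_pirenaica_table1() -> list[LocusForensicSummary]:
    """Published per-locus forensic summary of the Pirenaica reference sample.

    Thirty ISAG-FAO microsatellites typed in 114 purebred Pirenaica cattle;
    columns are allele count k, observed/expected heterozygosity, PIC,
    matching probability and the three exclusion powers, plus the
    Hardy-Weinberg departure flag (significant only at INRA037 after
    Bonferroni correction).
    """
    with resources.files("strtrace.data").joinpath("pirenaica_table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        LocusForensicSummary(
            locus=row.marker,
            k=int(row.k),
            Ho=row.Ho,
            He=row.He,
            PIC=row.PIC,
            MP=row.MP,
            PE1P=row.PE1P,
            PE2P=row.PE2P,
            PESI=row.PESI,
            hw_significant=bool(row.hw_significant),
        )
        for row in df.itertuples()
    ]
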