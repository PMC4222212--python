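"""Genotype containers and text I/O for diploid biallelic SNP panels.

The central container is :class:`GenotypeMatrix`: individuals x loci counts of
an arbitrarily chosen reference allele ("A") in {0, 1, 2}, with ``MISSING = -1``
for no-calls, plus a population label per individual.  Encoding genotypes as a
single A-allele dosage makes both the admixture likelihood and gamete sampling
binomial in one number.

Two text formats are supported:

* a STRUCTURE-style format — one row per individual by default (a two-row
  dialect can be read), columns ``id population a_1,1 a_1,2 ... a_L,1 a_L,2``,
  missing alleles coded ``-9``;
* a CSV dosage matrix — header ``id,population,<locus ids...>``, cells are
  dosages with ``NA`` for missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AlleleFrequencies",
    "StructureDialect",
    "read_structure_file",
    "write_structure_file",
    "read_csv_file",
    "write_csv_file",
    "allele_frequencies",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the expected layout."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a set of labeled individuals.

    Parameters
    ----------
    individual_ids : sequence of str
        Unique identifier per individual (rows).
    population_labels : sequence of str
        One population label per individual.
    locus_ids : sequence of str
        Unique identifier per locus (columns).
    genotypes : ndarray of shape (n_individuals, n_loci)
        A-allele dosage in {0, 1, 2}, or ``MISSING`` (-1).
    """

    individual_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.population_labels = [str(p) for p in self.population_labels]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        n, L = self.genotypes.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} genotype rows"
            )
        if len(self.population_labels) != n:
            raise ValueError("one population label per individual required")
        if len(self.locus_ids) != L:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {L} genotype columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus ids must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype value {self.genotypes[i, j]} at "
                f"individual {self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        return list(dict.fromkeys(self.population_labels))

    def population_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.population_labels) == label)
        if idx.size == 0:
            raise KeyError(f"population {label!r} not present")
        return idx

    def select_individuals(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in indices],
            [self.population_labels[i] for i in indices],
            list(self.locus_ids),
            self.genotypes[indices],
        )

    def select_populations(self, labels: Iterable[str]) -> "GenotypeMatrix":
        labels = list(labels)
        missing = [l for l in labels if l not in set(self.population_labels)]
        if missing:
            raise KeyError(f"populations not present: {missing}")
        mask = np.isin(np.asarray(self.population_labels), labels)
        return self.select_individuals(np.flatnonzero(mask))

    @staticmethod
    def concat(matrices: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack individuals from matrices sharing the same locus set."""
        if not matrices:
            raise ValueError("nothing to concatenate")
        loci = matrices[0].locus_ids
        for m in matrices[1:]:
            if m.locus_ids != loci:
                raise ValueError("locus sets differ between matrices")
        return GenotypeMatrix(
            [i for m in matrices for i in m.individual_ids],
            [p for m in matrices for p in m.population_labels],
            list(loci),
            np.vstack([m.genotypes for m in matrices]),
        )

    def relabel(self, label: str) -> "GenotypeMatrix":
        """Copy with every individual assigned population ``label``."""
        return GenotypeMatrix(
            list(self.individual_ids),
            [label] * self.n_individuals,
            list(self.locus_ids),
            self.genotypes.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes.astype(float), columns=self.locus_ids)
        df[df == MISSING] = np.nan
        df.insert(0, "population", self.population_labels)
        df.insert(0, "id", self.individual_ids)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.population_labels == other.population_labels
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class AlleleFrequencies:
    """Per-locus A-allele frequencies with the allele counts behind them.

    ``freq_A`` is NaN at loci where every genotype is missing
    (``n_alleles == 0``); ``defined`` flags the usable loci.
    """

    locus_ids: list[str]
    freq_A: np.ndarray
    n_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.freq_A = np.asarray(self.freq_A, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=int)
        if not (len(self.locus_ids) == self.freq_A.size == self.n_alleles.size):
            raise ValueError("inconsistent lengths")
        ok = self.freq_A[self.n_alleles > 0]
        if ok.size and ((ok < 0).any() or (ok > 1).any()):
            raise ValueError("allele frequencies outside [0, 1]")

    @property
    def defined(self) -> np.ndarray:
        return self.n_alleles > 0


@dataclass
class StructureDialect:
    """Options for the STRUCTURE-style text format.

    rows_per_individual
        1 (default): one row with 2L allele columns; 2: two rows of L alleles.
    missing
        Token for a missing allele.
    allele_order
        How allele labels map to the internal A/B encoding: ``"sorted"``
        (default; numeric sort when all labels are numeric, else lexical,
        with the format's own 1/2 coding treated as canonical — makes
        read∘write the identity) or ``"first_seen"`` (A is the first label
        encountered in file order).

    The format does not carry locus names; the reader synthesizes
    ``locus_1 ... locus_L``.
    """

    rows_per_individual: int = 1
    missing: str = "-9"
    allele_order: str = "sorted"

    def __post_init__(self) -> None:
        if self.rows_per_individual not in (1, 2):
            raise ValueError("rows_per_individual must be 1 or 2")
        if self.allele_order not in ("sorted", "first_seen"):
            raise ValueError("allele_order must be 'sorted' or 'first_seen'")


def _sort_key(label: str):
    try:
        return (0, float(label))
    except ValueError:
        return (1, label)


def read_structure_file(
    path: str | Path, dialect: StructureDialect | None = None
) -> GenotypeMatrix:
    """Read a STRUCTURE-style genotype file.

    Each individual contributes an id column, a population column and 2L
    allele tokens (on one row, or two rows of L in the two-row dialect).
    A locus may carry at most two distinct non-missing allele labels; a
    half-missing genotype collapses to MISSING with a warning.
    """
    dialect = dialect or StructureDialect()
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if tokens:
                rows.append((lineno, tokens))
    if not rows:
        return GenotypeMatrix([], [], [], np.empty((0, 0), dtype=np.int8))

    if dialect.rows_per_individual == 2:
        if len(rows) % 2:
            raise GenotypeParseError(
                f"{path}: odd number of rows ({len(rows)}) in two-row dialect"
            )
        merged = []
        for (ln1, r1), (ln2, r2) in zip(rows[::2], rows[1::2]):
            if r1[:2] != r2[:2]:
                raise GenotypeParseError(
                    f"{path}: line {ln2}: id/population differ from line {ln1}"
                )
            if len(r1) != len(r2):
                raise GenotypeParseError(
                    f"{path}: line {ln2}: column count differs from line {ln1}"
                )
            # interleave so each locus contributes adjacent allele pairs
            alleles = [a for pair in zip(r1[2:], r2[2:]) for a in pair]
            merged.append((ln1, r1[:2] + alleles))
        rows = merged

    width = len(rows[0][1])
    if width < 4 or (width - 2) % 2:
        raise GenotypeParseError(
            f"{path}: line {rows[0][0]}: expected id, population and 2L allele "
            f"columns, found {width} columns"
        )
    n_loci = (width - 2) // 2
    ids, pops = [], []
    raw = np.empty((len(rows), 2 * n_loci), dtype=object)
    for r, (lineno, tokens) in enumerate(rows):
        if len(tokens) != width:
            raise GenotypeParseError(
                f"{path}: line {lineno}: expected {width} columns, found {len(tokens)}"
            )
        ids.append(tokens[0])
        pops.append(tokens[1])
        raw[r] = tokens[2:]

    miss = dialect.missing
    genotypes = np.empty((len(rows), n_loci), dtype=np.int8)
    half_missing = 0
    for l in range(n_loci):
        a1, a2 = raw[:, 2 * l], raw[:, 2 * l + 1]
        observed = [a for a in np.concatenate([a1, a2]) if a != miss]
        labels = list(dict.fromkeys(observed))
        if len(labels) > 2:
            raise GenotypeParseError(
                f"{path}: locus column {l + 1}: >2 distinct alleles {sorted(set(labels))}"
            )
        if dialect.allele_order == "sorted":
            # the format's own 1/2 coding is treated as canonical, so a locus
            # where only "2" was observed keeps its orientation on read-back
            if set(labels) <= {"1", "2"}:
                labels = ["1", "2"]
            else:
                labels = sorted(labels, key=_sort_key)
        allele_A = labels[0] if labels else None
        for r in range(len(rows)):
            x, y = a1[r], a2[r]
            if x == miss and y == miss:
                genotypes[r, l] = MISSING
            elif x == miss or y == miss:
                half_missing += 1
                genotypes[r, l] = MISSING
            else:
                genotypes[r, l] = int(x == allele_A) + int(y == allele_A)
    if half_missing:
        warnings.warn(
            f"{path}: {half_missing} half-missing genotype(s) treated as missing",
            stacklevel=2,
        )
    locus_ids = [f"locus_{l + 1}" for l in range(n_loci)]
    return GenotypeMatrix(ids, pops, locus_ids, genotypes)


def write_structure_file(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the one-row-per-individual STRUCTURE dialect (alleles 1/2, -9 missing)."""
    path = Path(path)
    codes = {2: ("1", "1"), 1: ("1", "2"), 0: ("2", "2"), MISSING: ("-9", "-9")}
    with path.open("w") as fh:
        for i in range(matrix.n_individuals):
            tokens = [matrix.individual_ids[i], matrix.population_labels[i]]
            for g in matrix.genotypes[i]:
                tokens.extend(codes[int(g)])
            fh.write(" ".join(tokens) + "\n")


def read_csv_file(path: str | Path) -> GenotypeMatrix:
    """Read the CSV dosage dialect: columns id, population, then one per locus."""
    df = pd.read_csv(path, dtype={"id": str, "population": str})
    if list(df.columns[:2]) != ["id", "population"]:
        raise GenotypeParseError(
            f"{path}: first two CSV columns must be 'id' and 'population'"
        )
    loci = list(df.columns[2:])
    vals = df[loci].to_numpy(dtype=float)
    genotypes = np.where(np.isnan(vals), MISSING, vals)
    if not np.isin(genotypes, (0, 1, 2, MISSING)).all():
        raise GenotypeParseError(f"{path}: dosages must be 0, 1, 2 or NA")
    return GenotypeMatrix(
        df["id"].tolist(), df["population"].tolist(), loci, genotypes.astype(np.int8)
    )


def write_csv_file(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = matrix.to_dataframe()
    df.to_csv(path, index=False, na_rep="NA", float_format="%.0f")


def allele_frequencies(
    matrix: GenotypeMatrix, subset: Sequence[int] | np.ndarray | None = None
) -> AlleleFrequencies:
    """A-allele frequency per locus over a subset of individuals.

    freq_A(l) = (sum of A dosages over non-missing genotypes at l) / n_alleles(l),
    with n_alleles(l) = 2 x (number of non-missing genotypes).  Missing genotypes
    are excluded, not imputed.
    """
    G = matrix.genotypes if subset is None else matrix.genotypes[np.asarray(subset, int)]
    if G.shape[0] == 0:
        raise ValueError("empty individual subset")
    observed = G != MISSING
    n_alleles = 2 * observed.sum(axis=0)
    counts = np.where(observed, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), np.nan)
    return AlleleFrequencies(list(matrix.locus_ids), freq, n_alleles)
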