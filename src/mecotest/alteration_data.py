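"""Core data containers and file I/O for binary alteration matrices.

The central object is the :class:`AlterationMatrix`: a binary gene × tumor
matrix in which entry ``x[i, j]`` is 1 when gene ``i`` carries a somatic
alteration in tumor ``j``.  Genes are rows, tumors are columns.  An
optional stratum assignment (e.g. cancer type per tumor) supports
stratified background estimation.

File formats are plain text: TSV/CSV with a header row of tumor labels and
a first column of gene labels; GMT for gene sets; a two-column TSV for
strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlterationMatrix",
    "GeneSet",
    "read_alteration_matrix",
    "write_alteration_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_strata",
    "filter_genes",
    "EmptyResultError",
]


class EmptyResultError(ValueError):
    """Raised when an operation would silently return an empty matrix."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass
class AlterationMatrix:
    """Binary gene × tumor alteration matrix with labels and optional strata.

    Parameters
    ----------
    values:
        ``(n_genes, n_tumors)`` array with entries in {0, 1}.
    gene_labels, tumor_labels:
        Unique strings positionally aligned with the rows / columns.
    strata:
        Optional mapping ``tumor_label -> stratum id``.  When present every
        tumor must be assigned to exactly one stratum.
    """

    values: np.ndarray
    gene_labels: list[str]
    tumor_labels: list[str]
    strata: dict[str, str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if v.size and not np.isin(v, (0, 1)).all():
            i, j = np.argwhere(~np.isin(v, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry {v[i, j]!r} for gene "
                f"{self.gene_labels[i]!r}, tumor {self.tumor_labels[j]!r}"
            )
        self.values = v.astype(np.int8)
        self.gene_labels = [str(g) for g in self.gene_labels]
        self.tumor_labels = [str(t) for t in self.tumor_labels]
        if len(self.gene_labels) != v.shape[0]:
            raise ValueError("gene_labels length does not match row count")
        if len(self.tumor_labels) != v.shape[1]:
            raise ValueError("tumor_labels length does not match column count")
        _check_unique(self.gene_labels, "gene")
        _check_unique(self.tumor_labels, "tumor")
        if self.strata is not None:
            missing = [t for t in self.tumor_labels if t not in self.strata]
            if missing:
                raise ValueError(f"tumors without stratum assignment: {missing[:5]}")
            self.strata = {t: str(self.strata[t]) for t in self.tumor_labels}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_tumors(self) -> int:
        return self.values.shape[1]

    @property
    def gene_sums(self) -> np.ndarray:
        """Per-gene alteration counts (row sums x_i.)."""
        return self.values.sum(axis=1)

    @property
    def tumor_sums(self) -> np.ndarray:
        """Per-tumor alteration counts (column sums x_.j)."""
        return self.values.sum(axis=0)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_labels.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene label: {gene!r}") from None

    def tumor_index(self, tumor: str) -> int:
        try:
            return self.tumor_labels.index(tumor)
        except ValueError:
            raise KeyError(f"unknown tumor label: {tumor!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def stratum_ids(self) -> list[str]:
        """Distinct stratum ids in order of first appearance among tumors."""
        if self.strata is None:
            return []
        seen: list[str] = []
        for t in self.tumor_labels:
            s = self.strata[t]
            if s not in seen:
                seen.append(s)
        return seen

    def stratum_columns(self, stratum: str) -> np.ndarray:
        """Column indices of the tumors belonging to ``stratum``."""
        if self.strata is None:
            raise ValueError("matrix has no strata")
        idx = [j for j, t in enumerate(self.tumor_labels) if self.strata[t] == stratum]
        if not idx:
            raise ValueError(f"stratum {stratum!r} has zero tumors")
        return np.asarray(idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_labels, columns=self.tumor_labels
        )


@dataclass
class GeneSet:
    """Named set of gene labels (GMT-style)."""

    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        deduped: list[str] = []
        seen = set()
        for g in self.genes:
            if g in seen:
                continue
            seen.add(g)
            deduped.append(g)
        if len(deduped) < len(self.genes):
            warnings.warn(
                f"gene set {self.name!r} contains duplicate genes; deduplicated "
                f"from {len(self.genes)} to {len(deduped)}",
                stacklevel=2,
            )
        self.genes = deduped

    def __len__(self) -> int:
        return len(self.genes)


# -- readers / writers -----------------------------------------------------


def read_alteration_matrix(
    path: str | Path,
    dialect: str = "tsv",
    strata: Mapping[str, str] | None = None,
    transpose: bool = False,
) -> AlterationMatrix:
    """Read a binary alteration matrix from a delimited text file.

    The first row holds tumor labels and the first column gene labels
    (genes in rows).  Pass ``transpose=True`` for files written the other
    way around.  Any cell that is not 0 or 1 raises a ``ValueError``
    naming the offending gene and tumor.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if transpose:
        df = df.T
    raw = df.to_numpy()
    vals = np.zeros(raw.shape, dtype=np.int8)
    ok = {"0": 0, "1": 1}
    for (i, j), cell in np.ndenumerate(raw):
        tok = str(cell).strip()
        if tok not in ok:
            raise ValueError(
                f"non-binary cell {cell!r} for gene {df.index[i]!r}, "
                f"tumor {df.columns[j]!r} in {path}"
            )
        vals[i, j] = ok[tok]
    return AlterationMatrix(
        vals.astype(np.int8),
        list(df.index),
        list(df.columns),
        dict(strata) if strata is not None else None,
    )


def write_alteration_matrix(X: AlterationMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    X.to_frame().to_csv(path, sep=sep)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name TAB description TAB genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sets.append(GeneSet(fields[0], fields[1], [g for g in fields[2:] if g]))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_strata(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (tumor_label, stratum) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"strata file {path} needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# -- filtering -------------------------------------------------------------


def filter_genes(X: AlterationMatrix, min_alterations: int) -> AlterationMatrix:
    """Keep genes altered in at least ``min_alterations`` tumors.

    Tumors (columns) are never dropped.  The input matrix is left
    untouched.  Raises :class:`EmptyResultError` when no gene survives.
    """
    if min_alterations < 0:
        raise ValueError("min_alterations must be nonnegative")
    keep = X.gene_sums >= min_alterations
    if not keep.any():
        raise EmptyResultError(
            f"no gene has >= {min_alterations} alterations (max is {X.gene_sums.max() if X.n_genes else 0})"
        )
    return AlterationMatrix(
        X.values[keep].copy(),
        [g for g, k in zip(X.gene_labels, keep) if k],
        list(X.tumor_labels),
        dict(X.strata) if X.strata is not None else None,
    )
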