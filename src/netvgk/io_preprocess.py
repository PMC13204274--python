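"""Expression-matrix and gene-set I/O, normalization, and variable-gene selection.

The in-memory containers are thin, validated wrappers around pandas objects:
an :class:`ExpressionMatrix` is a gene x sample DataFrame tagged with the
space its values live in (``raw_counts``, ``rpkm``, ``lognorm`` or ``log2``),
and a :class:`GeneSetLibrary` is an ordered name -> (description, genes)
mapping round-trippable through GMT.

Transforms update the space tag so downstream operations can refuse inputs
on the wrong scale (e.g. module z-scoring expects log-normalized values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSetLibrary",
    "read_expression",
    "write_expression",
    "read_mtx",
    "write_mtx",
    "read_gmt",
    "write_gmt",
    "lognormalize",
    "log2_transform",
    "select_variable_genes",
]

SPACES = ("raw_counts", "rpkm", "lognorm", "log2")


class FormatError(ValueError):
    """Malformed input table or gene-set file."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a scale tag.

    Parameters
    ----------
    values
        DataFrame with unique gene IDs as the index and unique sample (or
        cell) IDs as columns. All entries must be numeric and finite.
    space
        One of ``raw_counts``, ``rpkm``, ``lognorm``, ``log2``.
    """

    values: pd.DataFrame
    space: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"unknown expression space {self.space!r}; expected one of {SPACES}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dup[:5]}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dup[:5]}")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            bad = [c for c, dt in self.values.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise FormatError(f"non-numeric columns: {bad[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.space)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(samples)], self.space)


@dataclass
class GeneSetLibrary:
    """Ordered collection of named gene sets (GMT semantics).

    ``sets`` maps set name -> (description, gene list). Within a set the
    gene list is non-empty and duplicate-free; across sets genes may repeat.
    """

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetLibrary):
            return NotImplemented
        return self.sets == other.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])


# ---------------------------------------------------------------------------
# dense and sparse readers/writers


def read_expression(path: str | Path, sep: str | None = None, space: str = "raw_counts") -> ExpressionMatrix:
    """Read a dense gene x sample table (TSV/CSV; genes in rows).

    The first column holds gene IDs and the header row holds sample IDs.
    ``sep`` defaults to tab for ``.tsv``/``.txt`` and comma for ``.csv``.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"non-numeric value in column {col!r}, gene row {row!r}")
    return ExpressionMatrix(df, space=space)


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.values.to_csv(path, sep=sep)


def read_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    space: str = "raw_counts",
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet (genes x samples) with sidecar ID files."""
    mat = mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    samples = pd.read_csv(samples_path, sep="\t", header=None)[0].astype(str).tolist()
    arr = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if arr.shape != (len(genes), len(samples)):
        raise FormatError(
            f"MTX shape {arr.shape} does not match sidecars ({len(genes)} genes, {len(samples)} samples)"
        )
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), space=space)


def write_mtx(matrix: ExpressionMatrix, outdir: str | Path, prefix: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / f"{prefix}matrix.mtx"), sparse.csr_matrix(matrix.values.to_numpy()))
    (outdir / f"{prefix}genes.tsv").write_text("\n".join(map(str, matrix.genes)) + "\n")
    (outdir / f"{prefix}barcodes.tsv").write_text("\n".join(map(str, matrix.samples)) + "\n")


def read_gmt(path: str | Path) -> GeneSetLibrary:
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line {lineno}: need name, description and >=1 gene")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = (desc, genes)
    return GeneSetLibrary(sets)


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    lines = [
        "\t".join([name, desc, *genes])
        for name, (desc, genes) in lib.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# transforms


def lognormalize(counts: ExpressionMatrix, scale: float = 10_000) -> ExpressionMatrix:
    """Library-size normalize and log-transform: ln(1 + scale * c / column total).

    The per-column (sample/cell) totals are computed over all genes, so the
    result is invariant to rescaling any single column's counts.
    """
    if counts.space != "raw_counts":
        raise ValueError(f"lognormalize expects raw counts, got space={counts.space!r}")
    vals = counts.values.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = counts.samples[zero].tolist()
        raise ValueError(f"zero-total columns cannot be normalized: {bad[:5]}")
    out = np.log1p(scale * vals / totals)
    return ExpressionMatrix(
        pd.DataFrame(out, index=counts.genes, columns=counts.samples), space="lognorm"
    )


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset); used for RPKM-style abundance tables before DE."""
    if matrix.space not in ("raw_counts", "rpkm"):
        raise ValueError(f"log2_transform expects linear-scale values, got space={matrix.space!r}")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals + offset <= 0).any():
        raise ValueError("log2_transform: values + offset must be positive")
    out = np.log2(vals + offset)
    return ExpressionMatrix(pd.DataFrame(out, index=matrix.genes, columns=matrix.samples), space="log2")


def select_variable_genes(matrix: ExpressionMatrix, top_n: int) -> list[str]:
    """Top ``top_n`` genes by (unbiased, n-1) variance of the stored values.

    Ranking is descending by variance; exact ties are broken by gene ID in
    lexicographic order, so the selection is deterministic and invariant to
    sample order.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    var = matrix.values.var(axis=1, ddof=1)
    nonconstant = var[var > 0]
    if top_n > len(nonconstant):
        raise ValueError(
            f"top_n={top_n} exceeds the {len(nonconstant)} genes with non-zero variance"
        )
    order = nonconstant.sort_index().sort_values(ascending=False, kind="stable")
    return order.index[:top_n].tolist()
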