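"""Reading and writing the standard on-disk formats.

Count matrices travel as MatrixMarket coordinate triplets with companion
``features.tsv`` / ``barcodes.tsv`` tables (the 10x dialect: genes as rows,
cells as columns; plain or gzipped). Gene sets travel as GMT. Everything
else is TSV.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import FormatError, logger

MITO_PREFIX = "mt-"  # mouse convention; configurable at every call site


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, genes x cells.

    ``gene_ids`` and ``barcodes`` are unique string arrays aligned to the
    rows and columns of ``counts``.
    """

    gene_ids: np.ndarray
    barcodes: np.ndarray
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.counts = sp.csr_matrix(self.counts)
        if len(np.unique(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(np.unique(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.gene_ids, self.barcodes[mask], self.counts[:, mask])


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the same layout as :class:`CountMatrix`."""

    gene_ids: np.ndarray
    barcodes: np.ndarray
    values: sp.csr_matrix = field(repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


def cell_metrics(cm: CountMatrix, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Per-cell QC metrics: total UMIs, detected genes, mitochondrial fraction."""
    counts = cm.counts.tocsc()
    n_umi = np.asarray(counts.sum(axis=0)).ravel().astype(int)
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel().astype(int)
    is_mito = np.array([str(g).startswith(mito_prefix) for g in cm.gene_ids])
    mito_umi = (
        np.asarray(counts[is_mito].sum(axis=0)).ravel() if is_mito.any() else np.zeros(cm.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_umi": n_umi,
            "n_genes_detected": n_genes,
            "mito_fraction": mito_frac,
        },
        index=pd.Index(cm.barcodes, name="barcode"),
    )


# ---------------------------------------------------------------------------
# MatrixMarket triplet directories
# ---------------------------------------------------------------------------

def _find(dir_path: str, stem: str) -> str:
    for name in (stem, stem + ".gz"):
        path = os.path.join(dir_path, name)
        if os.path.exists(path):
            return path
    raise FormatError(f"missing {stem}[.gz] in {dir_path}")


def _read_lines(path: str) -> list[str]:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_counts(dir_path: str, mito_prefix: str = MITO_PREFIX,
                metadata_file: str = "cells.tsv"):
    """Read a 10x-style triplet directory.

    Returns ``(CountMatrix, CellTable)`` where the cell table is a DataFrame
    indexed by barcode carrying ``n_umi``, ``n_genes_detected`` and
    ``mito_fraction`` plus any columns found in an optional per-cell
    metadata TSV (``cells.tsv``) in the same directory.
    """
    mtx_path = _find(dir_path, "matrix.mtx")
    try:
        mat = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("non-integral counts in matrix.mtx")
    mat = mat.astype(np.int64)

    genes = [line.split("\t")[0] for line in _read_lines(_find(dir_path, "features.tsv"))]
    barcodes = [line.split("\t")[0] for line in _read_lines(_find(dir_path, "barcodes.tsv"))]
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix header declares {mat.shape} but features/barcodes give "
            f"({len(genes)}, {len(barcodes)})"
        )
    cm = CountMatrix(np.array(genes, dtype=object), np.array(barcodes, dtype=object), mat)

    cells = cell_metrics(cm, mito_prefix=mito_prefix)
    meta_path = os.path.join(dir_path, metadata_file)
    if not os.path.exists(meta_path) and os.path.exists(meta_path + ".gz"):
        meta_path += ".gz"
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str}).set_index("barcode")
        extra = meta.columns.difference(cells.columns)
        cells = cells.join(meta[extra])
    return cm, cells


def write_counts(dir_path: str, cm: CountMatrix, cells: pd.DataFrame | None = None) -> None:
    """Write a triplet directory (matrix.mtx + features.tsv + barcodes.tsv
    and, if given, the cell metadata TSV)."""
    os.makedirs(dir_path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(dir_path, "matrix.mtx"), cm.counts.tocoo(), field="integer"
    )
    with open(os.path.join(dir_path, "features.tsv"), "w") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(os.path.join(dir_path, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, cm.barcodes)) + "\n")
    if cells is not None:
        write_table(cells, os.path.join(dir_path, "cells.tsv"))
    logger.info("wrote %d genes x %d cells to %s", cm.n_genes, cm.n_cells, dir_path)


# ---------------------------------------------------------------------------
# GMT gene sets and generic tables
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> dict[str, list[str]]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Tolerates a missing description field (lines with exactly two columns
    are read as name + one gene).
    """
    sets: dict[str, list[str]] = {}
    for line in _read_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"GMT line with fewer than 2 fields: {line[:60]!r}")
        name = parts[0]
        genes = parts[2:] if len(parts) > 2 else parts[1:]
        if name in sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def write_table(df: pd.DataFrame, path: str) -> None:
    """TSV writer with a stable float format so identical runs are
    byte-identical."""
    df.to_csv(path, sep="\t", index=df.index.name is not None, float_format="%.10g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
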