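"""Cell-level quality control, log-normalization, variable-gene selection
and the PC embedding consumed by the heterogeneity statistic.

QC retains a cell only if it detects at least ``min_genes`` unique genes,
has at least ``min_umi`` UMIs, and its mitochondrial read fraction does not
exceed ``max_mito`` (strictly greater is removed). External quality models
(doublet callers, mixture-model posteriors) are consumed as boolean flag
columns, not recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import EmptyResultError, logger
from .io import CountMatrix, NormalizedMatrix


@dataclass
class QCParams:
    min_genes: int = 200
    min_umi: int = 5000
    max_mito: float = 0.05
    drop_flagged: bool = False
    flag_columns: tuple[str, ...] = ("doublet_flag", "low_quality_flag")

    def __post_init__(self):
        if self.min_genes <= 0 or self.min_umi <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0.0 < self.max_mito < 1.0:
            raise ValueError("max_mito must lie in (0, 1)")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_low_genes: int
    removed_low_umi: int
    removed_high_mito: int
    removed_flagged: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def apply_qc(cm: CountMatrix, cells: pd.DataFrame, params: QCParams | None = None):
    """Filter cells by the QC thresholds; returns filtered matrix, table and
    a report counting removals per (non-exclusive) criterion."""
    params = params or QCParams()
    cells = cells.loc[list(cm.barcodes)]  # enforce alignment

    low_genes = cells["n_genes_detected"].to_numpy() < params.min_genes
    low_umi = cells["n_umi"].to_numpy() < params.min_umi
    high_mito = cells["mito_fraction"].to_numpy() > params.max_mito
    flagged = np.zeros(len(cells), dtype=bool)
    if params.drop_flagged:
        for col in params.flag_columns:
            if col in cells.columns:
                flagged |= cells[col].fillna(False).astype(bool).to_numpy()

    keep = ~(low_genes | low_umi | high_mito | flagged)
    report = QCReport(
        n_input=len(cells),
        n_retained=int(keep.sum()),
        removed_low_genes=int(low_genes.sum()),
        removed_low_umi=int(low_umi.sum()),
        removed_high_mito=int(high_mito.sum()),
        removed_flagged=int(flagged.sum()),
    )
    if report.n_retained == 0:
        raise EmptyResultError("no cells survive quality control", report=report)
    logger.info(
        "QC retained %d/%d cells (low-genes %d, low-UMI %d, high-mito %d, flagged %d)",
        report.n_retained, report.n_input, report.removed_low_genes,
        report.removed_low_umi, report.removed_high_mito, report.removed_flagged,
    )
    return cm.subset_cells(keep), cells.loc[keep], report


def lognormalize(cm: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """``ln(1 + scale * count / cell_total)`` per entry; zeros stay zero and
    the sparsity pattern is preserved."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = cm.counts.tocsc().astype(np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; run QC first")
    # scale columns by scale/total, then log1p on stored entries only
    counts = counts @ sp.diags(scale / totals)
    counts.data = np.log1p(counts.data)
    return NormalizedMatrix(cm.gene_ids, cm.barcodes, counts.tocsr())


def select_hvg(norm: NormalizedMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by binned standardized dispersion.

    Dispersion = variance / mean of log-normalized expression; z-scored
    within quantile bins of the mean so the selection is not a pure
    expression ranking. Deterministic; ties broken by gene id.
    """
    x = norm.values.tocsr()
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = x.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var = np.maximum(var, 0.0)

    expressed = mean > 0
    n_expressed = int(expressed.sum())
    if n > n_expressed:
        warnings.warn(
            f"requested {n} variable genes but only {n_expressed} are expressed; "
            "returning all expressed genes"
        )
        n = n_expressed

    disp = np.zeros_like(mean)
    disp[expressed] = var[expressed] / mean[expressed]

    # standardize dispersion within mean-quantile bins
    z = np.full_like(disp, -np.inf)
    means_e = mean[expressed]
    n_bins_eff = min(n_bins, max(1, n_expressed // 2))
    quantiles = np.quantile(means_e, np.linspace(0, 1, n_bins_eff + 1))
    bins = np.clip(np.searchsorted(quantiles[1:-1], means_e, side="right"), 0, n_bins_eff - 1)
    z_e = np.empty_like(means_e)
    disp_e = disp[expressed]
    for b in range(n_bins_eff):
        in_bin = bins == b
        if not in_bin.any():
            continue
        mu, sd = disp_e[in_bin].mean(), disp_e[in_bin].std()
        z_e[in_bin] = (disp_e[in_bin] - mu) / sd if sd > 0 else 0.0
    z[expressed] = z_e

    order = sorted(range(len(z)), key=lambda i: (-z[i], str(norm.gene_ids[i])))
    return [str(norm.gene_ids[i]) for i in order[:n]]


@dataclass
class Embedding:
    """PC coordinates (cells x components) with the gene list that produced
    them; components are ordered by non-increasing explained variance and
    sign-fixed so each component's largest-magnitude gene loading is
    positive."""

    barcodes: np.ndarray
    coordinates: np.ndarray = field(repr=False)
    explained_variance: np.ndarray = field(repr=False)
    genes: list[str] = field(repr=False)

    @property
    def n_pcs(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.barcodes, name="barcode"),
            columns=[f"PC{i + 1}" for i in range(self.n_pcs)],
        )
        return df


def compute_pca(norm: NormalizedMatrix, genes: list[str] | None = None,
                n_pcs: int = 20) -> Embedding:
    """PCA of centered, unit-scaled log-normalized expression on the given
    gene list (default: all genes)."""
    if genes is None:
        genes = [str(g) for g in norm.gene_ids]
    idx = pd.Index(norm.gene_ids).get_indexer(genes)
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    x = np.asarray(norm.values[idx].todense(), dtype=np.float64).T  # cells x genes

    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant genes contribute nothing after centering
    x /= sd

    n_max = min(x.shape)
    k = min(n_pcs, n_max)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    nonzero = s > s[0] * 1e-12 if s.size else np.array([], dtype=bool)
    k_eff = min(k, int(nonzero.sum()))
    if k_eff < n_pcs:
        warnings.warn(
            f"rank-deficient input: returning {k_eff} of {n_pcs} requested components"
        )
    u, s, vt = u[:, :k_eff], s[:k_eff], vt[:k_eff]

    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(k_eff), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = u * s * flip
    expl_var = s**2 / max(x.shape[0] - 1, 1)
    return Embedding(
        barcodes=np.asarray(norm.barcodes, dtype=object),
        coordinates=coords,
        explained_variance=expl_var,
        genes=list(genes),
    )
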