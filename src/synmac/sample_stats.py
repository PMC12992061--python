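"""Sample-level statistics: intercellular heterogeneity in PC space and
depth-normalized transcriptional divergence.

Heterogeneity is the mean Euclidean distance from each cell to its sample
group's centroid in principal-component space (20 components by default).
Divergence measures how concentrated a sample's expression is: pseudobulk
totals are depth-matched by downsampling reads without replacement
(multivariate hypergeometric) to a shared depth, genes are ranked by total
expression, and the statistic is the ratio of the mean of the top half to
the mean of the lower half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_rng
from .diffexpr import wilcoxon_p
from .io import CountMatrix
from .preprocess import Embedding

DEFAULT_DEPTH = 1_000_000


# ---------------------------------------------------------------------------
# Intercellular heterogeneity
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityResult:
    sample_group: str
    n_cells: int
    mean_centroid_distance: float
    distances: np.ndarray = field(repr=False)


def intercellular_heterogeneity(emb: Embedding, cells: pd.DataFrame,
                                group_col: str = "group") -> list[HeterogeneityResult]:
    """Per group: mean Euclidean distance of each cell to the group centroid
    in the embedding."""
    coords = pd.DataFrame(emb.coordinates, index=pd.Index(emb.barcodes))
    missing = cells.index.difference(coords.index)
    if len(missing):
        raise KeyError(f"{len(missing)} barcodes missing from embedding")
    results = []
    for group, sub in cells.groupby(group_col, sort=True):
        x = coords.loc[sub.index].to_numpy()
        if len(x) == 1:
            warnings.warn(f"group {group!r} has a single cell; distance is 0")
        centroid = x.mean(axis=0)
        d = np.linalg.norm(x - centroid, axis=1)
        results.append(
            HeterogeneityResult(
                sample_group=str(group),
                n_cells=len(x),
                mean_centroid_distance=float(d.mean()),
                distances=d,
            )
        )
    return results


def heterogeneity_test(result_a: HeterogeneityResult, result_b: HeterogeneityResult,
                       n_boot: int = 10000, seed=None) -> dict:
    """Compare per-cell centroid distances between two groups.

    Primary: two-sided rank-sum p on the distance distributions (exact for
    small groups). Secondary: bootstrap percentile CI for the difference of
    mean distances (a - b).
    """
    x, y = result_a.distances, result_b.distances
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in heterogeneity test")
    p = wilcoxon_p(x, y)
    rng = as_rng(seed)
    bx = rng.choice(x, size=(n_boot, len(x)), replace=True).mean(axis=1)
    by = rng.choice(y, size=(n_boot, len(y)), replace=True).mean(axis=1)
    diff = bx - by
    return {
        "p_ranksum": float(p),
        "mean_diff": float(x.mean() - y.mean()),
        "ci_low": float(np.quantile(diff, 0.025)),
        "ci_high": float(np.quantile(diff, 0.975)),
    }


# ---------------------------------------------------------------------------
# Pseudobulk, downsampling, divergence
# ---------------------------------------------------------------------------

def pseudobulk(cm: CountMatrix, cells: pd.DataFrame,
               group_col: str = "group") -> pd.DataFrame:
    """Per-group gene count totals (genes x groups, integer)."""
    barcode_pos = pd.Index(cm.barcodes)
    out = {}
    for group, sub in cells.groupby(group_col, sort=True):
        cols = barcode_pos.get_indexer(sub.index)
        if (cols < 0).any():
            raise KeyError(f"barcodes of group {group!r} missing from count matrix")
        out[str(group)] = np.asarray(cm.counts[:, cols].sum(axis=1)).ravel().astype(np.int64)
    return pd.DataFrame(out, index=pd.Index(cm.gene_ids, name="gene"))


def downsample_counts(vector, depth: int = DEFAULT_DEPTH, seed=None) -> np.ndarray:
    """Downsample a gene-total vector without replacement to exactly
    ``depth`` reads (multivariate hypergeometric draw)."""
    v = np.asarray(vector, dtype=np.int64)
    if (v < 0).any():
        raise ValueError("negative counts")
    total = int(v.sum())
    if total < depth:
        raise ValueError(
            f"total reads {total} < target depth {depth}; use a shared depth of "
            f"min(group totals) capped at {DEFAULT_DEPTH}"
        )
    if total == depth:
        return v.copy()
    rng = as_rng(seed)
    return rng.multivariate_hypergeometric(v, depth).astype(np.int64)


def transcriptional_divergence(vector, gene_ids=None, drop_zeros: bool = False) -> float:
    """Ratio of mean expression of the top half of genes (ranked by total,
    descending, ties by gene id) to the mean of the lower half. With an odd
    gene count the extra gene joins the lower half. Returns ``inf`` when
    the lower half is all zero."""
    v = np.asarray(vector, dtype=float)
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(len(v))], dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    if drop_zeros:
        keep = v > 0
        v, gene_ids = v[keep], gene_ids[keep]
    if len(v) < 2:
        raise ValueError("divergence needs at least 2 genes")
    order = sorted(range(len(v)), key=lambda i: (-v[i], str(gene_ids[i])))
    ranked = v[order]
    n_top = len(v) // 2
    top, lower = ranked[:n_top], ranked[n_top:]
    if lower.mean() == 0:
        warnings.warn("lower half all zero; divergence is infinite")
        return float("inf")
    return float(top.mean() / lower.mean())


@dataclass
class DivergenceResult:
    sample_group: str
    target_depth: int
    n_genes_used: int
    divergence: float
    divergence_sd: float
    n_draws: int
    seed: int | None


def divergence_by_group(cm: CountMatrix, cells: pd.DataFrame,
                        group_col: str = "group", depth: int | None = None,
                        n_draws: int = 25, seed=None,
                        drop_zeros: bool = False) -> list[DivergenceResult]:
    """Pseudobulk each group, downsample to a shared depth and compute
    divergence, averaged over ``n_draws`` downsampling draws (``n_draws=1``
    is the single-draw literal procedure)."""
    pb = pseudobulk(cm, cells, group_col=group_col)
    totals = pb.sum(axis=0)
    shared = int(min(int(totals.min()), DEFAULT_DEPTH if depth is None else depth))
    rng = as_rng(seed)
    results = []
    for group in pb.columns:
        vals = np.empty(n_draws)
        for i in range(n_draws):
            ds = downsample_counts(pb[group].to_numpy(), depth=shared, seed=rng)
            vals[i] = transcriptional_divergence(
                ds, gene_ids=pb.index.to_numpy(), drop_zeros=drop_zeros
            )
        results.append(
            DivergenceResult(
                sample_group=str(group),
                target_depth=shared,
                n_genes_used=int((pb[group] > 0).sum()) if drop_zeros else len(pb),
                divergence=float(vals.mean()),
                divergence_sd=float(vals.std(ddof=1)) if n_draws > 1 else 0.0,
                n_draws=n_draws,
                seed=seed if isinstance(seed, int) else None,
            )
        )
    return results
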