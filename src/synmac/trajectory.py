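"""Root-anchored graph pseudotime, branch extraction, per-group densities
along branches, and smooth expression trends.

Pseudotime is the multi-source shortest-path distance from the root
subpopulation's cells over a symmetric k-nearest-neighbor graph in PC
space, min-max rescaled to [0, 1]. This is an explicitly labeled stand-in
for principal-graph learners; externally computed pseudotime/branch tables
can be ingested from TSV instead (columns: barcode, pseudotime,
branch_id). Branch membership is a relation, not a partition: cells on the
shared root segment belong to every branch passing through them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.csgraph import dijkstra
from sklearn.neighbors import kneighbors_graph

from .io import NormalizedMatrix
from .preprocess import Embedding


def build_knn_graph(emb: Embedding, k: int = 15) -> sp.csr_matrix:
    """Symmetric kNN graph on PC coordinates with Euclidean edge weights."""
    a = kneighbors_graph(emb.coordinates, n_neighbors=k, mode="distance")
    return a.maximum(a.T).tocsr()


def assign_pseudotime(emb: Embedding, cells: pd.DataFrame,
                      root_subpop: str = "Ly6C+", k: int = 15,
                      subpop_col: str = "subpopulation") -> pd.DataFrame:
    """Shortest-path pseudotime from the nearest root cell.

    Returns a DataFrame indexed by barcode with ``pseudotime`` (rescaled to
    [0, 1] over reachable cells), ``root_flag`` and ``orphan`` (cells
    disconnected from every root).
    """
    order = pd.Index(emb.barcodes)
    sub = cells.loc[order, subpop_col].to_numpy()
    roots = np.where(sub == root_subpop)[0]
    if roots.size == 0:
        raise ValueError(f"no cells of root subpopulation {root_subpop!r}")
    graph = build_knn_graph(emb, k=k)
    dist = dijkstra(graph, directed=False, indices=roots, min_only=True)
    orphan = ~np.isfinite(dist)
    if orphan.mean() > 0.05:
        warnings.warn(
            f"{orphan.sum()} cells ({orphan.mean():.1%}) unreachable from the root; "
            "consider a larger k"
        )
    finite = dist[~orphan]
    lo, hi = finite.min(), finite.max()
    span = hi - lo if hi > lo else 1.0
    pt = np.where(orphan, np.nan, (dist - lo) / span)
    return pd.DataFrame(
        {
            "pseudotime": pt,
            "root_flag": sub == root_subpop,
            "orphan": orphan,
        },
        index=pd.Index(order, name="barcode"),
    )


def extract_branches(emb: Embedding, cells: pd.DataFrame, terminals: list[str],
                     root_subpop: str = "Ly6C+", k: int = 15,
                     subpop_col: str = "subpopulation") -> pd.DataFrame:
    """Branch membership relation: for each terminal subpopulation, the
    union of kNN-graph shortest-path vertices from the root region to each
    of that terminal's cells.

    Returns a boolean DataFrame (barcode x terminal). A terminal equal to
    the root yields a degenerate branch of root cells only (with a
    warning); unreachable terminals are omitted with a warning.
    """
    order = pd.Index(emb.barcodes)
    sub = cells.loc[order, subpop_col].to_numpy()
    roots = np.where(sub == root_subpop)[0]
    if roots.size == 0:
        raise ValueError(f"no cells of root subpopulation {root_subpop!r}")
    graph = build_knn_graph(emb, k=k)
    dist, predecessors, _sources = dijkstra(
        graph, directed=False, indices=roots, min_only=True, return_predecessors=True
    )

    membership = {}
    for term in terminals:
        if term == root_subpop:
            warnings.warn(f"terminal {term!r} equals the root; degenerate branch")
            membership[term] = sub == root_subpop
            continue
        term_cells = np.where(sub == term)[0]
        reachable = term_cells[np.isfinite(dist[term_cells])]
        if reachable.size == 0:
            warnings.warn(f"terminal {term!r} unreachable from root; branch omitted")
            continue
        on_branch = np.zeros(len(order), dtype=bool)
        for c in reachable:
            v = c
            while v >= 0:
                if on_branch[v]:
                    break  # rest of the path to the root is already marked
                on_branch[v] = True
                v = predecessors[v]
        membership[term] = on_branch
    return pd.DataFrame(membership, index=pd.Index(order, name="barcode"))


def branch_density(pt: pd.DataFrame, branches: pd.DataFrame, cells: pd.DataFrame,
                   branch_id: str, group_col: str = "group",
                   grid_size: int = 200, min_cells: int = 5) -> pd.DataFrame:
    """Gaussian KDE (Silverman bandwidth) of each group's pseudotime values
    on one branch, evaluated on a shared grid spanning the branch's pooled
    pseudotime range and renormalized to integrate to 1.

    Returns a long DataFrame: branch_id, group, grid, density, bandwidth.
    Groups with fewer than ``min_cells`` cells on the branch are omitted
    with a warning.
    """
    on_branch = branches.index[branches[branch_id]]
    vals_all = pt.loc[on_branch, "pseudotime"].dropna()
    if len(vals_all) < min_cells:
        raise ValueError(f"branch {branch_id!r} has too few cells")
    lo, hi = float(vals_all.min()), float(vals_all.max())
    if hi <= lo:
        lo, hi = lo - 0.01, hi + 0.01
    grid = np.linspace(lo, hi, grid_size)

    frames = []
    for group, subset in cells.loc[vals_all.index].groupby(group_col, sort=True):
        v = vals_all.loc[subset.index].to_numpy()
        if len(v) < min_cells:
            warnings.warn(
                f"group {group!r} has {len(v)} cells on branch {branch_id!r} "
                f"(<{min_cells}); omitted"
            )
            continue
        if np.ptp(v) == 0:
            # degenerate spike: narrow Gaussian at the common value
            bw = (hi - lo) / grid_size
            dens = scipy.stats.norm.pdf(grid, loc=v[0], scale=bw)
        else:
            kde = scipy.stats.gaussian_kde(v, bw_method="silverman")
            bw = float(kde.factor * v.std(ddof=1))
            dens = kde(grid)
        area = np.trapezoid(dens, grid)
        dens = dens / area
        frames.append(
            pd.DataFrame(
                {
                    "branch_id": branch_id,
                    "group": str(group),
                    "grid": grid,
                    "density": dens,
                    "bandwidth": bw,
                    "n_cells": len(v),
                }
            )
        )
    if not frames:
        raise ValueError(f"no group reached {min_cells} cells on branch {branch_id!r}")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Spline trends
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, df: int = 5,
                         knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Boundary knots at the data range, ``df - 1`` interior knots at
    quantiles; the basis is linear beyond the boundaries and nests the
    identity (first column is x itself).
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("df must be >= 2")
    if knots is None:
        probs = np.linspace(0, 1, df + 1)
        knots = np.quantile(x, probs)
    knots = np.unique(np.asarray(knots, dtype=float))
    if len(knots) < 3:
        # not enough distinct knots for curvature terms: linear basis
        return x[:, None]
    k_last = knots[-1]
    k_penult = knots[-2]

    def d(kj):
        num = np.clip(x - kj, 0, None) ** 3 - np.clip(x - k_last, 0, None) ** 3
        return num / (k_last - kj)

    d_penult = d(k_penult)
    cols = [x] + [d(kj) - d_penult for kj in knots[:-2]]
    return np.column_stack(cols)


def fit_trend(norm: NormalizedMatrix, pt: pd.DataFrame, branches: pd.DataFrame,
              gene: str, branch_id: str, df: int = 5,
              grid_size: int = 100) -> dict:
    """Least-squares natural-cubic-spline fit of one gene's log-normalized
    expression against pseudotime on one branch.

    Returns the grid, fitted values on the grid, fitted values at the
    observed cells, residual variance and the effective df used (reduced
    with a warning when too few distinct pseudotime values exist).
    """
    on_branch = branches.index[branches[branch_id]]
    pt_vals = pt.loc[on_branch, "pseudotime"].dropna()
    if len(pt_vals) < 20:
        raise ValueError(f"branch {branch_id!r} has {len(pt_vals)} cells; need >= 20")
    gene_idx = pd.Index(norm.gene_ids).get_indexer([gene])
    if gene_idx[0] < 0:
        raise KeyError(f"gene {gene!r} not in matrix")
    col_idx = pd.Index(norm.barcodes).get_indexer(pt_vals.index)
    y = np.asarray(norm.values[gene_idx[0], col_idx].todense()).ravel()
    x = pt_vals.to_numpy()

    n_distinct = len(np.unique(x))
    df_eff = df
    if n_distinct <= df:
        df_eff = max(2, n_distinct - 1)
        warnings.warn(f"only {n_distinct} distinct pseudotime values; reduced df to {df_eff}")

    basis = natural_spline_basis(x, df=df_eff)
    design = np.column_stack([np.ones(len(x)), basis])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    dof = max(len(y) - design.shape[1], 1)

    grid = np.linspace(x.min(), x.max(), grid_size)
    probs = np.linspace(0, 1, df_eff + 1)
    gbasis = natural_spline_basis(grid, df=df_eff, knots=np.quantile(x, probs))
    gdesign = np.column_stack([np.ones(len(grid)), gbasis])
    return {
        "gene": gene,
        "branch_id": branch_id,
        "df": df_eff,
        "knots": np.quantile(x, probs),
        "grid": grid,
        "fitted_grid": gdesign @ coef,
        "fitted_cells": fitted,
        "residual_variance": float(resid @ resid / dof),
        "coefficients": coef,
    }
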