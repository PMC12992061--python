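"""Preranked permutation gene-set enrichment on signed DE weights, plus a
rank-based per-cell pathway activity score.

Genes are ranked by the signed weight ``-log10(p) * log2(FC)`` from a DE
contrast. The enrichment score is the weighted Kolmogorov-Smirnov running
sum (GSEA-style, exponent 1): walking down the ranked list, member genes
add ``|weight| / sum(|member weights|)`` and non-members subtract
``1 / (N - k)``; the score is the running sum's largest-magnitude
deviation, signed. The null distribution draws random same-size gene sets
from the ranked universe (gene-label permutation); only sets with at least
10 members present in the list are tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._utils import as_rng
from .io import NormalizedMatrix

MIN_SET_SIZE = 10
P_FLOOR = 1e-300


def compute_weights(de: pd.DataFrame, p_floor: float = P_FLOOR) -> pd.DataFrame:
    """Signed ranking weight per gene: ``-log10(p) * log2fc`` with the
    p-value floored to keep weights finite. Sorted descending by weight,
    ties broken by gene id."""
    if len(de) == 0:
        raise ValueError("empty DE result")
    p = np.maximum(de["p"].to_numpy(dtype=float), p_floor)
    weight = -np.log10(p) * de["avg_log2fc"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "gene": de["gene"].astype(str),
            "p": de["p"],
            "log2fc": de["avg_log2fc"],
            "weight": weight,
        }
    )
    return out.sort_values(
        ["weight", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _es_from_positions(absw: np.ndarray, positions: np.ndarray):
    """Enrichment score given sorted member positions in the ranked list.

    The running sum is piecewise linear between member positions; its
    extrema occur immediately after a member increment (candidate maxima)
    or immediately before one (candidate minima), so only 2k points need
    evaluating. Works on a (n_draws, k) matrix of sorted positions.
    """
    n = len(absw)
    w = absw[positions]
    denom = w.sum(axis=-1, keepdims=True)
    denom = np.where(denom > 0, denom, 1.0)
    cum_hit = np.cumsum(w, axis=-1) / denom
    k = positions.shape[-1]
    miss_step = 1.0 / (n - k) if k < n else 0.0
    ranks = np.arange(k)
    misses_before = positions - ranks  # non-members preceding each member
    after = cum_hit - misses_before * miss_step
    before = np.concatenate(
        [np.zeros((*cum_hit.shape[:-1], 1)), cum_hit[..., :-1]], axis=-1
    ) - misses_before * miss_step
    hi = after.max(axis=-1)
    # the walk ends at 0 exactly; local minima sit just before each member
    lo = np.minimum(before.min(axis=-1), 0.0)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo), after


@dataclass
class EnrichmentResult:
    pathway: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr: float = np.nan
    direction: str = ""
    leading_edge: list[str] = field(default_factory=list)


def permutation_enrichment(ranked: pd.DataFrame, sets: dict[str, list[str]],
                           n_perm: int = 10000, seed=None,
                           min_size: int = MIN_SET_SIZE,
                           batch: int = 1000) -> pd.DataFrame:
    """Test each gene set against random same-size sets from the ranked
    universe; returns a DataFrame with es, nes, permutation p, BH-FDR,
    direction and the leading-edge genes."""
    genes = ranked["gene"].astype(str).to_numpy()
    if len(genes) < 50:
        raise ValueError("ranked list too short (< 50 genes)")
    absw = np.abs(ranked["weight"].to_numpy(dtype=float))
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = as_rng(seed)

    rows = []
    for name, members in sets.items():
        positions = np.sort(
            np.array([gene_pos[g] for g in set(members) if g in gene_pos], dtype=int)
        )
        k = len(positions)
        if k < min_size:
            warnings.warn(f"gene set {name!r} has {k} genes in the list (<{min_size}); skipped")
            continue
        es, after = _es_from_positions(absw, positions)
        es = float(es)

        null_abs = np.empty(n_perm)
        done = 0
        while done < n_perm:
            m = min(batch, n_perm - done)
            draw = np.argpartition(rng.random((m, len(genes))), k - 1, axis=1)[:, :k]
            draw.sort(axis=1)
            null_es, _ = _es_from_positions(absw, draw)
            null_abs[done : done + m] = np.abs(null_es)
            done += m

        p_perm = (1.0 + (null_abs >= abs(es)).sum()) / (n_perm + 1.0)
        nes = es / null_abs.mean() if null_abs.mean() > 0 else 0.0

        running = np.asarray(after).ravel()
        if es >= 0:
            edge = positions[: int(running.argmax()) + 1]
        else:
            # members at or beyond the running-sum minimum
            before = running - absw[positions] / max(absw[positions].sum(), 1e-300)
            edge = positions[int(before.argmin()):]
        rows.append(
            {
                "pathway": name,
                "size": k,
                "es": es,
                "nes": float(nes),
                "p_perm": float(p_perm),
                "direction": "up" if es >= 0 else "down",
                "leading_edge": ",".join(genes[edge]),
            }
        )

    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    return out


def cell_pathway_scores(norm: NormalizedMatrix, gene_set: list[str],
                        pathway: str = "pathway") -> pd.DataFrame:
    """Rank-based per-cell pathway activity.

    For each set gene, cells are midranked by its expression across all
    cells; a cell's score is the mean rank fraction ``(rank - 0.5) /
    n_cells`` over set genes, minus 0.5. Positive scores mean the cell
    expresses the set's genes above the population median; a gene constant
    across cells contributes exactly zero.
    """
    present = [g for g in gene_set if g in set(map(str, norm.gene_ids))]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    idx = pd.Index(norm.gene_ids).get_indexer(present)
    x = np.asarray(norm.values[idx].todense())
    n = x.shape[1]
    ranks = scipy.stats.rankdata(x, axis=1)  # midranks
    score = ((ranks - 0.5) / n).mean(axis=0) - 0.5
    return pd.DataFrame(
        {"barcode": norm.barcodes, "pathway": pathway, "score": score}
    )
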