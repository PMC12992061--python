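"""Wilcoxon rank-sum differential expression on log-normalized counts, with
the study's gene filters, and the cross-sex concordance comparison.

Genes enter testing only if expressed (normalized value > 0) in at least
``min_pct`` of cells in at least one of the two groups ("either" mode; a
"both" mode is available), minus mitochondrial genes, ribosomal genes and a
short list of rRNA-contamination genes. A gene is called significant when
its BH-adjusted p is below 0.05 and its average absolute log2 fold change
exceeds 0.25.

The rank-sum p-value is exact — full permutation distribution of the rank
sum with midranks for ties, computed by dynamic programming — whenever both
groups are small (default <= 25 cells each); otherwise the tie-corrected
normal approximation is used (vectorized across genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import NormalizedMatrix

#: rRNA-contamination genes excluded from DE in mouse synovial data
CONTAMINATION_GENES = ("Gm42418", "Malat1", "Gm26917", "AY036118")

SIG_P_ADJ = 0.05
SIG_ABS_LOG2FC = 0.25


@dataclass
class ExclusionList:
    mito_prefixes: tuple[str, ...] = ("mt-",)
    ribo_prefixes: tuple[str, ...] = ("Rps", "Rpl")
    genes: tuple[str, ...] = CONTAMINATION_GENES

    def matches(self, gene: str) -> bool:
        g = str(gene)
        return (
            g in self.genes
            or any(g.startswith(p) for p in self.mito_prefixes)
            or any(g.startswith(p) for p in self.ribo_prefixes)
        )

    def mask(self, genes) -> np.ndarray:
        return np.array([self.matches(g) for g in genes])


# ---------------------------------------------------------------------------
# Rank-sum p-values
# ---------------------------------------------------------------------------

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p of the rank-sum statistic by DP over the full
    permutation distribution; midranks handle ties (doubled ranks keep the
    arithmetic integral)."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = nx + ny
    ranks2 = np.round(2.0 * scipy.stats.rankdata(pooled)).astype(np.int64)
    w2_obs = int(ranks2[:nx].sum())
    e2 = nx * (n + 1)  # doubled expectation of the rank sum

    t_max = int(ranks2.sum())
    dp = np.zeros((nx + 1, t_max + 1))
    dp[0, 0] = 1.0
    for s in ranks2:
        # descending j: each pooled value used at most once per subset
        for j in range(nx, 0, -1):
            dp[j, s:] += dp[j - 1, : t_max + 1 - s]
    # dp holds exactly-representable integer counts; divide once so an
    # all-inclusive tail gives p = 1.0 exactly
    dev = np.abs(np.arange(t_max + 1) - e2)
    count = dp[nx][dev >= abs(w2_obs - e2)].sum()
    return float(min(1.0, count / comb(n, nx)))


def wilcoxon_p(x, y, exact: bool | None = None, exact_max_n: int = 50) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    ``exact=None`` chooses exact enumeration when the pooled size is at
    most ``exact_max_n``, else the tie-corrected normal approximation with
    continuity correction. All-tied inputs give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if exact is None:
        exact = len(pooled) <= exact_max_n
    if exact:
        return _exact_ranksum_p(x, y)
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _vectorized_asymptotic_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tie-corrected normal-approximation rank-sum p per gene (rows)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(
            a, b, axis=1, alternative="two-sided", method="asymptotic"
        )
        p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def de_test(norm: NormalizedMatrix, cells: pd.DataFrame, group_a: str, group_b: str,
            subpop: str | None = None, min_pct: float = 0.05,
            min_pct_mode: str = "either",
            excl: ExclusionList | None = None,
            group_col: str = "group", subpop_col: str = "subpopulation",
            exact_max_cells: int = 25) -> pd.DataFrame:
    """Wilcoxon DE between two groups (optionally within a subpopulation).

    Returns a DataFrame with ``gene, pct_a, pct_b, avg_log2fc, p, p_adj,
    significant`` sorted by p then gene. ``avg_log2fc`` is computed on
    de-logged means with a pseudocount of 1:
    ``log2((mean(expm1(a)) + 1) / (mean(expm1(b)) + 1))``.
    """
    if min_pct_mode not in ("either", "both"):
        raise ValueError("min_pct_mode must be 'either' or 'both'")
    excl = excl or ExclusionList()

    sel = cells.index
    if subpop is not None:
        sel = cells.index[cells[subpop_col] == subpop]
    sub = cells.loc[sel]
    bars_a = sub.index[sub[group_col] == group_a]
    bars_b = sub.index[sub[group_col] == group_b]
    if len(bars_a) < 3 or len(bars_b) < 3:
        raise ValueError(
            f"need >= 3 cells per group (got {len(bars_a)}, {len(bars_b)})"
        )
    pos = pd.Index(norm.barcodes)
    a = np.asarray(norm.values[:, pos.get_indexer(bars_a)].todense())
    b = np.asarray(norm.values[:, pos.get_indexer(bars_b)].todense())

    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    if min_pct_mode == "either":
        passes = (pct_a >= min_pct) | (pct_b >= min_pct)
    else:
        passes = (pct_a >= min_pct) & (pct_b >= min_pct)
    universe = passes & ~excl.mask(norm.gene_ids)
    if not universe.any():
        warnings.warn("empty gene universe after filters")
        return pd.DataFrame(
            columns=["gene", "pct_a", "pct_b", "avg_log2fc", "p", "p_adj", "significant"]
        )

    a_u, b_u = a[universe], b[universe]
    genes_u = np.asarray(norm.gene_ids)[universe]

    if max(a_u.shape[1], b_u.shape[1]) <= exact_max_cells:
        p = np.array([wilcoxon_p(a_u[i], b_u[i], exact=True) for i in range(len(genes_u))])
    else:
        p = _vectorized_asymptotic_p(a_u, b_u)

    mean_a = np.expm1(a_u).mean(axis=1)
    mean_b = np.expm1(b_u).mean(axis=1)
    avg_log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": genes_u,
            "pct_a": pct_a[universe],
            "pct_b": pct_b[universe],
            "avg_log2fc": avg_log2fc,
            "p": p,
            "p_adj": p_adj,
            "significant": (p_adj < SIG_P_ADJ) & (np.abs(avg_log2fc) > SIG_ABS_LOG2FC),
        }
    )
    return out.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-contrast concordance
# ---------------------------------------------------------------------------

def concordance(de_1: pd.DataFrame, de_2: pd.DataFrame,
                labels: tuple[str, str] = ("contrast1", "contrast2")) -> dict:
    """Compare two DE contrasts (e.g. old-vs-young within each sex) on their
    shared gene universe.

    Per gene the change in expressing-cell percentage, ``pct_a - pct_b``,
    is taken from each contrast; the Pearson correlation between the two
    delta vectors is reported over all shared genes and over the genes
    significant in at least one contrast, together with a per-gene
    classification (significant in both, concordant or opposite direction;
    one contrast only; neither).
    """
    l1, l2 = labels
    merged = de_1.merge(de_2, on="gene", suffixes=("_1", "_2"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared genes; need >= 3")
    d1 = (merged["pct_a_1"] - merged["pct_b_1"]).to_numpy()
    d2 = (merged["pct_a_2"] - merged["pct_b_2"]).to_numpy()
    r, p = scipy.stats.pearsonr(d1, d2)

    sig1 = merged["significant_1"].to_numpy(dtype=bool)
    sig2 = merged["significant_2"].to_numpy(dtype=bool)
    same_sign = np.sign(merged["avg_log2fc_1"]) == np.sign(merged["avg_log2fc_2"])
    cls = np.where(
        sig1 & sig2,
        np.where(same_sign, "both_concordant", "both_opposite"),
        np.where(sig1, f"{l1}_only", np.where(sig2, f"{l2}_only", "neither")),
    )
    either = sig1 | sig2
    if either.sum() >= 3:
        r_sig, p_sig = scipy.stats.pearsonr(d1[either], d2[either])
    else:
        r_sig, p_sig = np.nan, np.nan

    table = pd.DataFrame(
        {
            "gene": merged["gene"],
            f"delta_pct_{l1}": d1,
            f"delta_pct_{l2}": d2,
            f"avg_log2fc_{l1}": merged["avg_log2fc_1"],
            f"avg_log2fc_{l2}": merged["avg_log2fc_2"],
            "classification": cls,
        }
    )
    return {
        "r": float(r),
        "p": float(p),
        "r_significant": float(r_sig) if np.isfinite(r_sig) else None,
        "p_significant": float(p_sig) if np.isfinite(p_sig) else None,
        "n_genes": len(merged),
        "table": table,
    }
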