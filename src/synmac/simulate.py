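"""Synthetic CITE-seq-like count generator with planted ground truth.

Emulates a pooled age x sex factorial design over five synovial macrophage
subpopulations: per-group subpopulation proportions, marker genes,
group/subpopulation-specific expression shifts, mitochondrial reads, a
branching latent pseudotime rooted in infiltrating cells, and an optional
ADT (surface-protein tag) layer. Counts follow a negative binomial law via
a gamma-Poisson mixture with per-gene dispersion; library sizes are
lognormal, truncated above the QC UMI floor unless QC failures are
explicitly planted.

Every quantity downstream modules estimate (proportion shifts, fold
changes, pseudotime densities) is planted here with known truth, so the
statistics can be validated by parameter recovery rather than by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import ConfigError, logger
from .io import CountMatrix, cell_metrics, write_counts, write_table

SUBPOPS = ("Ly6C+", "MHCII+", "CX3CR1+", "CD163+", "Ctsk+")
GROUPS = ("young_M", "old_M", "young_F", "old_F")

# Reported subpopulation percentages by group (infiltrating, monocyte-derived,
# lining, interstitial, osteoclast-like), renormalized to sum to 1.
_STUDY_PROPS = {
    "young_M": (2.1, 14.7, 35.6, 41.9, 4.6),
    "old_M": (8.0, 11.3, 29.8, 41.5, 7.6),
    "young_F": (2.3, 12.9, 32.4, 45.9, 5.3),
    "old_F": (9.5, 17.3, 24.9, 40.8, 5.8),
}


def _norm_props(raw) -> np.ndarray:
    v = np.asarray(raw, dtype=float)
    return v / v.sum()


def default_subpop_props() -> dict[str, np.ndarray]:
    return {g: _norm_props(v) for g, v in _STUDY_PROPS.items()}


@dataclass
class DEEffect:
    """A planted expression shift: gene ``gene`` is multiplied by
    ``2**log2fc`` in cells of ``group`` (optionally restricted to one
    subpopulation)."""

    gene: int
    group: str
    log2fc: float
    subpop: str | None = None


@dataclass
class PseudotimeEffect:
    """A gene whose relative expression follows a sigmoid of latent
    pseudotime t: multiplier ``2 ** (log2_amplitude * sigmoid(slope * (t -
    center)))`` — monotone in t when the sigmoid is."""

    gene: int
    center: float = 0.5
    slope: float = 10.0
    log2_amplitude: float = 2.0


@dataclass
class PseudotimeSpec:
    """Branching latent pseudotime from a root subpopulation.

    Each branch is an ordered subpopulation sequence starting at the root;
    a cell's subpopulation occupies an equal t-interval along its branch.
    ``branch_probs[group][branch]`` weights branch choice when a
    subpopulation sits on several branches; ``t_weights[(branch, group)]``
    is a piecewise-constant density over [0, 1] (bin weights) used to plant
    group-specific density features such as mid-branch depletion.
    """

    root: str = "Ly6C+"
    branches: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            s: ("Ly6C+", s) for s in SUBPOPS if s != "Ly6C+"
        }
    )
    branch_probs: dict[str, dict[str, float]] | None = None
    t_weights: dict[tuple[str, str], np.ndarray] | None = None

    def validate(self):
        for bid, seq in self.branches.items():
            if seq[0] != self.root:
                raise ConfigError(f"branch {bid!r} does not start at root {self.root!r}")


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_cells_per_group: int = 4000
    groups: tuple[str, ...] = GROUPS
    subpop_names: tuple[str, ...] = SUBPOPS
    subpop_props: dict[str, np.ndarray] = field(default_factory=default_subpop_props)
    marker_genes_per_subpop: int = 10
    marker_log2fc: float = 2.0
    de_effects: list[DEEffect] = field(default_factory=list)
    pt_effects: list[PseudotimeEffect] = field(default_factory=list)
    libsize_log_mean: float = float(np.log(9000.0))
    libsize_log_sd: float = 0.25
    nb_dispersion: float = 0.3
    pseudotime_spec: PseudotimeSpec | None = field(default_factory=PseudotimeSpec)
    n_mito_genes: int = 5
    mito_beta: tuple[float, float] = (2.0, 98.0)  # mean mito fraction 0.02
    base_expr_log_sd: float = 1.2
    qc_fail_fraction: float = 0.0
    umi_floor: int = 5000  # libsize truncation target (QC UMI threshold)
    adt_markers: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self):
        if self.n_genes <= 0 or self.n_cells_per_group <= 0:
            raise ConfigError("n_genes and n_cells_per_group must be positive")
        if self.nb_dispersion <= 0 or self.libsize_log_sd <= 0:
            raise ConfigError("count law parameters must be strictly positive")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("duplicate group labels")
        n_sub = len(self.subpop_names)
        for g in self.groups:
            if g not in self.subpop_props:
                raise ConfigError(f"no subpop_props for group {g!r}")
            p = np.asarray(self.subpop_props[g], dtype=float)
            if p.shape != (n_sub,):
                raise ConfigError(
                    f"subpop_props[{g!r}] has length {p.shape[0]}, expected {n_sub}"
                )
            if abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
                raise ConfigError(f"subpop_props[{g!r}] is not a probability vector")
        if self.marker_genes_per_subpop * n_sub + self.n_mito_genes > self.n_genes:
            raise ConfigError("not enough genes for markers + mitochondrial block")
        for eff in self.de_effects:
            if not 0 <= eff.gene < self.n_genes - self.n_mito_genes:
                raise ConfigError(f"DE effect gene index {eff.gene} out of range")
            if eff.group not in self.groups:
                raise ConfigError(f"DE effect group {eff.group!r} not in groups")
            if eff.subpop is not None and eff.subpop not in self.subpop_names:
                raise ConfigError(f"DE effect subpop {eff.subpop!r} unknown")
        if self.pseudotime_spec is not None:
            self.pseudotime_spec.validate()
            if self.pseudotime_spec.root not in self.subpop_names:
                raise ConfigError("pseudotime root is not a subpopulation")


@dataclass
class SimTruth:
    """Ground truth of one simulation: per-cell latent state, per-gene
    annotations, and the exact planted effect list."""

    cells: pd.DataFrame
    genes: pd.DataFrame
    de_effects: list[DEEffect]
    pt_effects: list[PseudotimeEffect]


def gene_names(config: SimConfig) -> np.ndarray:
    """Deterministic gene naming: marker blocks first, then background,
    then the mitochondrial block (``mt-`` prefix)."""
    names = [f"gene{i + 1:05d}" for i in range(config.n_genes - config.n_mito_genes)]
    names += [f"mt-gene{i + 1}" for i in range(config.n_mito_genes)]
    return np.array(names, dtype=object)


def base_expression(config: SimConfig) -> np.ndarray:
    """Baseline relative expression weights for the non-mitochondrial genes,
    drawn from the config seed (so callers can plant effects in genes of
    known baseline)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_genes - config.n_mito_genes
    return rng.lognormal(0.0, config.base_expr_log_sd, size=n)


def marker_gene_indices(config: SimConfig) -> dict[str, np.ndarray]:
    m = config.marker_genes_per_subpop
    return {
        s: np.arange(i * m, (i + 1) * m) for i, s in enumerate(config.subpop_names)
    }


def _sample_t(rng, branch_seq, subpop, weights, n):
    """Sample latent t for cells of ``subpop`` on a branch, restricted to the
    subpopulation's interval, from the branch's piecewise-constant density."""
    m = len(branch_seq)
    pos = branch_seq.index(subpop)
    lo, hi = pos / m, (pos + 1) / m
    if weights is None:
        return rng.uniform(lo, hi, size=n)
    w = np.asarray(weights, dtype=float)
    edges = np.linspace(0.0, 1.0, len(w) + 1)
    # overlap of each bin with [lo, hi], weighted
    left = np.clip(edges[:-1], lo, hi)
    right = np.clip(edges[1:], lo, hi)
    mass = w * np.maximum(right - left, 0.0)
    if mass.sum() <= 0:
        return rng.uniform(lo, hi, size=n)
    mass = mass / mass.sum()
    bins = rng.choice(len(w), size=n, p=mass)
    return rng.uniform(left[bins], right[bins])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_counts(config: SimConfig):
    """Generate ``(CountMatrix, CellTable, SimTruth)`` from a validated
    config. Identical seeds give byte-identical output."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    # stream 0 reserved for base_expression() so it can be re-derived alone
    streams = ss.spawn(6)
    rng_cells = np.random.default_rng(streams[1])
    rng_lib = np.random.default_rng(streams[2])
    rng_counts = np.random.default_rng(streams[3])
    rng_mito = np.random.default_rng(streams[4])
    rng_adt = np.random.default_rng(streams[5])

    n_sub = len(config.subpop_names)
    n_bg = config.n_genes - config.n_mito_genes
    base = base_expression(config)
    markers = marker_gene_indices(config)
    names = gene_names(config)
    spec = config.pseudotime_spec

    cell_rows = []
    count_blocks = []
    adt_cols: dict[str, list[np.ndarray]] = {a: [] for a in config.adt_markers}

    for group in config.groups:
        n_c = config.n_cells_per_group
        props = np.asarray(config.subpop_props[group], dtype=float)
        sub_idx = rng_cells.choice(n_sub, size=n_c, p=props)
        subpops = np.array(config.subpop_names, dtype=object)[sub_idx]

        # branch + latent pseudotime per cell
        t = np.full(n_c, np.nan)
        branch = np.array([""] * n_c, dtype=object)
        if spec is not None:
            bprobs = spec.branch_probs[group] if spec.branch_probs else None
            for s in config.subpop_names:
                on_s = np.where(subpops == s)[0]
                if on_s.size == 0:
                    continue
                cands = [b for b, seq in spec.branches.items() if s in seq]
                if not cands:
                    continue
                if bprobs:
                    w = np.array([max(bprobs.get(b, 0.0), 0.0) for b in cands])
                    w = w / w.sum() if w.sum() > 0 else np.full(len(cands), 1 / len(cands))
                else:
                    w = np.full(len(cands), 1.0 / len(cands))
                chosen = rng_cells.choice(len(cands), size=on_s.size, p=w)
                for bi, b in enumerate(cands):
                    cells_b = on_s[chosen == bi]
                    if cells_b.size == 0:
                        continue
                    branch[cells_b] = b
                    tw = spec.t_weights.get((b, group)) if spec.t_weights else None
                    t[cells_b] = _sample_t(
                        rng_cells, list(spec.branches[b]), s, tw, cells_b.size
                    )

        # library sizes: lognormal truncated above the QC floor
        floor = 1.3 * config.umi_floor
        lib = rng_lib.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n_c)
        for _ in range(100):
            bad = lib < floor
            if not bad.any():
                break
            lib[bad] = rng_lib.lognormal(
                config.libsize_log_mean, config.libsize_log_sd, size=int(bad.sum())
            )
        else:
            lib = np.maximum(lib, floor)
        qc_fail = np.zeros(n_c, dtype=bool)
        if config.qc_fail_fraction > 0:
            qc_fail = rng_lib.random(n_c) < config.qc_fail_fraction
            lib[qc_fail] = rng_lib.lognormal(np.log(1200.0), 0.3, size=int(qc_fail.sum()))

        mito_frac = rng_mito.beta(*config.mito_beta, size=n_c)

        # per-cell relative expression over background genes
        rel = np.tile(base, (n_c, 1))
        for s, gidx in markers.items():
            rows = subpops == s
            if rows.any():
                rel[np.ix_(rows, gidx)] *= 2.0**config.marker_log2fc
        for eff in config.de_effects:
            rows = np.full(n_c, group == eff.group)
            if eff.subpop is not None:
                rows &= subpops == eff.subpop
            if rows.any():
                rel[rows, eff.gene] *= 2.0**eff.log2fc
        if spec is not None:
            for eff in config.pt_effects:
                ok = ~np.isnan(t)
                if ok.any():
                    mult = 2.0 ** (
                        eff.log2_amplitude * _sigmoid(eff.slope * (t[ok] - eff.center))
                    )
                    rel[ok, eff.gene] *= mult

        rel /= rel.sum(axis=1, keepdims=True)
        # mitochondrial block takes fraction mito_frac of each cell's mass
        mean_bg = rel * ((1.0 - mito_frac) * lib)[:, None]
        mean_mt = np.tile(
            np.full(config.n_mito_genes, 1.0 / config.n_mito_genes), (n_c, 1)
        ) * (mito_frac * lib)[:, None]
        mean = np.concatenate([mean_bg, mean_mt], axis=1)

        shape = 1.0 / config.nb_dispersion
        lam = rng_counts.gamma(shape, mean * config.nb_dispersion)
        counts = rng_counts.poisson(lam).astype(np.int64)
        count_blocks.append(sp.csr_matrix(counts.T))  # genes x cells

        for adt_name, gidx in config.adt_markers.items():
            adt_mean = 20.0 + 2000.0 * rel[:, gidx] / max(rel[:, gidx].max(), 1e-12)
            lam_a = rng_adt.gamma(shape, adt_mean * config.nb_dispersion)
            adt_cols[adt_name].append(rng_adt.poisson(lam_a).astype(np.int64))

        age, sex = group.rsplit("_", 1) if "_" in group else (group, "")
        cell_rows.append(
            pd.DataFrame(
                {
                    "barcode": [f"{group}_{i + 1:05d}" for i in range(n_c)],
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "subpopulation": subpops,
                    "true_pseudotime": t,
                    "true_branch": branch,
                    "planted_qc_fail": qc_fail,
                }
            )
        )

    counts = sp.hstack(count_blocks, format="csr")
    cells_truth = pd.concat(cell_rows, ignore_index=True).set_index("barcode")
    cm = CountMatrix(names, np.array(cells_truth.index, dtype=object), counts)

    cells = cell_metrics(cm)
    cells["group"] = cells_truth["group"]
    cells["age"] = cells_truth["age"]
    cells["sex"] = cells_truth["sex"]
    cells["subpopulation"] = cells_truth["subpopulation"]
    cells["doublet_flag"] = False
    cells["low_quality_flag"] = False
    for adt_name, blocks in adt_cols.items():
        cells[f"adt_{adt_name}"] = np.concatenate(blocks)

    marker_of = np.array([""] * config.n_genes, dtype=object)
    for s, gidx in markers.items():
        marker_of[gidx] = s
    genes_truth = pd.DataFrame(
        {
            "gene": names,
            "base_expr": np.concatenate([base, np.zeros(config.n_mito_genes)]),
            "marker_subpop": marker_of,
            "is_mito": [str(g).startswith("mt-") for g in names],
        }
    ).set_index("gene")

    truth = SimTruth(
        cells=cells_truth,
        genes=genes_truth,
        de_effects=list(config.de_effects),
        pt_effects=list(config.pt_effects),
    )
    logger.info(
        "simulated %d genes x %d cells (%d groups)",
        cm.n_genes, cm.n_cells, len(config.groups),
    )
    return cm, cells, truth


def simulate_null(config: SimConfig):
    """As :func:`simulate_counts` but with all group-contrast effects
    (abundance and expression) forced to zero, so groups are exchangeable
    by construction."""
    config.validate()
    mean_props = _norm_props(
        np.mean([np.asarray(config.subpop_props[g], float) for g in config.groups], axis=0)
    )
    spec = config.pseudotime_spec
    if spec is not None:
        # collapse any group-dependence of branch choice and t-density
        shared_bp = None
        shared_tw = None
        if spec.branch_probs:
            first = spec.branch_probs[next(iter(spec.branch_probs))]
            shared_bp = {g: dict(first) for g in config.groups}
        if spec.t_weights:
            by_branch = {}
            for (b, _g), w in spec.t_weights.items():
                by_branch.setdefault(b, w)
            shared_tw = {
                (b, g): by_branch[b] for b in by_branch for g in config.groups
            }
        spec = replace(spec, branch_probs=shared_bp, t_weights=shared_tw)
    null_cfg = replace(
        config,
        de_effects=[],
        subpop_props={g: mean_props.copy() for g in config.groups},
        pseudotime_spec=spec,
    )
    return simulate_counts(null_cfg)


def choose_de_genes(config: SimConfig, n: int, min_quantile: float = 0.5,
                    seed: int | None = None) -> np.ndarray:
    """Pick ``n`` background genes with baseline expression above the given
    quantile, avoiding marker blocks — genes in which a planted fold change
    is observable at realistic depth."""
    base = base_expression(config)
    n_marker = config.marker_genes_per_subpop * len(config.subpop_names)
    candidates = np.arange(n_marker, len(base))
    thresh = np.quantile(base[candidates], min_quantile)
    eligible = candidates[base[candidates] >= thresh]
    if len(eligible) < n:
        raise ConfigError(f"only {len(eligible)} eligible genes for {n} effects")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return np.sort(rng.choice(eligible, size=n, replace=False))


def write_simulation(out_dir: str, cm: CountMatrix, cells: pd.DataFrame,
                     truth: SimTruth, config: SimConfig) -> None:
    """Write the triplet directory, cell metadata, truth tables and a
    machine-readable config echo."""
    import json
    import os

    write_counts(out_dir, cm, cells.reset_index())
    write_table(truth.cells.reset_index(), os.path.join(out_dir, "truth_cells.tsv"))
    write_table(truth.genes.reset_index(), os.path.join(out_dir, "truth_genes.tsv"))
    echo = {
        "n_genes": config.n_genes,
        "n_cells_per_group": config.n_cells_per_group,
        "groups": list(config.groups),
        "subpop_names": list(config.subpop_names),
        "subpop_props": {g: list(map(float, v)) for g, v in config.subpop_props.items()},
        "marker_genes_per_subpop": config.marker_genes_per_subpop,
        "marker_log2fc": config.marker_log2fc,
        "de_effects": [vars(e) for e in config.de_effects],
        "pt_effects": [vars(e) for e in config.pt_effects],
        "libsize_log_mean": config.libsize_log_mean,
        "libsize_log_sd": config.libsize_log_sd,
        "nb_dispersion": config.nb_dispersion,
        "seed": config.seed,
    }
    with open(os.path.join(out_dir, "sim_config.json"), "w") as fh:
        json.dump(echo, fh, indent=1, sort_keys=True)
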