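"""End-to-end orchestration: simulate or ingest counts, QC, embed, then run
every statistic stage, writing one TSV per stage plus a reproducibility
manifest.

The YAML config carries either a ``simulate`` block (SimConfig fields) or
an ``input_dir`` pointing at a triplet directory, the QC and embedding
parameters, the group contrasts, optional GMT path and the trajectory
spec. All randomness derives from the single top-level ``seed`` through
counter-based stream splitting, so a rerun with the same config is
byte-identical; the manifest carries no timestamps for the same reason.
"""

from __future__ import annotations

import json
import os
from dataclasses import fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import ConfigError, logger, spawn_rngs
from . import composition as comp_mod
from . import diffexpr, enrichment, sample_stats, trajectory
from .io import read_counts, read_gmt, write_table
from .preprocess import QCParams, apply_qc, compute_pca, lognormalize, select_hvg
from .simulate import (
    DEEffect,
    PseudotimeEffect,
    PseudotimeSpec,
    SimConfig,
    simulate_counts,
    write_simulation,
)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are already on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config file must hold a mapping")
    if "simulate" not in cfg and "input_dir" not in cfg:
        raise ConfigError("config needs either a 'simulate' block or 'input_dir'")
    return cfg


def _sim_config_from_dict(block: dict, seed: int) -> SimConfig:
    known = {f.name for f in dc_fields(SimConfig)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    kwargs = dict(block)
    if "groups" in kwargs:
        kwargs["groups"] = tuple(kwargs["groups"])
    if "subpop_names" in kwargs:
        kwargs["subpop_names"] = tuple(kwargs["subpop_names"])
    if "subpop_props" in kwargs:
        kwargs["subpop_props"] = {
            g: np.asarray(v, dtype=float) for g, v in kwargs["subpop_props"].items()
        }
    if "de_effects" in kwargs:
        kwargs["de_effects"] = [DEEffect(**e) for e in kwargs["de_effects"]]
    if "pt_effects" in kwargs:
        kwargs["pt_effects"] = [PseudotimeEffect(**e) for e in kwargs["pt_effects"]]
    if "pseudotime_spec" in kwargs:
        spec = kwargs["pseudotime_spec"]
        if spec is not None:
            spec = dict(spec)
            if "branches" in spec:
                spec["branches"] = {b: tuple(s) for b, s in spec["branches"].items()}
            kwargs["pseudotime_spec"] = PseudotimeSpec(**spec)
    kwargs.setdefault("seed", seed)
    return SimConfig(**kwargs)


def run_pipeline(config: dict | str, out_dir: str | None = None) -> dict:
    """Execute every stage; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    if isinstance(config, str):
        config = load_config(config)
    out_dir = out_dir or config.get("output_dir", "synmac_out")
    os.makedirs(out_dir, exist_ok=True)
    seed = int(config.get("seed", 0))
    rngs = spawn_rngs(seed, 8)
    n_perm = int(config.get("n_permutations", 10000))

    manifest: dict = {
        "synmac_version": __version__,
        "seed": seed,
        "n_permutations": n_perm,
        "config": _jsonable(config),
        "stages": {},
    }

    def record(stage: str, n_rows: int, path: str | None = None):
        rel = os.path.relpath(path, out_dir) if path else None
        manifest["stages"][stage] = {"rows": int(n_rows), "output": rel}
        logger.info("[%s] %d rows%s", stage, n_rows, f" -> {path}" if path else "")

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # persist what we have, then halt
            _write_manifest(manifest, out_dir)
            raise StageError(name, exc) from exc

    # --- counts ----------------------------------------------------------
    def stage_counts():
        if "simulate" in config:
            sim_cfg = _sim_config_from_dict(dict(config["simulate"] or {}), seed)
            cm, cells, truth = simulate_counts(sim_cfg)
            sim_dir = os.path.join(out_dir, "simulated")
            write_simulation(sim_dir, cm, cells, truth, sim_cfg)
            record("simulate", cm.n_cells, sim_dir)
            return cm, cells
        cm, cells = read_counts(config["input_dir"])
        record("ingest", cm.n_cells, config["input_dir"])
        return cm, cells

    cm, cells = run_stage("counts", stage_counts)

    # --- QC ---------------------------------------------------------------
    def stage_qc():
        params = QCParams(**(config.get("qc") or {}))
        cm_f, cells_f, report = apply_qc(cm, cells, params)
        path = os.path.join(out_dir, "qc_report.tsv")
        write_table(report.to_frame(), path)
        record("qc", report.n_retained, path)
        return cm_f, cells_f

    cm, cells = run_stage("qc", stage_qc)

    # --- normalize + embed -------------------------------------------------
    def stage_embed():
        emb_cfg = config.get("embedding") or {}
        norm = lognormalize(cm, scale=float(emb_cfg.get("scale", 1e4)))
        hvg = select_hvg(norm, n=min(int(emb_cfg.get("n_hvg", 2000)), cm.n_genes))
        emb = compute_pca(norm, hvg, n_pcs=int(emb_cfg.get("n_pcs", 20)))
        path = os.path.join(out_dir, "embedding.tsv")
        write_table(emb.to_frame(), path)
        record("embed", len(emb.barcodes), path)
        return norm, emb

    norm, emb = run_stage("embed", stage_embed)

    contrasts = [tuple(c) for c in config.get("contrasts") or []]
    for ga, gb in contrasts:
        present = set(cells["group"])
        if ga not in present or gb not in present:
            raise ConfigError(f"contrast ({ga}, {gb}) references unknown groups")

    # --- composition --------------------------------------------------------
    def stage_composition():
        frames = []
        for ga, gb in contrasts:
            res = comp_mod.proportion_test(
                cells, ga, gb, n_perm=n_perm, seed=rngs[1]
            )
            res.insert(0, "contrast", f"{ga}_vs_{gb}")
            frames.append(res)
        if not frames:
            return 0
        df = pd.concat(frames, ignore_index=True)
        path = os.path.join(out_dir, "composition.tsv")
        write_table(df, path)
        record("composition", len(df), path)
        return len(df)

    run_stage("composition", stage_composition)

    # --- sample statistics ---------------------------------------------------
    def stage_sample_stats():
        het = sample_stats.intercellular_heterogeneity(emb, cells)
        het_df = pd.DataFrame(
            [
                {
                    "group": h.sample_group,
                    "n_cells": h.n_cells,
                    "mean_centroid_distance": h.mean_centroid_distance,
                }
                for h in het
            ]
        )
        write_table(het_df, os.path.join(out_dir, "heterogeneity.tsv"))
        div = sample_stats.divergence_by_group(
            cm, cells, n_draws=int(config.get("divergence_draws", 25)), seed=rngs[2]
        )
        div_df = pd.DataFrame(
            [
                {
                    "group": d.sample_group,
                    "target_depth": d.target_depth,
                    "divergence": d.divergence,
                    "divergence_sd": d.divergence_sd,
                    "n_draws": d.n_draws,
                }
                for d in div
            ]
        )
        path = os.path.join(out_dir, "divergence.tsv")
        write_table(div_df, path)
        record("sample_stats", len(het_df) + len(div_df), path)

    run_stage("sample_stats", stage_sample_stats)

    # --- differential expression ----------------------------------------------
    de_tables: dict[tuple[str, str, str], pd.DataFrame] = {}

    def stage_de():
        de_cfg = config.get("de") or {}
        min_pct = float(de_cfg.get("min_pct", 0.05))
        subpops = de_cfg.get("subpops") or sorted(cells["subpopulation"].unique())
        n_rows = 0
        for ga, gb in contrasts:
            for sp_name in subpops:
                in_sp = cells["subpopulation"] == sp_name
                n_a = int((in_sp & (cells["group"] == ga)).sum())
                n_b = int((in_sp & (cells["group"] == gb)).sum())
                if min(n_a, n_b) < 3:
                    logger.info(
                        "[de] skipping %s %s vs %s (%d, %d cells)",
                        sp_name, ga, gb, n_a, n_b,
                    )
                    continue
                res = diffexpr.de_test(
                    norm, cells, ga, gb, subpop=sp_name, min_pct=min_pct
                )
                de_tables[(sp_name, ga, gb)] = res
                out = res.copy()
                out.insert(0, "subpopulation", sp_name)
                out.insert(0, "contrast", f"{ga}_vs_{gb}")
                fname = f"de_{sp_name.replace('+', '')}_{ga}_vs_{gb}.tsv"
                write_table(out, os.path.join(out_dir, fname))
                n_rows += len(out)
        record("de", n_rows)

    run_stage("de", stage_de)

    # --- cross-contrast concordance ---------------------------------------------
    def stage_concordance():
        if len(contrasts) < 2:
            return
        (a1, b1), (a2, b2) = contrasts[0], contrasts[1]
        rows = []
        for sp_name in sorted({k[0] for k in de_tables}):
            de1 = de_tables.get((sp_name, a1, b1))
            de2 = de_tables.get((sp_name, a2, b2))
            if de1 is None or de2 is None:
                continue
            try:
                res = diffexpr.concordance(de1, de2)
            except ValueError:
                continue
            rows.append(
                {
                    "subpopulation": sp_name,
                    "r": res["r"],
                    "p": res["p"],
                    "r_significant": res["r_significant"],
                    "n_genes": res["n_genes"],
                }
            )
        if rows:
            df = pd.DataFrame(rows)
            path = os.path.join(out_dir, "concordance.tsv")
            write_table(df, path)
            record("concordance", len(df), path)

    run_stage("concordance", stage_concordance)

    # --- enrichment -----------------------------------------------------------
    def stage_enrichment():
        enr_cfg = config.get("enrichment") or {}
        gmt_path = enr_cfg.get("gmt")
        if not gmt_path:
            return
        sets = read_gmt(gmt_path)
        n_rows = 0
        for (sp_name, ga, gb), de in sorted(de_tables.items()):
            if len(de) < 50:
                continue
            ranked = enrichment.compute_weights(de)
            res = enrichment.permutation_enrichment(
                ranked, sets, n_perm=n_perm, seed=rngs[3],
                min_size=int(enr_cfg.get("min_size", 10)),
            )
            if len(res) == 0:
                continue
            res.insert(0, "subpopulation", sp_name)
            res.insert(0, "contrast", f"{ga}_vs_{gb}")
            fname = f"enrichment_{sp_name.replace('+', '')}_{ga}_vs_{gb}.tsv"
            write_table(res, os.path.join(out_dir, fname))
            n_rows += len(res)
        record("enrichment", n_rows)

    run_stage("enrichment", stage_enrichment)

    # --- trajectory -----------------------------------------------------------
    def stage_trajectory():
        tr_cfg = config.get("trajectory") or {}
        root = tr_cfg.get("root", "Ly6C+")
        if root not in set(cells["subpopulation"]):
            logger.info("[trajectory] root %r absent; stage skipped", root)
            return
        k = int(tr_cfg.get("k", 15))
        pt = trajectory.assign_pseudotime(emb, cells, root_subpop=root, k=k)
        write_table(pt.reset_index(), os.path.join(out_dir, "pseudotime.tsv"))
        terminals = tr_cfg.get("terminals") or [
            s for s in sorted(cells["subpopulation"].unique()) if s != root
        ]
        branches = trajectory.extract_branches(
            emb, cells, terminals, root_subpop=root, k=k
        )
        write_table(branches.reset_index(), os.path.join(out_dir, "branches.tsv"))
        frames = []
        for bid in branches.columns:
            try:
                frames.append(
                    trajectory.branch_density(
                        pt, branches, cells, bid,
                        grid_size=int(tr_cfg.get("grid_size", 200)),
                    )
                )
            except ValueError as exc:
                logger.info("[trajectory] branch %s: %s", bid, exc)
        n_rows = len(pt)
        if frames:
            dens = pd.concat(frames, ignore_index=True)
            path = os.path.join(out_dir, "branch_density.tsv")
            write_table(dens, path)
            n_rows += len(dens)
        record("trajectory", n_rows)

    run_stage("trajectory", stage_trajectory)

    _write_manifest(manifest, out_dir)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
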