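"""End-to-end orchestration: rarefy -> partition -> diversity -> spatial ->
network -> assembly -> environmental attribution, from one config."""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .assembly import (
    beta_nti_from_dist,
    classify_processes,
    process_fractions,
    raup_crick_bray,
)
from .cooccurrence import (
    er_null_ensemble,
    fit_degree_distribution,
    keystones,
    o_r_ratios,
    prevalence_filter,
    spearman_edges,
    topology,
)
from .core_io import (
    AsvTable,
    SampleMetadata,
    goods_coverage,
    patristic_matrix,
    rarefy,
    read_asv_table,
    read_metadata,
    read_tree,
    write_distance_matrix,
)
from .diversity import alpha_diversity_table, bray_curtis, unweighted_unifrac
from .envstats import (
    env_distance,
    kruskal_wallis,
    mantel_table,
    vpa_two_sets,
)
from .partition import classify_asvs, partition_summary, subcommunity
from .spatial import anosim, distance_decay, pairwise_anosim
from .synthetic import SimulationConfig, sample_communities

logger = logging.getLogger("asvkit")

NATURAL_FACTORS = ["WT", "pH", "river_flow", "channel_slope"]
NUTRIENT_FACTORS = ["NH3-N", "NO3-N", "TN", "TOC", "TP"]


@dataclass
class PipelineConfig:
    # inputs: either file paths or a simulation block
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    simulation: dict | None = None
    # thresholds
    rarefaction_depth: int | None = None
    rare_cut: float = 1e-4
    abundant_cut: float = 1e-2
    rho_min: float = 0.8
    alpha: float = 0.01
    prevalence: float = 0.2
    nti_cut: float = 2.0
    rc_cut: float = 0.95
    keystone_degree_min: float = 100.0
    keystone_betweenness_max: float = 5000.0
    # replicate counts (pipeline-scale defaults; raise for full analyses)
    er_reps: int = 1000
    n_null: int = 199
    n_perm: int = 999
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not (0 < self.rare_cut < self.abundant_cut <= 1):
            raise ValueError("invalid abundance cuts")
        if not (0 <= self.prevalence <= 1 and 0 < self.alpha < 1):
            raise ValueError("invalid network thresholds")
        if self.simulation is None and self.table_path is None:
            raise ValueError("either input paths or a simulation block required")


def _stage_seed(master: int, stage: str) -> int:
    """Derive a stable per-stage seed from the master seed."""
    h = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([master, h]).generate_state(1)[0])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "stages": {},
    }

    def stage(name):
        t0 = time.time()

        def done(**extra):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 2), **extra}
            logger.info("stage %s done in %.2fs", name, time.time() - t0)

        return done

    # ---- inputs ----------------------------------------------------------
    done = stage("load")
    if cfg.simulation is not None:
        sim = SimulationConfig(**{**cfg.simulation, "seed": cfg.seed})
        ds = sample_communities(sim)
        table, tree, meta = ds.table, ds.tree, ds.metadata
    else:
        table = read_asv_table(cfg.table_path)
        tree = read_tree(cfg.tree_path)
        meta = read_metadata(cfg.metadata_path)
    done(n_samples=table.n_samples, n_asvs=table.n_asvs)

    # ---- rarefaction & coverage -----------------------------------------
    done = stage("rarefy")
    table = rarefy(table, depth=cfg.rarefaction_depth,
                   seed=_stage_seed(cfg.seed, "rarefy"))
    coverage = goods_coverage(table)
    coverage.to_csv(out / "goods_coverage.tsv", sep="\t")
    done(depth=int(table.sample_totals()[0]))

    meta = meta.aligned_to(table.sample_ids)
    season = meta.frame["season"].to_dict()
    landform = meta.frame["landform"].to_dict()

    # ---- partition -------------------------------------------------------
    done = stage("partition")
    part = classify_asvs(table, cfg.rare_cut, cfg.abundant_cut)
    part.assignments.to_csv(out / "partition.tsv", sep="\t")
    partition_summary(part, table).to_csv(out / "partition_summary.tsv",
                                          sep="\t", index=False)
    done(categories=part.richness_counts().to_dict())

    # ---- alpha & beta diversity -----------------------------------------
    done = stage("diversity")
    alpha = alpha_diversity_table(table, tree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    bray = bray_curtis(table)
    write_distance_matrix(bray, out / "bray_curtis.tsv")
    unifrac = unweighted_unifrac(table, tree)
    write_distance_matrix(unifrac, out / "unweighted_unifrac.tsv")
    done()

    # ---- spatial patterns ------------------------------------------------
    done = stage("spatial")
    decay = distance_decay(bray, meta, n_perm=cfg.n_perm,
                           seed=_stage_seed(cfg.seed, "decay"))
    rows = [{"beta": "bray_curtis", **asdict(decay)}]
    pd.DataFrame(rows).to_csv(out / "distance_decay.tsv", sep="\t", index=False)
    anosim_rows = []
    for grouping, labels in (("season", season), ("landform", landform)):
        vals = [labels[s] for s in bray.ids]
        if len(set(vals)) >= 2:
            res = anosim(bray, vals, n_perm=cfg.n_perm,
                         seed=_stage_seed(cfg.seed, "anosim"), grouping=grouping)
            anosim_rows.append(
                {"grouping": grouping, "r": res.r_statistic, "p": res.p_value}
            )
    pd.DataFrame(anosim_rows).to_csv(out / "anosim.tsv", sep="\t", index=False)
    pairwise_anosim(bray, [landform[s] for s in bray.ids], n_perm=cfg.n_perm,
                    seed=_stage_seed(cfg.seed, "panosim")).to_csv(
        out / "pairwise_anosim_landform.tsv", sep="\t", index=False)
    done()

    # ---- co-occurrence network ------------------------------------------
    done = stage("network")
    filtered = prevalence_filter(table, cfg.prevalence)
    cat_map = part.assignments["category"].to_dict()
    net = spearman_edges(filtered, cfg.rho_min, cfg.alpha,
                         node_attrs={"category": cat_map})
    net.edges_frame().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nx.write_graphml(net.graph, out / "network.graphml")
    manifest["network"] = {"nodes": len(net.nodes), "edges": net.n_edges}
    if net.n_edges > 0:
        topo = topology(net)
        topo.to_csv(out / "node_topology.tsv", sep="\t")
        keys = keystones(topo, cfg.keystone_degree_min, cfg.keystone_betweenness_max)
        (out / "keystones.txt").write_text("\n".join(keys) + "\n")
        ens = er_null_ensemble(len(net.nodes), net.n_edges, reps=cfg.er_reps,
                               seed=_stage_seed(cfg.seed, "er"))
        groups = {v: (cat_map.get(v) or "NA") for v in net.nodes}
        o_r_ratios(net, groups, ens).to_csv(out / "o_r_ratios.tsv", sep="\t",
                                            index=False)
        for model in ("power_law", "gaussian"):
            try:
                fit = fit_degree_distribution(net, model)
                manifest["stages"].setdefault("degree_fits", {})[model] = {
                    "adj_r2": fit.adjusted_r_squared
                }
            except ValueError as exc:
                logger.warning("degree fit %s skipped: %s", model, exc)
    done()

    # ---- assembly processes ---------------------------------------------
    done = stage("assembly")
    dist_full = patristic_matrix(tree, table.asv_ids)
    asv_pos = {a: i for i, a in enumerate(table.asv_ids)}
    sub_defs = {"ART": ["ART"], "CRT": ["CRT"], "CRAT": ["CRAT"], "all": None}
    frac_rows = []
    pair_frames = []
    for name, cats in sub_defs.items():
        sub = table if cats is None else subcommunity(table, part, cats)
        if sub.n_asvs < 2:
            continue
        usable = sub.sample_totals() > 0
        if usable.sum() < 3:
            continue
        sub = sub.select_samples([s for s, u in zip(sub.sample_ids, usable) if u])
        idx = [asv_pos[a] for a in sub.asv_ids]
        d_sub = dist_full[np.ix_(idx, idx)]
        nti = beta_nti_from_dist(sub.counts, d_sub, sub.sample_ids,
                                 n_null=cfg.n_null,
                                 seed=_stage_seed(cfg.seed, f"nti-{name}"))
        rc = raup_crick_bray(sub, n_null=cfg.n_null,
                             seed=_stage_seed(cfg.seed, f"rc-{name}"))
        cls = classify_processes(nti, rc, cfg.nti_cut, cfg.rc_cut)
        pair_frames.append(cls.pairs.assign(subcommunity=name))
        fr = process_fractions(cls, strata=season)
        frac_rows.append(fr.assign(subcommunity=name))
    if pair_frames:
        pd.concat(pair_frames).to_csv(out / "assembly_pairs.tsv", sep="\t",
                                      index=False)
        pd.concat(frac_rows).to_csv(out / "process_fractions.tsv", sep="\t",
                                    index=False)
    done()

    # ---- environmental attribution --------------------------------------
    done = stage("envstats")
    factors = [f for f in meta.env_matrix().columns]
    geo = env_distance(meta, "dist_to_mouth_km")
    mt = mantel_table({"bray_curtis": bray}, meta, factors, n_perm=cfg.n_perm,
                      seed=_stage_seed(cfg.seed, "mantel"))
    mt.to_csv(out / "mantel.tsv", sep="\t", index=False)
    pm = mantel_table({"bray_curtis": bray}, meta, factors, n_perm=cfg.n_perm,
                      seed=_stage_seed(cfg.seed, "pmantel"), control=geo)
    pm.to_csv(out / "partial_mantel.tsv", sep="\t", index=False)
    natural = [f for f in NATURAL_FACTORS if f in factors]
    nutrients = [f for f in NUTRIENT_FACTORS if f in factors]
    if natural and nutrients and table.n_samples > len(natural) + len(nutrients) + 1:
        vpa = vpa_two_sets(table, meta.env_matrix(natural),
                           meta.env_matrix(nutrients))
        with open(out / "vpa.json", "w") as fh:
            json.dump({"a": vpa.a, "b": vpa.b, "c": vpa.c, "d": vpa.d,
                       "raw": vpa.raw}, fh, indent=2)
    kw_rows = []
    lf = meta.frame["landform"]
    if lf.nunique() >= 2:
        for f in factors:
            groups = [g.to_numpy() for _, g in meta.frame[f].groupby(lf)
                      if len(g) > 0]
            if len(groups) >= 2:
                h, p = kruskal_wallis(groups)
                kw_rows.append({"factor": f, "H": h, "p": p})
    pd.DataFrame(kw_rows).to_csv(out / "kruskal_wallis_landform.tsv", sep="\t",
                                 index=False)
    done()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
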