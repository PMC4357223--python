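"""Stage orchestration: simulate, build, decompose, map, stats, profile.

Each stage reads its inputs from disk, writes TSV/JSON artifacts into the
output directory, and is idempotent given identical inputs and seed.  A
manifest records the config hash, seeds, and record counts at every stage
boundary.  The single global seed fans out to per-stage seeds by fixed
offsets so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import io as dio
from . import kcore, mapping, network, profile, simulate, stats

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets
SEED_OFFSET_SIMULATE = 0
SEED_OFFSET_ENSEMBLES = 10_000


@dataclass
class RunConfig:
    """All inputs, thresholds, and seeds for one pipeline run."""

    outdir: str = "dcnmut_out"
    domain_hits: Optional[str] = None
    gene_models: Optional[str] = None
    mutations: Dict[str, str] = field(default_factory=dict)  # condition label -> MAF path
    conservation: Optional[str] = None
    e_value_max: float = network.DEFAULT_EVALUE_MAX
    lfdr_threshold: float = stats.DEFAULT_LFDR_THRESHOLD
    lfdr_bins: int = 120
    lfdr_degree: int = 7
    lfdr_null_method: str = "central-matching"
    lfdr_log_transform: bool = False
    n_replicates: int = 100
    seed: int = 0
    simulate: Dict[str, object] = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if self.e_value_max <= 0 or self.lfdr_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _outdir(cfg: RunConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _update_manifest(cfg: RunConfig, stage: str, info: Dict[str, object]) -> None:
    path = _outdir(cfg) / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest["config_hash"] = cfg.config_hash()
    manifest["seed"] = cfg.seed
    manifest.setdefault("stages", {})[stage] = info
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def cmd_simulate(cfg: RunConfig) -> RunConfig:
    """Generate a synthetic fixture set and point the config's inputs at it."""
    out = _outdir(cfg)
    sim_cfg = simulate.SimConfig(seed=cfg.seed + SEED_OFFSET_SIMULATE, **cfg.simulate)
    ds = simulate.simulate_dataset(sim_cfg)
    dio.write_pfamscan(ds.hits, out / "domain_hits.pfamscan.tsv")
    dio.write_gene_models(ds.models, out / "gene_models.tsv")
    dio.write_maf(ds.mutations, out / "mutations.SYN.maf")
    dio.write_conservation(ds.conservation, out / "conservation.tsv")
    (out / "truth.json").write_text(json.dumps(ds.truth.to_json_dict(), indent=2) + "\n")
    cfg.domain_hits = str(out / "domain_hits.pfamscan.tsv")
    cfg.gene_models = str(out / "gene_models.tsv")
    cfg.mutations = {"SYN": str(out / "mutations.SYN.maf")}
    cfg.conservation = str(out / "conservation.tsv")
    _update_manifest(cfg, "simulate", {
        "n_hits": len(ds.hits), "n_proteins": len(ds.models),
        "n_mutations": len(ds.mutations), "n_hot_domains": len(ds.truth.hot_domains),
    })
    return cfg


def _require(cfg: RunConfig, attr: str, producer: str):
    value = getattr(cfg, attr)
    if not value:
        raise FileNotFoundError(
            f"RunConfig.{attr} is unset; run '{producer}' first or point it at an input file"
        )
    return value


def cmd_build(cfg: RunConfig) -> None:
    """Build the DCN, keep the largest component, write edges and stats."""
    out = _outdir(cfg)
    hits = dio.read_pfamscan(_require(cfg, "domain_hits", "simulate"))
    dcn = network.build_dcn(hits, e_value_max=cfg.e_value_max)
    main = network.largest_component(dcn)
    dio.write_edge_list(main, out / "dcn_edges.tsv")
    for name, table in network.network_stats(main).items():
        dio.write_table(table, out / f"network_{name}.tsv")
    _update_manifest(cfg, "build", {
        "n_hits": len(hits), "nodes_total": dcn.number_of_nodes(),
        "nodes_main": main.number_of_nodes(), "edges_main": main.number_of_edges(),
    })


def cmd_decompose(cfg: RunConfig) -> None:
    """k-core decomposition of the built network; coreness table."""
    out = _outdir(cfg)
    edges = out / "dcn_edges.tsv"
    if not edges.exists():
        raise FileNotFoundError(f"{edges} missing; run 'build' first")
    g = dio.read_edge_list(edges)
    decomp = kcore.decompose(g)
    table = pd.DataFrame(
        sorted(decomp.coreness.items()), columns=["domain_acc", "coreness"]
    )
    dio.write_table(table, out / "coreness.tsv")
    _update_manifest(cfg, "decompose", {"k_max": decomp.k_max, "core_sizes": decomp.core_sizes()})


def cmd_map(cfg: RunConfig) -> None:
    """Footprints plus filtered mutation counts per condition."""
    out = _outdir(cfg)
    hits = network.filter_hits(
        dio.read_pfamscan(_require(cfg, "domain_hits", "simulate")), cfg.e_value_max
    )
    models = {m.protein_id: m for m in dio.read_gene_models(_require(cfg, "gene_models", "simulate"))}
    footprints = mapping.build_footprints(hits, models)
    dio.write_bed(footprints, out / "footprints.bed")
    info: Dict[str, object] = {"n_domains": len(footprints)}
    if not cfg.mutations:
        raise FileNotFoundError("RunConfig.mutations is empty; run 'simulate' or supply MAF paths")
    for label, maf in sorted(cfg.mutations.items()):
        records = dio.read_maf(maf, cancer_type=label)
        kept = mapping.filter_mutations(records)
        counts = mapping.map_mutations(kept, footprints)
        table = pd.DataFrame(sorted(counts.counts.items()), columns=["domain_acc", "m"])
        dio.write_table(table, out / f"counts.{label}.tsv")
        info[label] = {
            "n_records": len(records), "n_after_filter": len(kept),
            "mapped": counts.mapped, "mapped_percentage": round(counts.mapped_percentage, 4),
        }
    _update_manifest(cfg, "map", info)


def _load_footprints(cfg: RunConfig) -> Dict[str, mapping.DomainFootprint]:
    hits = network.filter_hits(
        dio.read_pfamscan(_require(cfg, "domain_hits", "simulate")), cfg.e_value_max
    )
    models = {m.protein_id: m for m in dio.read_gene_models(_require(cfg, "gene_models", "simulate"))}
    return mapping.build_footprints(hits, models)


def cmd_stats(cfg: RunConfig) -> None:
    """Per-condition domain statistics tables and the cross-condition overlap."""
    out = _outdir(cfg)
    footprints = _load_footprints(cfg)
    significant_sets: Dict[str, set] = {}
    info: Dict[str, object] = {}
    for label in sorted(cfg.mutations):
        counts_path = out / f"counts.{label}.tsv"
        if not counts_path.exists():
            raise FileNotFoundError(f"{counts_path} missing; run 'map' first")
        m = dict(dio.read_table(counts_path)[["domain_acc", "m"]].itertuples(index=False, name=None))
        counts = mapping.DomainMutationCounts(counts=m, total=0, mapped=0)
        table, fit = stats.compute_domain_stats(
            counts, footprints,
            lfdr_threshold=cfg.lfdr_threshold, bins=cfg.lfdr_bins,
            poly_degree=cfg.lfdr_degree, null_method=cfg.lfdr_null_method,
            log_transform=cfg.lfdr_log_transform,
        )
        dio.write_table(table, out / f"domain_stats.{label}.tsv")
        significant_sets[label] = set(stats.call_significant(table, cfg.lfdr_threshold))
        info[label] = {
            "n_significant": len(significant_sets[label]),
            "pi0": round(fit.pi0, 6), "delta0": round(fit.delta0, 6),
            "sigma0": round(fit.sigma0, 6),
        }
    if len(significant_sets) >= 2:
        overlap = stats.overlap_sets(significant_sets)
        report = {
            "regions": {"+".join(k): v for k, v in overlap["regions"].items()},
            "intersection": overlap["intersection"],
            "union_size": overlap["union_size"],
        }
        (out / "overlap.json").write_text(json.dumps(report, indent=2) + "\n")
        info["intersection_size"] = len(overlap["intersection"])
    _update_manifest(cfg, "stats", info)


def cmd_profile(cfg: RunConfig, plots: bool = True) -> None:
    """Per-core profiles, randomization trend tests, and the chi-square GOF."""
    out = _outdir(cfg)
    coreness_path = out / "coreness.tsv"
    if not coreness_path.exists():
        raise FileNotFoundError(f"{coreness_path} missing; run 'decompose' first")
    coreness = dict(
        dio.read_table(coreness_path)[["domain_acc", "coreness"]].itertuples(index=False, name=None)
    )
    decomp = kcore.CoreDecomposition(coreness={k: int(v) for k, v in coreness.items()})
    g = dio.read_edge_list(out / "dcn_edges.tsv")
    ensembles = kcore.random_ensembles(
        g, decomp, n_replicates=cfg.n_replicates, seed=cfg.seed + SEED_OFFSET_ENSEMBLES
    )
    footprints = _load_footprints(cfg)
    conservation = None
    if cfg.conservation:
        conservation = {l.domain_acc: l.conserved for l in dio.read_conservation(cfg.conservation)}

    info: Dict[str, object] = {}
    for label in sorted(cfg.mutations):
        table = dio.read_table(out / f"domain_stats.{label}.tsv")
        significant = set(stats.call_significant(table, cfg.lfdr_threshold))
        prof = profile.profile_cores(decomp, ensembles, table, conservation, significant)
        dio.write_table(prof, out / f"core_profile.{label}.tsv")
        s_attr = dict(zip(table["domain_acc"], table["s"]))
        trend = profile.trend_test(prof, ensembles, s_attr)
        m_attr = dict(zip(table["domain_acc"], table["m"]))
        gof = profile.chi_square_cores(decomp, footprints, m_attr)
        dio.write_table(
            pd.DataFrame({"k": gof.shells, "observed": gof.observed, "expected": gof.expected}),
            out / f"chi_square.{label}.tsv",
        )
        info[label] = {
            "trend_spearman": round(trend.statistic, 6),
            "trend_p_empirical": round(trend.p_empirical, 6),
            "trend_direction": trend.direction,
            "chi2": round(gof.statistic, 4), "chi2_dof": gof.dof,
            "chi2_p": float(f"{gof.p_value:.6g}"),
        }
        if plots:
            profile.plot_core_profile(prof, "mean_s", out / f"fig_mean_s.{label}.png",
                                      "mean normalized mutation score")
            profile.plot_core_profile(prof, "pct_significant", out / f"fig_pct_significant.{label}.png",
                                      "% significantly mutated domains")
            if conservation is not None:
                profile.plot_core_profile(prof, "pct_conserved", out / f"fig_pct_conserved.{label}.png",
                                          "% conserved domains")
            profile.plot_observed_expected(gof, out / f"fig_chi_square.{label}.png")
    _update_manifest(cfg, "profile", info)


def cmd_run_all(cfg: RunConfig, do_simulate: bool = None, plots: bool = True) -> None:
    """Run every stage in order; simulates inputs when none are configured."""
    if do_simulate is None:
        do_simulate = cfg.domain_hits is None
    if do_simulate:
        cmd_simulate(cfg)
    cmd_build(cfg)
    cmd_decompose(cfg)
    cmd_map(cfg)
    cmd_stats(cfg)
    cmd_profile(cfg, plots=plots)
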