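"""End-to-end orchestration: filter -> cluster -> promoters -> scan ->
enrichment -> de novo discovery -> network, from a single flat config.

Stages communicate only through files in the output directory, so any
stage can be inspected or re-run.  A run is a pure function of its config
and seed: re-running with the same inputs reproduces the outputs byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coexpress import ClusterConfig, build_clusters, write_clusters_tsv
from .composites import (
    CompositeConfig,
    enrich_composites,
    single_tfbs_enrichment,
    write_enrichment_tsv,
)
from .denovo import DenovoConfig, discover_all, match_library, write_matches_tsv, write_meme, estimate_background
from .exprdata import (
    FilterConfig,
    RatioMatrix,
    diet_within_time,
    filter_panel,
    filter_timeseries,
    read_expression,
)
from .motifscan import MatchConfig, parse_transfac, presence_map, scan_promoters, write_hits_tsv
from .network import HubConfig, build_network, gene_significance_from_pvalues, hub_genes, write_modules_tsv
from .promoters import (
    build_background,
    extract_promoter,
    load_genome,
    masked_view,
    read_tss,
    write_promoters_fasta,
)

log = logging.getLogger("lsgkit")


@dataclass
class PipelineConfig:
    expression: str = ""
    metadata: str = ""
    present: str = ""
    pvals: str = ""
    ratios: str = ""
    genome: str = ""
    tss_bed: str = ""
    pwm_file: str = ""
    seeds_file: str = ""  # one seed (LST) gene id per line
    outdir: str = "lsg_out"
    mode: str = "panel"  # panel | timeseries
    seed: int = 0
    min_intensity: float = 250.0
    sig_p: float = 0.05
    seed_r: float = 0.90
    avg_r: float = 0.75
    fold: float = 2.0
    core_threshold: float = 0.9
    matrix_threshold: float = 0.85
    d_min: tuple[int, ...] = (20, 50, 100)
    d_max: int = 250
    alpha: float = 0.1
    denovo_width_min: int = 6
    denovo_width_max: int = 16
    denovo_restarts: int = 100
    beta: int = 8
    gs_cutoff: float = 1.2
    k_ratio_cutoff: float = 0.95
    n_hubs: int = 5
    run_denovo: bool = True
    run_network: bool = True


def read_config(path) -> PipelineConfig:
    """Flat `key = value` config file; '#' starts a comment."""
    cfg = PipelineConfig()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if isinstance(cur, bool):
                setattr(cfg, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(cur, int):
                setattr(cfg, key, int(val))
            elif isinstance(cur, float):
                setattr(cfg, key, float(val))
            elif isinstance(cur, tuple):
                setattr(cfg, key, tuple(int(x) for x in val.split(",")))
            else:
                setattr(cfg, key, val)
    return cfg


def validate(cfg: PipelineConfig) -> list[str]:
    """Static config checks, reported without running anything."""
    issues: list[str] = []
    if not 0 < cfg.avg_r <= cfg.seed_r <= 1:
        issues.append(f"require 0 < avg_r <= seed_r <= 1, got {cfg.avg_r}, {cfg.seed_r}")
    for d in cfg.d_min:
        if d > cfg.d_max:
            issues.append(f"d_min {d} exceeds d_max {cfg.d_max}")
    if not 0 < cfg.alpha <= 1:
        issues.append(f"alpha must lie in (0, 1], got {cfg.alpha}")
    if not 0 < cfg.core_threshold <= 1 or not 0 < cfg.matrix_threshold <= 1:
        issues.append("similarity thresholds must lie in (0, 1]")
    if cfg.mode not in ("panel", "timeseries"):
        issues.append(f"unknown mode {cfg.mode!r}")
    if cfg.min_intensity <= 0:
        issues.append("min_intensity must be positive")
    for key in ("expression", "metadata", "genome", "tss_bed", "pwm_file", "seeds_file"):
        path = getattr(cfg, key)
        if path and not Path(path).exists():
            issues.append(f"{key}: file not found: {path}")
    return issues


@dataclass
class RunReport:
    config_hash: str = ""
    version: str = ""
    seed: int = 0
    counts: dict = field(default_factory=dict)
    clusters: list = field(default_factory=list)
    enrichment: dict = field(default_factory=dict)
    motif_matches: list = field(default_factory=list)
    hubs: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def run(cfg: PipelineConfig) -> RunReport:
    """Execute every configured stage; see module docstring for the order."""
    issues = validate(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    report = RunReport(
        config_hash=hashlib.sha256(cfg_blob).hexdigest()[:16],
        version=__version__,
        seed=cfg.seed,
    )

    # -- stage: filter ------------------------------------------------------
    log.info("stage=filter mode=%s", cfg.mode)
    m = read_expression(
        cfg.expression,
        cfg.metadata,
        present_path=cfg.present or None,
        pvals_path=cfg.pvals or None,
    )
    fcfg = FilterConfig(
        min_intensity=cfg.min_intensity,
        sig_p=cfg.sig_p if cfg.mode == "timeseries" else None,
    )
    filtered = filter_timeseries(m, fcfg) if cfg.mode == "timeseries" else filter_panel(m, fcfg)
    report.counts["genes_input"] = len(m.genes)
    report.counts["genes_filtered"] = len(filtered.genes)
    log.info("stage=filter kept=%d of=%d", len(filtered.genes), len(m.genes))

    # -- stage: cluster -----------------------------------------------------
    seeds = [s.strip() for s in open(cfg.seeds_file) if s.strip()]
    seeds = [s for s in seeds if s in filtered.intensity.index]
    if not seeds:
        raise ValueError("stage=cluster: no seed genes survive filtering")
    if cfg.mode == "timeseries":
        ratio_df = pd.read_csv(cfg.ratios, sep="\t", index_col=0)
        profile = ratio_df.loc[[g for g in filtered.genes if g in ratio_df.index]]
    else:
        profile = np.log2(filtered.intensity)
    ccfg = ClusterConfig(seed_r=cfg.seed_r, avg_r=cfg.avg_r, fold=cfg.fold)
    clusters = build_clusters(profile, profile.loc[seeds], ccfg)
    write_clusters_tsv(clusters, profile, outdir / "clusters.tsv")
    report.clusters = [
        {
            "members": len(c.members),
            "seeds": len(c.seeds),
            "avg_r": round(c.avg_r, 4),
            "warning": c.warning,
        }
        for c in clusters
    ]
    if not clusters:
        raise ValueError("stage=cluster: no clusters produced")
    main = max(clusters, key=lambda c: len(c.members))
    log.info("stage=cluster n=%d main_size=%d", len(clusters), len(main.members))

    # -- stage: promoters ---------------------------------------------------
    genome = load_genome(cfg.genome)
    records = read_tss(cfg.tss_bed)
    bg_proms = build_background(records, genome)
    fg_proms = {g: p for g, p in bg_proms.items() if g in main.members}
    if not fg_proms:
        raise ValueError("stage=promoters: no promoters for cluster genes")
    write_promoters_fasta(fg_proms, outdir / "cluster_promoters.fa")
    report.counts["cluster_promoters"] = len(fg_proms)
    report.counts["background_promoters"] = len(bg_proms)

    fg_masked = {g: masked_view(p)[0] for g, p in fg_proms.items()}
    fg_unmasked = {g: masked_view(p)[1] for g, p in fg_proms.items()}
    bg_masked = {g: masked_view(p)[0] for g, p in bg_proms.items()}
    bg_unmasked = {g: masked_view(p)[1] for g, p in bg_proms.items()}

    # -- stage: scan --------------------------------------------------------
    pwms = parse_transfac(cfg.pwm_file)
    mcfg = MatchConfig(core_threshold=cfg.core_threshold, matrix_threshold=cfg.matrix_threshold)
    fg_hits = scan_promoters(pwms, fg_masked, mcfg)
    bg_hits = scan_promoters(pwms, bg_masked, mcfg)
    fg_hits_unmasked = scan_promoters(pwms, fg_unmasked, mcfg)
    write_hits_tsv(fg_hits, outdir / "cluster_hits.tsv")
    report.counts["cluster_hits"] = sum(len(h) for h in fg_hits.values())
    log.info("stage=scan cluster_hits=%d", report.counts["cluster_hits"])

    # -- stage: enrichment --------------------------------------------------
    single = single_tfbs_enrichment(
        {p: {h.matrix_id for h in hs} for p, hs in fg_hits.items()},
        {p: {h.matrix_id for h in hs} for p, hs in bg_hits.items()},
        CompositeConfig(alpha=cfg.alpha, min_cell=0),
        {p: {h.matrix_id for h in hs} for p, hs in fg_hits_unmasked.items()},
    )
    write_enrichment_tsv(single, outdir / "single_tfbs_enrichment.tsv")
    report.enrichment["single_significant"] = sum(r.significant for r in single)
    for arity, ordered in ((2, True), (3, False)):
        for d_min in cfg.d_min:
            comp_cfg = CompositeConfig(
                arity=arity, ordered=ordered, d_min=d_min, d_max=cfg.d_max, alpha=cfg.alpha
            )
            res = enrich_composites(fg_hits, bg_hits, comp_cfg, fg_hits_unmasked)
            tag = f"{'ordered_pairs' if arity == 2 else 'unordered_triplets'}_dmin{d_min}"
            write_enrichment_tsv(res, outdir / f"composites_{tag}.tsv")
            report.enrichment[tag] = sum(r.significant for r in res)

    # -- stage: denovo ------------------------------------------------------
    if cfg.run_denovo:
        dn_bg = {g: s for g, s in bg_unmasked.items() if g not in main.members}
        dcfg = DenovoConfig(
            width_min=cfg.denovo_width_min,
            width_max=cfg.denovo_width_max,
            restarts=cfg.denovo_restarts,
            seed=cfg.seed,
        )
        motifs = discover_all(fg_unmasked, dn_bg, dcfg)
        write_meme(motifs, outdir / "denovo_motifs.meme", estimate_background(dn_bg))
        matches = match_library(motifs[0], pwms, seed=cfg.seed)
        write_matches_tsv(matches, outdir / "denovo_matches.tsv")
        report.motif_matches = [
            {"target": m.target_id, "score": round(m.score, 4), "p": m.p, "significant": m.significant}
            for m in matches[:5]
        ]
        log.info("stage=denovo best_objective=%.3f", motifs[0].objective)

    # -- stage: network -----------------------------------------------------
    if cfg.run_network and cfg.mode == "timeseries":
        expr = profile.loc[sorted(main.members & set(profile.index))]
        net = build_network(expr, beta=cfg.beta, min_module_size=min(30, len(expr) // 2))
        rm = RatioMatrix(ratios=expr, meta=m.meta)
        dres = diet_within_time(rm)
        pmat = dres.table.pivot(index="gene", columns="time", values="p")
        gs = gene_significance_from_pvalues(pmat)
        hubs = hub_genes(
            net,
            gs,
            HubConfig(n_hubs=cfg.n_hubs, gs_cutoff=cfg.gs_cutoff, k_ratio_cutoff=cfg.k_ratio_cutoff, beta=cfg.beta),
        )
        write_modules_tsv(net, outdir / "modules.tsv")
        report.hubs = hubs.hubs
        report.counts["modules"] = int(net.modules.max()) if net.modules is not None else 0
        log.info("stage=network modules=%d hubs=%s", report.counts["modules"], hubs.hubs)

    report.to_json(outdir / "report.json")
    return report
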