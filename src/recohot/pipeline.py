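"""End-to-end pipeline: simulate → filter → group → crossovers → hotspots.

``run_pipeline`` executes the whole analysis from a single config (a YAML
file or dict), writes every stage output in standard text formats under an
output directory, and returns a machine-readable report plus a run
manifest (config hash, seed, version, per-file checksums, thresholds), so
a run can be reproduced and audited stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossover import STATUS_PASS, call_crossovers, count_events, events_frame, segment_blocks
from .genome import GenomeSpec, HotspotInterval, scaled_study_genome
from .hotspots import call_fold_hotspots, call_poisson_hotspots, call_ril_hotspots, consensus_hotspots, hotspot_fraction
from .io import filter_map_markers, write_bed, write_genotypes, write_map
from .landscape import conservation_score, genome_mean_rate, length_correlation, map_rate_track, window_counts, window_rates
from .linkage import genetic_distances, map_summary
from .simulate import SimConfig, simulate_panel, simulate_ril

__all__ = ["PipelineError", "RunManifest", "load_config", "run_pipeline", "detect_events"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    thresholds: dict
    checksums: dict[str, str] = field(default_factory=dict)

    def add(self, path: Path) -> None:
        self.checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {"n_chrom": 20, "chrom_bp": 10_000_000, "cm_per_chrom": 145.0,
               "hotspots_per_chrom": 2, "hotspot_bp": 100_000, "fold": 20.0},
    "ril": {"n_lines": 200, "generations": 6, "n_markers": 2000, "missing_rate": 0.03},
    "panel": {"n_accessions": 49, "n_founders": 8, "n_markers": 2000,
              "missing_rate": 0.05, "mosaic_depth": 1.0},
    "filters": {"max_missing": 0.05, "min_call": 0.8, "min_maf": 0.05},
    "crossover": {"min_flank_span": 10_000, "small_block": 200_000},
    "windows": {"locus_bp": 100_000, "rate_bp": 1_000_000},
    "hotspots": {"fold": 3.0, "ril_cm_per_mb": 50.0, "alpha": 0.01},
    "genes": {"gff3": None, "go_map": None, "go_labels": None, "flank": 100_000},
}


def load_config(path_or_dict) -> dict:
    """Merge a user config (YAML path or dict) over the defaults."""
    user = path_or_dict
    if not isinstance(user, dict):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def build_genome(cfg: dict) -> GenomeSpec:
    g = cfg["genome"]
    if "chromosomes" in g:  # explicit genome spec
        hotspots = [HotspotInterval(**h) for h in g.get("hotspots", [])]
        return GenomeSpec([(c["name"], int(c["length"])) for c in g["chromosomes"]],
                          g.get("baseline_cm_per_mb", 1.0), hotspots)
    rng = np.random.default_rng(cfg["seed"])
    return scaled_study_genome(
        n_chrom=g["n_chrom"], chrom_bp=g["chrom_bp"], cm_per_chrom=g["cm_per_chrom"],
        hotspots_per_chrom=g["hotspots_per_chrom"], hotspot_bp=g["hotspot_bp"],
        fold=g["fold"], rng=rng,
    )


def detect_events(gm, min_flank_span: int = 10_000, small_block: int = 200_000):
    """Segment every sample and call crossover events (convenience wrapper)."""
    events = []
    for sample in gm.samples:
        blocks = segment_blocks(gm, sample)
        events.extend(call_crossovers(blocks, min_flank_span=min_flank_span, small_block=small_block))
    return events


def run_pipeline(config, outdir) -> tuple[RunManifest, dict]:
    """Run the full analysis; returns (manifest, report).

    Writes genotypes (TSV), truth junctions (BED), the genetic map, event
    tables, window tracks (bedgraph-style TSV), hotspot calls and the
    report (JSON + TSV) under ``outdir``.
    """
    cfg = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_blob).hexdigest(),
        seed=int(cfg["seed"]),
        version=__version__,
        thresholds={**cfg["filters"], **cfg["crossover"], **cfg["hotspots"]},
    )
    report: dict = {"seed": int(cfg["seed"])}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, str(exc)) from exc

    genome = _stage("genome", build_genome, cfg)

    # -- simulate ---------------------------------------------------------
    ril_cfg = SimConfig(seed=cfg["seed"], **{k: v for k, v in cfg["ril"].items()})
    ril_gm, ril_truth = _stage("simulate_ril", simulate_ril, genome, ril_cfg)
    p = cfg["panel"]
    panel_cfg = SimConfig(seed=cfg["seed"] + 1, n_lines=p["n_accessions"], generations=2,
                          n_markers=p["n_markers"], missing_rate=p["missing_rate"], marker_type="indel")
    panel_gm, panel_truth = _stage(
        "simulate_panel", simulate_panel, genome, p["n_founders"], p["n_accessions"], panel_cfg,
        mosaic_depth=p["mosaic_depth"], min_call=cfg["filters"]["min_call"], min_maf=cfg["filters"]["min_maf"],
    )
    write_genotypes(ril_gm, out / "ril_genotypes.tsv")
    write_genotypes(panel_gm, out / "panel_genotypes.tsv")
    ril_truth.to_bed(out / "ril_truth.bed")
    panel_truth.to_bed(out / "panel_truth.bed")
    logger.info("simulated %d RIL markers, %d panel markers", ril_gm.n_markers, panel_gm.n_markers)

    # -- filter + map ------------------------------------------------------
    ril_mapped = _stage("filter_map_markers", filter_map_markers, ril_gm, cfg["filters"]["max_missing"])
    report["ril_markers_total"] = ril_gm.n_markers
    report["ril_markers_mapped"] = ril_mapped.n_markers
    report["panel_markers_kept"] = panel_gm.n_markers
    map_df = _stage("genetic_distances", genetic_distances, ril_mapped)
    write_map(map_df, out / "ril_map.tsv")
    phys = {lg: genome.length(c) / 1e6
            for lg, c in zip(pd.unique(map_df["linkage_group"]), genome.names)}
    summary = _stage("map_summary", map_summary, map_df, phys)
    summary.to_csv(out / "map_summary.tsv", sep="\t", index=False)
    report["map_total_cm"] = float(summary["genetic_cm"].sum())

    # -- crossover events --------------------------------------------------
    xo = cfg["crossover"]
    ril_events = _stage("crossovers_ril", detect_events, ril_mapped, xo["min_flank_span"], xo["small_block"])
    panel_events = _stage("crossovers_panel", detect_events, panel_gm, xo["min_flank_span"], xo["small_block"])
    events_frame(ril_events).to_csv(out / "ril_events.tsv", sep="\t", index=False)
    events_frame(panel_events).to_csv(out / "panel_events.tsv", sep="\t", index=False)
    report["ril_events_pass"] = count_events(ril_events)
    report["panel_events_pass"] = count_events(panel_events)

    # -- landscapes --------------------------------------------------------
    w = cfg["windows"]
    ril_track = window_rates(window_counts(ril_events, genome, w["locus_bp"]))
    panel_track = window_rates(window_counts(panel_events, genome, w["locus_bp"]))
    panel_rate_track = window_rates(window_counts(panel_events, genome, w["rate_bp"]))
    for name, tr in [("ril_windows.tsv", ril_track), ("panel_windows.tsv", panel_track),
                     ("panel_rate_windows.tsv", panel_rate_track)]:
        tr.to_csv(out / name, sep="\t", index=False)
    report["panel_mean_rate_per_mb"] = genome_mean_rate(panel_rate_track)

    per_chrom = count_events(panel_events, by="chrom").reindex(genome.names).fillna(0)
    lengths_mb = [genome.length(c) / 1e6 for c in genome.names]
    if len(genome.names) >= 3 and np.ptp(per_chrom.to_numpy()) > 0 and np.ptp(lengths_mb) > 0:
        r, pval = _stage("length_correlation", length_correlation, per_chrom.to_numpy(), lengths_mb)
        report["count_length_r"] = r
        report["count_length_p"] = pval
    else:
        report["count_length_r"] = None  # undefined below 3 chromosomes
        report["count_length_p"] = None

    # -- hotspots ----------------------------------------------------------
    h = cfg["hotspots"]
    cm_track = _stage("map_rate_track", map_rate_track, map_df, ril_mapped.markers, genome, w["locus_bp"])
    ril_calls = call_ril_hotspots(cm_track, h["ril_cm_per_mb"])
    fold_calls = call_fold_hotspots(panel_track, fold=h["fold"])
    pois_calls = call_poisson_hotspots(panel_track, alpha=h["alpha"])
    cons = conservation_score(ril_mapped, genome.windows(w["locus_bp"]))
    consensus = consensus_hotspots(genome.windows(w["locus_bp"]), ril_calls, panel_track, cons)
    for name, calls in [("hotspots_ril.tsv", ril_calls), ("hotspots_fold.tsv", fold_calls),
                        ("hotspots_poisson.tsv", pois_calls), ("hotspots_consensus.tsv", consensus)]:
        calls.to_csv(out / name, sep="\t", index=False)
        write_bed(calls.assign(name=calls["rules_fired"]), out / name.replace(".tsv", ".bed"))
    n_windows = len(panel_track)
    report["hotspots_ril"] = len(ril_calls)
    report["hotspots_fold"] = len(fold_calls)
    report["hotspots_poisson"] = len(pois_calls)
    report["hotspots_consensus"] = len(consensus)
    report["hotspot_pct_of_windows"] = hotspot_fraction(len(fold_calls), n_windows)

    # -- genes (optional) --------------------------------------------------
    g = cfg["genes"]
    if g.get("gff3"):
        from .genes import genes_near_hotspots, go_frequency
        from .io import read_gff3_genes, read_go_labels, read_go_mapping

        genes = _stage("read_genes", read_gff3_genes, g["gff3"])
        near = _stage("genes_near_hotspots", genes_near_hotspots, fold_calls, genes, g["flank"])
        near.to_csv(out / "hotspot_genes.tsv", sep="\t", index=False)
        report["hotspot_genes"] = len(near)
        if g.get("go_map"):
            go_map = read_go_mapping(g["go_map"])
            labels = read_go_labels(g["go_labels"]) if g.get("go_labels") else None
            freq = _stage("go_frequency", go_frequency, near, go_map, labels)
            freq.to_csv(out / "hotspot_go_frequency.tsv", sep="\t", index=False)
            report["hotspot_go_terms"] = int((freq["term_id"] != "unannotated").sum())

    # -- report + manifest -------------------------------------------------
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    pd.Series(report).rename("value").to_csv(out / "report.tsv", sep="\t")
    for f in sorted(out.iterdir()):
        if f.name not in ("manifest.json",) and f.is_file():
            manifest.add(f)
    manifest.write(out / "manifest.json")
    return manifest, report
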