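"""End-to-end orchestration: simulate/call/catalogue/filter/enrich/annotate.

A run is driven by a :class:`RunConfig` (YAML-serializable). Every run
writes a manifest with the frozen configuration, a config hash, the
seeds used and package versions, so a catalogue can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coldspot_catalog import (
    Coldspot,
    build_co_regions,
    cluster_coldspots,
    clusters_to_frame,
    coldspots_to_frame,
    conserved_coldspots,
    detect_coldspots,
)
from .crossover_detection import (
    CoFilterParams,
    detect_crossovers,
    events_to_intervals,
    filter_high_resolution,
    summarize_events,
    write_events,
)
from .enrichment_stats import (
    enrichment_table,
    genic_enrichment,
    landscape_correlation,
    overlap_fisher,
    permutation_enrichment,
)
from .feature_annotation import (
    assign_features,
    coldspot_gene_report,
    count_genic_cos,
    genes_to_intervals,
)
from .genome_model import IntervalSet, coverage, write_bed
from .sv_filtering import SvFilterParams, filter_parental_svs, svs_to_intervals
from .synthetic_data import SimConfig, simulate_corpus, write_corpus

__all__ = ["RunConfig", "run_pipeline", "make_fixture"]


@dataclass
class RunConfig:
    """All stage parameters with the analysis defaults.

    The window/merge constants (10 kb / 5 kb / 1 kb), the 1 Mb coldspot
    floor, the clustering constants (50% reciprocal overlap, 1.5x span
    ratio, 0.3 dendrogram cut), the 0.001 resolution cutoff, the SV size
    classes (50 bp / 1 kb / 30 kb) and the 10,000 permutations are the
    method's published operating points.
    """

    outdir: str = "results"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    co_filters: CoFilterParams = field(default_factory=CoFilterParams)
    sv_filters: SvFilterParams = field(default_factory=SvFilterParams)
    co_window: int = 10_000
    co_step: int = 5_000
    co_merge_gap: int = 1_000
    coldspot_min_size: int = 1_000_000
    min_resolution: float = 0.001
    n_perm: int = 10_000
    fisher_window: int = 10_000
    landscape_window: int = 500_000
    landscape_step: int = 50_000
    min_genes_per_group: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(raw)
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            sim = dict(kwargs["sim"])
            if "te_tracks" in sim and isinstance(sim["te_tracks"], dict):
                from .synthetic_data import TeTrackConfig

                sim["te_tracks"] = {
                    k: TeTrackConfig(**v) if isinstance(v, dict) else v
                    for k, v in sim["te_tracks"].items()
                }
            if "hybrids" in sim:
                sim["hybrids"] = tuple(sim["hybrids"])
            kwargs["sim"] = SimConfig(**sim)
        if "co_filters" in kwargs and isinstance(kwargs["co_filters"], dict):
            kwargs["co_filters"] = CoFilterParams(**kwargs["co_filters"])
        if "sv_filters" in kwargs and isinstance(kwargs["sv_filters"], dict):
            kwargs["sv_filters"] = SvFilterParams(**kwargs["sv_filters"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["hybrids"] = list(d["sim"]["hybrids"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _fmt_float(x) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6g}"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis on a simulated corpus; write the catalogue.

    Stages: simulate -> CO calling -> CO regions -> coldspots ->
    cross-hybrid clustering + conserved coldspots -> SV filtering ->
    enrichment statistics -> gene-feature annotation. Returns a summary
    dict; all tables land under ``cfg.outdir``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    corpus = simulate_corpus(sim)
    genome = corpus.genome
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)

    say(f"simulated corpus: {len(genome.chrom_names)} chromosomes, "
        f"{len(corpus.hybrids)} hybrids, seed={cfg.seed}")

    events_by_hybrid = {}
    co_sets = {}
    coldspots_by_hybrid = {}
    all_coldspots: list[Coldspot] = []
    summary_rows = []
    for hybrid, hc in corpus.hybrids.items():
        events, tally = detect_crossovers(hc.molecules, cfg.co_filters, hybrid_id=hybrid)
        say(f"{hybrid}: {len(hc.molecules)} molecules -> {len(events)} COs "
            f"(rejections: { {k: v for k, v in sorted(tally.items()) if k != 'ok'} })")
        highres = filter_high_resolution(events, cfg.min_resolution)
        say(f"{hybrid}: {len(highres)} COs at resolution > {cfg.min_resolution}")
        events_by_hybrid[hybrid] = events
        write_events(events, out / f"co_events_{hybrid}.tsv", out / f"co_events_{hybrid}.bed")

        regions = build_co_regions(
            events, genome, cfg.co_window, cfg.co_step, cfg.co_merge_gap, hybrid_id=hybrid
        )
        bp, frac = regions.coverage(genome)
        say(f"{hybrid}: CO regions cover {bp} bp ({100 * frac:.2f}%)")
        write_bed(regions.intervals, out / f"co_regions_{hybrid}.bed")
        co_sets[hybrid] = events_to_intervals(events, label=hybrid)

        spots, nomarker = detect_coldspots(
            regions, genome, hc.markers, cfg.coldspot_min_size
        )
        coldspots_by_hybrid[hybrid] = spots
        all_coldspots.extend(spots)
        say(f"{hybrid}: {len(spots)} coldspots >= {cfg.coldspot_min_size} bp "
            f"({len(nomarker)} marker-free gaps set aside)")
        coldspots_to_frame(spots).to_csv(out / f"coldspots_{hybrid}.tsv", sep="\t", index=False)
        if nomarker:
            coldspots_to_frame(nomarker).to_csv(
                out / f"coldspots_{hybrid}_no_markers.tsv", sep="\t", index=False
            )
        stats = summarize_events(events)
        summary_rows.append(
            {
                "hybrid": hybrid,
                "n_markers": len(hc.markers),
                "n_molecules": len(hc.molecules),
                "n_cos": stats["n_events"],
                "mean_distance_kb": stats["mean_distance_kb"],
                "sd_distance_kb": stats["sd_distance_kb"],
                "co_region_bp": bp,
                "co_region_fraction": frac,
                "n_coldspots": len(spots),
            }
        )

    clusters = cluster_coldspots(all_coldspots)
    cl_frame = clusters_to_frame(clusters)
    cl_frame.to_csv(out / "coldspot_clusters.tsv", sep="\t", index=False)
    n_unique = sum(1 for c in clusters if c.cls == "unique")
    n_shared = sum(1 for c in clusters if c.cls == "shared")
    say(f"clusters: {n_unique} unique, {n_shared} shared")

    conserved, cons_info = conserved_coldspots(coldspots_by_hybrid, genome)
    write_bed(conserved, out / "conserved_coldspots.bed")
    say(f"conserved coldspots: {cons_info['bp']} bp "
        f"({100 * cons_info['fraction']:.1f}% of genome)")

    union = IntervalSet([iv for s in co_sets.values() for iv in s])
    union_bp, union_frac = coverage(union, genome)
    say(f"combined CO coverage: {union_bp} bp ({100 * union_frac:.2f}%)")

    sv_rows = []
    sv_analysis = {}
    for hybrid, hc in corpus.hybrids.items():
        res = filter_parental_svs(
            hc.sv_sets["wild_inbred"],
            hc.sv_sets["f1_pollen"],
            hc.sv_sets["self"],
            cfg.sv_filters,
        )
        sv_analysis[hybrid] = svs_to_intervals(res["analysis"], label=hybrid)
        sv_rows.append(
            {
                "hybrid": hybrid,
                "inbred": len(hc.sv_sets["wild_inbred"]),
                "parental": len(res["parental"]),
                "retained": len(res["retained"]),
                "analysis": len(res["analysis"]),
                "inv_report": len(res["inv_report"]),
            }
        )
        say(f"{hybrid}: SV filter {len(hc.sv_sets['wild_inbred'])} inbred -> "
            f"{len(res['parental'])} parental -> {len(res['retained'])} retained "
            f"({len(res['analysis'])} in the >1 kb analysis set)")
    pd.DataFrame(sv_rows).to_csv(out / "sv_filtering.tsv", sep="\t", index=False)

    rng_rows = []
    gene_ivs = genes_to_intervals(corpus.genes)
    enr = {}
    for hybrid in corpus.hybrids:
        cos = co_sets[hybrid]
        res_sv = (
            permutation_enrichment(
                cos, sv_analysis[hybrid], genome, n_perm=cfg.n_perm, seed=cfg.seed + 1
            )
            if len(sv_analysis[hybrid])
            else None
        )
        res_gene = genic_enrichment(
            cos, gene_ivs, genome.deu_intervals, genome, n_perm=cfg.n_perm, seed=cfg.seed + 2
        )
        te_table = enrichment_table(
            cos, corpus.te_tracks, genome, n_perm=cfg.n_perm, seed=cfg.seed + 3
        )
        te_table.insert(0, "hybrid", hybrid)
        res_acr = permutation_enrichment(
            cos, corpus.acrs, genome, n_perm=cfg.n_perm, seed=cfg.seed + 4
        )
        enr[hybrid] = {"sv": res_sv, "gene": res_gene, "te": te_table, "acr": res_acr}
        rng_rows.append(te_table)
        say(
            f"{hybrid}: permutation z — SV "
            f"{_fmt_float(res_sv.z_score if res_sv else np.nan)}, genes(DEU) "
            f"{_fmt_float(res_gene.z_score)}, ACR {_fmt_float(res_acr.z_score)}"
        )
    pd.concat(rng_rows, ignore_index=True).to_csv(
        out / "te_enrichment.tsv", sep="\t", index=False
    )

    rho, pvals = landscape_correlation(
        co_sets, genome, cfg.landscape_window, cfg.landscape_step
    )
    rho.to_csv(out / "landscape_correlation.tsv", sep="\t")
    fisher_rows = []
    hybrids = list(co_sets)
    for i, a in enumerate(hybrids):
        for b in hybrids[i + 1 :]:
            f = overlap_fisher(co_sets[a], co_sets[b], genome, cfg.fisher_window)
            fisher_rows.append(
                {
                    "hybrid_a": a,
                    "hybrid_b": b,
                    "odds_ratio": f["odds_ratio"],
                    "p_value": f["p_value"],
                    "shared_fraction": f["shared_fraction"],
                }
            )
    pd.DataFrame(fisher_rows).to_csv(out / "co_overlap_fisher.tsv", sep="\t", index=False)

    feat_frames = []
    genic_rows = []
    for hybrid in corpus.hybrids:
        feats = assign_features(co_sets[hybrid], corpus.genes, genome)
        feats.insert(0, "hybrid", hybrid)
        feat_frames.append(feats)
        w, m, b = count_genic_cos(co_sets[hybrid], corpus.genes, genome)
        genic_rows.append({"hybrid": hybrid, "within_1kb": w, "kb1_3": m, "beyond": b})
    pd.concat(feat_frames, ignore_index=True).to_csv(
        out / "co_features.tsv", sep="\t", index=False
    )
    pd.DataFrame(genic_rows).to_csv(out / "co_gene_distance.tsv", sep="\t", index=False)

    groups, gene_summary = coldspot_gene_report(
        all_coldspots, corpus.genes, min_genes=cfg.min_genes_per_group
    )
    say(
        f"coldspot genes: {gene_summary['n_coldspot_genes']} "
        f"({100 * gene_summary['fraction_of_genes']:.1f}% of genes); "
        f"{gene_summary['n_groups_min_genes']} groups with >= {cfg.min_genes_per_group} genes"
    )

    summary = {
        "per_hybrid": pd.DataFrame(summary_rows),
        "clusters": {"unique": n_unique, "shared": n_shared},
        "conserved": cons_info,
        "union_co_bp": union_bp,
        "union_co_fraction": union_frac,
        "enrichment": enr,
        "landscape_rho": rho,
        "fisher": pd.DataFrame(fisher_rows),
        "gene_summary": gene_summary,
        "log": log,
    }
    summary["per_hybrid"].to_csv(out / "summary_per_hybrid.tsv", sep="\t", index=False)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return summary


def make_fixture(seed: int = 0, outdir: str | Path | None = None) -> "SimConfig":
    """A small deterministic noise-free corpus config for the test suite.

    Three 12 Mb chromosomes, 3,000 molecules, one shared and one unique
    planted coldspot per hybrid; noise rates zero so planted COs are
    recoverable exactly. If ``outdir`` is given, the corpus is written
    there.
    """
    cfg = SimConfig(
        hybrids=("PM", "NE", "CH", "HB", "PN"),
        n_chromosomes=3,
        chrom_length=12_000_000,
        n_molecules=3_000,
        coldspot_length=1_500_000,
        n_shared_coldspots=1,
        n_unique_coldspots=1,
        sv_count=40,
        gene_count=800,
        acr_count=500,
        seed=seed,
    )
    if outdir is not None:
        write_corpus(simulate_corpus(cfg), outdir)
    return cfg
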