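"""End-to-end orchestration of the genome-landscape stages.

Stages run in dependency order: repeat landmarks, R-gene
classification, TE enrichment, SV merging/hemizygosity, ASE calling,
SV-ASE density correlation, and cluster detection/projection.  A stage
failure halts its dependents but independent stages still complete.
Every random draw flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import classify as classify_mod
from . import clusters as clusters_mod
from . import core_io
from . import landmarks as landmarks_mod
from . import sv as sv_mod
from . import te_enrichment as te_mod

log = logging.getLogger("rgenescape")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class RunConfig:
    """Inputs and thresholds for a full pipeline run.

    Paths default to the fixture layout the simulator emits; thresholds
    default to the study conventions (50-kb flank, 100 background
    replicates, alpha 0.05, 1.0-Mb / 3-member clusters, >10% coding
    overlap, 2-kb promoter, fold-change 2, FDR 0.05).
    """

    input_dir: str = "."
    out_dir: str = "results"
    seed: int = 0
    genome_fasta: str = "genome.fa"
    genes_gff: str = "genes.gff3"
    proteins_fasta: str = "proteins.faa"
    domains_tsv: str = "domains.tsv"
    te_gff: str = "tes.gff3"
    intact_ltrs_tsv: str = "intact_ltrs.tsv"
    vcf_hap1: str = "hap1.vcf"
    vcf_hap2: str = "hap2.vcf"
    allele_counts_tsv: str = "allele_counts.tsv"
    genes_b_gff: str = ""  # optional second assembly for cluster projection
    proteins_b_fasta: str = ""
    domains_b_tsv: str = ""
    ortholog_map_tsv: str = ""
    skip_sv: bool = False
    # landmark parameters
    telomere_motif: str = landmarks_mod.TELOMERE_UNIT
    telomere_min_copies: int = 10
    terminal_window: int = 50_000
    monomer: str = landmarks_mod.CENTROMERE_MONOMER
    monomer_min_identity: float = 80.0
    monomer_min_copies: int = 10
    # classification
    evalue_cutoff: float = 1e-5
    feature_ks: tuple = (0, 1, 2, 3)
    # TE enrichment
    flank: int = 50_000
    n_background_reps: int = 100
    background_frac: float = 0.0  # >0 switches to fraction-of-genes sampling
    alpha: float = 0.05
    # SV / hemizygosity
    sv_pos_tolerance: int = 1000
    sv_len_tolerance: float = 0.25
    sv_min_support: int = 1
    hemizygous_min_fraction: float = 0.10
    promoter_len: int = 2000
    correlation_bin: int = 500_000
    # ASE
    ase_min_snps: int = 1
    ase_min_depth: int = 10
    ase_fc_threshold: float = 2.0
    ase_fdr_threshold: float = 0.05
    # clusters
    cluster_window: int = 1_000_000
    cluster_min_members: int = 3
    homology_id_min: float = 40.0
    homology_cov_min: float = 0.50

    def path(self, name: str) -> Path:
        return Path(self.input_dir) / name

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a plain key-value (YAML-compatible) config file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "feature_ks" in data:
            data["feature_ks"] = tuple(data["feature_ks"])
        return cls(**data)


@dataclass
class RunReport:
    completed: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def run_all(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    state: dict = {}

    stages = [
        ("load", _stage_load, []),
        ("landmarks", _stage_landmarks, ["load"]),
        ("classify", _stage_classify, ["load"]),
        ("te_enrichment", _stage_te, ["load", "classify"]),
        ("sv_hemizygosity", _stage_sv, ["load"]),
        ("ase", _stage_ase, ["load"]),
        ("correlation", _stage_correlation, ["sv_hemizygosity", "ase"]),
        ("clusters", _stage_clusters, ["load", "classify"]),
        ("summary", _stage_summary, ["load"]),
    ]
    for name, fn, deps in stages:
        if name == "sv_hemizygosity" and config.skip_sv:
            report.skipped.append(name)
            continue
        missing = [d for d in deps if d not in report.completed]
        if missing:
            report.skipped.append(name)
            log.warning("stage %s skipped (unmet dependencies: %s)", name, missing)
            continue
        try:
            fn(config, state, out, report)
            report.completed.append(name)
            log.info("stage %s complete", name)
        except Exception as exc:  # halt dependents, keep independents running
            report.failed[name] = f"{type(exc).__name__}: {exc}"
            log.error("stage %s failed: %s", name, exc)

    # echo config for provenance
    cfg = dataclasses.asdict(config)
    cfg["feature_ks"] = list(config.feature_ks)
    with open(out / "run_config.json", "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
    with open(out / "run_report.json", "w") as fh:
        json.dump(
            {"completed": report.completed, "failed": report.failed,
             "skipped": report.skipped, "summary": report.summary},
            fh, indent=1, sort_keys=True, default=_jsonable,
        )
    return report


def _stage_load(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    state["sequences"] = core_io.read_fasta(cfg.path(cfg.genome_fasta))
    state["chrom_lengths"] = {s.chrom_id: s.length for s in state["sequences"]}
    state["genes"] = core_io.read_gff_genes(cfg.path(cfg.genes_gff))
    proteins = core_io.read_protein_fasta(cfg.path(cfg.proteins_fasta))
    for g in state["genes"]:
        g.protein_seq = proteins.get(g.gene_id)
    state["proteins"] = proteins
    state["domain_hits"] = core_io.read_domain_hits(cfg.path(cfg.domains_tsv)).hits
    state["tes"] = core_io.read_te_gff(cfg.path(cfg.te_gff))
    p = cfg.path(cfg.intact_ltrs_tsv)
    state["intact_ltrs"] = core_io.read_intact_ltrs(p) if p.exists() else []
    p = cfg.path(cfg.allele_counts_tsv)
    state["allele_counts"] = core_io.read_allele_counts(p) if p.exists() else None


def _stage_landmarks(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    telomeres, centromeres = [], []
    for seq in state["sequences"]:
        telomeres.extend(
            landmarks_mod.scan_telomeres(
                seq, cfg.telomere_motif, cfg.telomere_min_copies, cfg.terminal_window
            )
        )
        centromeres.extend(
            landmarks_mod.scan_monomer_array(
                seq, cfg.monomer, cfg.monomer_min_identity, cfg.monomer_min_copies
            )
        )
    landmarks_mod.landmark_bed(telomeres, centromeres, out / "landmarks.bed")
    state["telomeres"], state["centromeres"] = telomeres, centromeres
    report.summary["telomeres_found"] = landmarks_mod.telomere_summary(
        telomeres, len(state["sequences"])
    )
    report.summary["centromere_total_bp"] = landmarks_mod.total_array_length(centromeres)


def _stage_classify(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    r_genes = classify_mod.classify_genes(
        state["genes"], state["domain_hits"], cfg.evalue_cutoff
    )
    state["r_genes"] = r_genes
    rows = [
        {"gene_id": rg.gene.gene_id, "category": rg.category.value,
         "domains": ",".join(sorted(rg.domains)), "ambiguous": rg.ambiguous}
        for rg in r_genes
    ]
    pd.DataFrame(rows).to_csv(out / "rgene_categories.tsv", sep="\t", index=False)
    report.summary["r_genes_per_category"] = dict(
        pd.Series([rg.category.value for rg in r_genes]).value_counts().sort_index()
        .astype(int)
    )
    # PCA validation of category coherence on composition features
    proteins = {
        rg.gene.gene_id: rg.gene.protein_seq
        for rg in r_genes
        if rg.gene.protein_seq
    }
    if proteins:
        ids, matrix = classify_mod.feature_matrix(proteins, ks=cfg.feature_ks)
        labels = {rg.gene.gene_id: rg.category.value for rg in r_genes}
        try:
            coords, score = classify_mod.validate_categories(
                matrix, [labels[i] for i in ids]
            )
            pd.DataFrame(
                {"gene_id": ids, "pc1": coords[:, 0], "pc2": coords[:, 1],
                 "category": [labels[i] for i in ids]}
            ).to_csv(out / "rgene_embedding.tsv", sep="\t", index=False)
            report.summary["category_separation_score"] = round(score, 4)
        except ValueError as exc:
            log.warning("category validation skipped: %s", exc)


def _stage_te(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    r_genes = state["r_genes"]
    r_models = [rg.gene for rg in r_genes]
    r_ids = {rg.gene.gene_id for rg in r_genes}
    profiles = te_mod.profile_genes(
        r_models, state["tes"], cfg.flank, state["chrom_lengths"]
    )
    sample_size = None
    if cfg.background_frac > 0:
        sample_size = max(1, int(cfg.background_frac * len(state["genes"])))
    background = te_mod.background_resample(
        state["genes"], r_ids, state["tes"], cfg.n_background_reps,
        seed=cfg.seed, flank=cfg.flank, chrom_lengths=state["chrom_lengths"],
        sample_size=sample_size,
    )
    results = te_mod.enrichment_test(profiles, background, cfg.alpha)
    results.append(te_mod.intact_ltr_windows(profiles, background, cfg.alpha))
    pd.DataFrame(
        [
            {"te_class": r.te_class, "r_mean": r.r_mean, "bg_mean": r.bg_mean,
             "p_value": r.p_value, "jackknife_stable": r.jackknife_stable,
             "degenerate": r.degenerate}
            for r in results
        ]
    ).to_csv(out / "te_enrichment.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_id": p.gene_id, "window_start": p.window[0],
             "window_end": p.window[1], "te_fraction": p.te_fraction_total,
             "intact_ltr_fraction": p.intact_ltr_fraction}
            for p in profiles
        ]
    ).to_csv(out / "rgene_te_windows.tsv", sep="\t", index=False)
    state["te_results"] = results
    total = next(r for r in results if r.te_class == "total")
    report.summary["te_enrichment"] = {
        "r_mean": round(total.r_mean, 4),
        "bg_mean": round(total.bg_mean, 4),
        "p_value": total.p_value,
        "jackknife_stable": total.jackknife_stable,
    }
    if state["intact_ltrs"]:
        idents = [
            {"chrom_id": l.te.chrom_id, "start": l.te.start, "te_class": l.te.te_class,
             "identity": te_mod.ltr_pair_identity(l.ltr5_seq, l.ltr3_seq)}
            for l in state["intact_ltrs"]
        ]
        pd.DataFrame(idents).to_csv(out / "ltr_identity.tsv", sep="\t", index=False)


def _stage_sv(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    res1 = core_io.read_sv_vcf(cfg.path(cfg.vcf_hap1), "hap1")
    res2 = core_io.read_sv_vcf(cfg.path(cfg.vcf_hap2), "hap2")
    merged = sv_mod.merge_svs(
        {"hap1": res1.records, "hap2": res2.records},
        cfg.sv_pos_tolerance, cfg.sv_len_tolerance,
        min_support=cfg.sv_min_support,
    )
    het = [m for m in merged if m.zygosity == "heterozygous"]
    state["merged_svs"], state["het_svs"] = merged, het
    core_io.write_sv_vcf(
        [core_io.SVRecord(m.merged_id, m.chrom_id, m.pos, m.sv_type, m.length, "merged")
         for m in merged],
        out / "merged_svs.vcf",
        state["chrom_lengths"],
        extra_info={
            m.merged_id: {"ZYG": m.zygosity,
                          "SUPP": ",".join(sorted(m.supporting_haplotypes))}
            for m in merged
        },
    )
    hemi = sv_mod.call_hemizygous(het, state["genes"], cfg.hemizygous_min_fraction)
    state["hemizygous"] = hemi
    pd.DataFrame(
        [
            {"gene_id": h.gene_id, "sv_ids": ",".join(h.sv_ids),
             "coding_overlap_bp": h.coding_overlap_bp,
             "coding_overlap_fraction": round(h.coding_overlap_fraction, 4)}
            for h in hemi
        ]
    ).to_csv(out / "hemizygous_genes.tsv", sep="\t", index=False)
    state["promoter_sv_genes"] = sv_mod.promoter_sv_genes(
        state["genes"], het, cfg.promoter_len
    )
    report.summary["svs"] = {
        "merged": len(merged),
        "heterozygous": len(het),
        "hemizygous_genes": len(hemi),
        "promoter_sv_genes": len(state["promoter_sv_genes"]),
    }


def _stage_ase(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    if state.get("allele_counts") is None:
        raise FileNotFoundError("no allele-count table available")
    summaries, excluded = ase_mod.summarize_alleles(
        state["allele_counts"], cfg.ase_min_snps, cfg.ase_min_depth
    )
    results = ase_mod.call_ase(summaries, cfg.ase_fc_threshold, cfg.ase_fdr_threshold)
    state["ase_results"] = results
    ase_mod.ase_table(results, excluded).to_csv(out / "ase_calls.tsv", sep="\t", index=False)
    report.summary["ase"] = {
        "tested": len(results),
        "called": sum(r.called for r in results),
        "excluded": len(excluded),
    }


def _stage_correlation(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    called = {r.gene_id for r in state["ase_results"] if r.called}
    ase_genes = [g for g in state["genes"] if g.gene_id in called]
    rho, p = sv_mod.sv_ase_density_correlation(
        state["het_svs"], ase_genes, state["chrom_lengths"], cfg.correlation_bin
    )
    report.summary["sv_ase_correlation"] = {"rho": round(rho, 4), "p_value": p}


def _stage_clusters(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    r_genes = state["r_genes"]
    proteins = {
        rg.gene.gene_id: rg.gene.protein_seq for rg in r_genes if rg.gene.protein_seq
    }
    graph = clusters_mod.homology_graph(
        proteins, cfg.homology_id_min, cfg.homology_cov_min
    )
    found = clusters_mod.detect_clusters(
        r_genes, graph, cfg.cluster_window, cfg.cluster_min_members
    )
    state["clusters"] = found
    labels: dict[str, str] = {}
    if cfg.genes_b_gff and cfg.ortholog_map_tsv:
        genes_b = core_io.read_gff_genes(cfg.path(cfg.genes_b_gff))
        proteins_b = core_io.read_protein_fasta(cfg.path(cfg.proteins_b_fasta))
        hits_b = core_io.read_domain_hits(cfg.path(cfg.domains_b_tsv)).hits
        r_b = classify_mod.classify_genes(genes_b, hits_b, cfg.evalue_cutoff)
        for g in genes_b:
            g.protein_seq = proteins_b.get(g.gene_id)
        prot_b = {rg.gene.gene_id: proteins_b[rg.gene.gene_id] for rg in r_b
                  if rg.gene.gene_id in proteins_b}
        graph_b = clusters_mod.homology_graph(
            prot_b, cfg.homology_id_min, cfg.homology_cov_min
        )
        clusters_b = clusters_mod.detect_clusters(
            r_b, graph_b, cfg.cluster_window, cfg.cluster_min_members
        )
        omap = pd.read_csv(cfg.path(cfg.ortholog_map_tsv), sep="\t")
        ortholog_map = dict(zip(omap["gene_a"], omap["gene_b"]))
        labels = clusters_mod.project_clusters(
            found, clusters_b, ortholog_map,
            known_a={g.gene_id for g in state["genes"]},
            known_b={g.gene_id for g in genes_b},
        )
        state["clusters_b"] = clusters_b
    state["cluster_labels"] = labels
    with open(out / "clusters.bed", "w") as fh:
        for c in found:
            fh.write(f"{c.chrom_id}\t{c.span[0]}\t{c.span[1]}\t{c.cluster_id}\t{len(c.members)}\n")
    pd.DataFrame(
        [
            {"cluster_id": c.cluster_id, "chrom_id": c.chrom_id,
             "start": c.span[0], "end": c.span[1],
             "members": ",".join(c.members),
             "category_mode": c.category_mode.value if c.category_mode else "NA",
             "specificity": labels.get(c.cluster_id, "NA")}
            for c in found
        ]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    report.summary["clusters"] = {
        "detected": len(found),
        "specific": sum(1 for v in labels.values() if v == "A-specific"),
        "shared": sum(1 for v in labels.values() if v == "shared"),
    }


def _stage_summary(cfg: RunConfig, state: dict, out: Path, report: RunReport) -> None:
    """Per-assembly overview table in the style of a genome-stats table."""
    rows = []
    n_chroms = len(state["sequences"])
    rows.append({"metric": "chromosomes", "value": n_chroms})
    rows.append({"metric": "genome_bp", "value": sum(s.length for s in state["sequences"])})
    rows.append({"metric": "genes", "value": len(state["genes"])})
    if "telomeres" in state:
        rows.append({"metric": "telomeres_found",
                     "value": landmarks_mod.telomere_summary(state["telomeres"], n_chroms)})
    if "centromeres" in state:
        rows.append({"metric": "centromere_bp",
                     "value": sum(c.end - c.start for c in state["centromeres"])})
    te_bp = 0
    for chrom in {t.chrom_id for t in state["tes"]}:
        te_bp += core_io.union_length(
            [(t.start, t.end) for t in state["tes"] if t.chrom_id == chrom]
        )
    rows.append({"metric": "te_bp", "value": te_bp})
    if "r_genes" in state:
        rows.append({"metric": "r_genes", "value": len(state["r_genes"])})
    pd.DataFrame(rows).to_csv(out / "assembly_summary.tsv", sep="\t", index=False)
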