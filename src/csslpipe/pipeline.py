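"""End-to-end pipeline: scan -> network -> prioritize, plus phenomics and
physiology stages, driven by one YAML/JSON config with a global seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import coexpression, introgression, phenomics, physiostats, prioritization

log = logging.getLogger("csslpipe")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    out_dir: Path
    line_vcf: Path | None = None
    parent_vcf: Path | None = None
    genes_gff3: Path | None = None
    chrom_lengths_tsv: Path | None = None
    expression_tsv: Path | None = None
    marker_map_tsv: Path | None = None
    qtl_tsv: Path | None = None
    homolog_tsv: Path | None = None
    phenotype_csv: Path | None = None
    physiology_tsv: Path | None = None
    scan: introgression.ScanConfig = field(default_factory=introgression.ScanConfig)
    network: coexpression.NetworkConfig = field(default_factory=coexpression.NetworkConfig)
    wild_type: str = "WT"
    stability_day: float = 6.0
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")

        def p(key: str) -> Path | None:
            return (base / raw[key]) if raw.get(key) else None

        scan = introgression.ScanConfig(**raw.get("scan", {}))
        network = coexpression.NetworkConfig(**raw.get("network", {}))
        return cls(
            out_dir=base / raw.get("out_dir", "out"),
            line_vcf=p("line_vcf"), parent_vcf=p("parent_vcf"),
            genes_gff3=p("genes_gff3"), chrom_lengths_tsv=p("chrom_lengths_tsv"),
            expression_tsv=p("expression_tsv"), marker_map_tsv=p("marker_map_tsv"),
            qtl_tsv=p("qtl_tsv"), homolog_tsv=p("homolog_tsv"),
            phenotype_csv=p("phenotype_csv"), physiology_tsv=p("physiology_tsv"),
            scan=scan, network=network,
            wild_type=raw.get("wild_type", "WT"),
            stability_day=float(raw.get("stability_day", 6.0)),
            alpha=float(raw.get("alpha", 0.05)),
            seed=int(raw.get("seed", 0)),
        )


def _require(path: Path | None, stage: str, what: str) -> Path:
    if path is None:
        raise PipelineError(f"stage {stage}: no {what} configured")
    if not Path(path).exists():
        raise PipelineError(f"stage {stage}: {what} not found at {path}")
    return Path(path)


def run_scan(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    line = introgression.read_vcf(_require(cfg.line_vcf, "scan", "line VCF"))
    parent = introgression.read_vcf(_require(cfg.parent_vcf, "scan", "parent VCF"))
    if cfg.chrom_lengths_tsv:
        lengths = introgression.read_chrom_lengths(cfg.chrom_lengths_tsv)
    else:
        lengths = introgression.chrom_lengths_from_vcf(cfg.line_vcf)
    diff = introgression.differential_snps(line, parent)
    windows = introgression.window_scan(diff, lengths, cfg.scan)
    segments = introgression.merge_flagged(windows)
    genes = (introgression.read_genes_gff3(cfg.genes_gff3) if cfg.genes_gff3 else [])
    per_gene, totals = introgression.snps_to_genes(diff, genes)
    introgression.windows_to_tsv(windows, out / "windows.tsv")
    introgression.segments_to_bed(segments, out / "segments.bed")
    introgression.gene_hits_to_tsv(per_gene, out / "gene_hits.tsv")
    introgression.plot_chromosome_density(windows, out / "density.png", lengths)
    log.info("scan: %d differential SNPs, %d segments, %d genes hit",
             len(diff), len(segments), totals["n_genes_hit"])
    return {"n_differential_snps": len(diff), "segments": segments,
            "genes": genes, "per_gene": per_gene, "totals": totals}


def run_network(cfg: PipelineConfig, out: Path, seed_genes: list[str]) -> dict[str, Any]:
    matrix = coexpression.read_expression_tsv(
        _require(cfg.expression_tsv, "network", "expression matrix"))
    corr = coexpression.pearson_correlations(matrix, seed_genes or None,
                                             cfg.network.min_samples)
    net = coexpression.build_network(corr, cfg.network, seed_genes)
    hubs = coexpression.find_major_nodes(net, cfg.network)
    coexpression.edges_to_tsv(net, out / "edges.tsv")
    coexpression.network_to_graphml(net, out / "network.graphml")
    coexpression.hubs_to_tsv(hubs, out / "hubs.tsv")
    log.info("network: %d nodes, %d edges, %d hubs",
             net.number_of_nodes(), net.number_of_edges(), len(hubs))
    return {"network": net, "hubs": hubs}


def run_prioritize(cfg: PipelineConfig, out: Path, hubs, segments, genes) -> pd.DataFrame:
    markers = prioritization.read_marker_map(
        _require(cfg.marker_map_tsv, "prioritize", "marker map"))
    qtl_defs = prioritization.read_qtl_table(
        _require(cfg.qtl_tsv, "prioritize", "QTL table"))
    qtls = prioritization.resolve_qtl_intervals(qtl_defs, markers)
    membership = prioritization.genes_in_qtl(genes, qtls)
    homologs = prioritization.load_homolog_table(cfg.homolog_tsv)
    report = prioritization.build_candidate_report(
        hubs, segments, genes, membership, homologs)
    ranked = prioritization.rank_candidates(report)
    prioritization.report_to_tsv(ranked, out / "candidates.tsv")
    prioritization.report_to_json(ranked, out / "candidates.json")
    log.info("prioritize: %d candidate rows", len(ranked))
    return ranked


def run_pheno(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    df = phenomics.read_phenotype_csv(
        _require(cfg.phenotype_csv, "pheno", "phenotype CSV"))
    curves = phenomics.growth_curve_table(df)
    curves.to_csv(out / "growth_curves.tsv", sep="\t", index=False)
    comparisons = []
    for t in sorted(df["timepoint"].unique()):
        comparisons.extend(phenomics.growth_compare(df, cfg.wild_type, t))
    phenomics.comparisons_to_tsv(comparisons, out / "growth_compare.tsv")
    stability = phenomics.stability_table(df, cfg.wild_type, cfg.stability_day)
    stability.to_csv(out / "stability.tsv", sep="\t", index=False)
    log.info("pheno: %d comparisons, %d stability rows", len(comparisons), len(stability))
    return {"comparisons": comparisons, "stability": stability}


def run_physio(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    table = physiostats.load_physiology_table(cfg.physiology_tsv)
    letters_rows = []
    for (trait, condition, day), _ in table.groupby(["trait", "condition", "day"]):
        grouping = physiostats.dmrt_letters_for_cell(table, trait, condition, day, cfg.alpha)
        for _, r in grouping.table.iterrows():
            letters_rows.append({"trait": trait, "condition": condition, "day": day,
                                 "line": r["group"], "mean": r["mean"],
                                 "letters": r["letters"]})
    letters = pd.DataFrame(letters_rows)
    letters.to_csv(out / "dmrt_letters.tsv", sep="\t", index=False)
    log.info("physio: %d letter rows", len(letters))
    return {"letters": letters}


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage; write per-stage outputs plus a combined
    JSON + HTML report under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed}
    segments, genes, hubs = [], [], []
    seed_genes: list[str] = []
    stages = []
    if cfg.line_vcf:
        stages.append("scan")
    if cfg.expression_tsv:
        stages.append("network")
    if cfg.marker_map_tsv:
        stages.append("prioritize")
    if cfg.phenotype_csv:
        stages.append("pheno")
    for stage in stages:
        try:
            if stage == "scan":
                res = run_scan(cfg, out)
                segments, genes = res["segments"], res["genes"]
                report["scan"] = {"n_differential_snps": res["n_differential_snps"],
                                  "n_segments": len(segments), **res["totals"]}
                seed_genes = sorted(res["per_gene"])
            elif stage == "network":
                res = run_network(cfg, out, seed_genes)
                hubs = res["hubs"]
                report["network"] = {
                    "n_nodes": res["network"].number_of_nodes(),
                    "n_edges": res["network"].number_of_edges(),
                    "hubs": [{"gene_id": g, "degree": d} for g, d in hubs],
                }
            elif stage == "prioritize":
                ranked = run_prioritize(cfg, out, hubs, segments, genes)
                report["candidates"] = ranked.to_dict("records")
            elif stage == "pheno":
                res = run_pheno(cfg, out)
                report["stability"] = res["stability"].to_dict("records")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
    if cfg.physiology_tsv:
        try:
            res = run_physio(cfg, out)
            report["dmrt_letters"] = res["letters"].to_dict("records")
        except Exception as exc:
            raise PipelineError(f"stage physio failed: {exc}") from exc
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    _write_html_report(report, out / "report.html")
    return report


def _write_html_report(report: Mapping[str, Any], path: Path) -> None:
    parts = ["<html><head><title>csslpipe report</title></head><body>",
             "<h1>Candidate-gene pipeline report</h1>"]
    for section, content in report.items():
        parts.append(f"<h2>{section}</h2><pre>{json.dumps(content, indent=2, default=str)}</pre>")
    parts.append("</body></html>")
    path.write_text("\n".join(parts))
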