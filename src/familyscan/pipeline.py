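"""End-to-end pipeline: identify → structure → duplication → phylogeny →
promoters → expression, with a summary report in the style of a
gene-family survey (counts plus one-decimal percentages).

Every stage reads files and writes files, so stages are independently
invokable and a rerun with the same inputs and seed is byte-identical.
Missing optional inputs skip their stage with a log entry rather than
failing the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import duplication, expression, genome_io, identification, phylogeny, promoters, structure

log = logging.getLogger("familyscan")


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full run (defaults = the survey's values)."""

    genome_fasta: str | None = None
    gff3: str | None = None
    proteome_fasta: str | None = None
    annotations_tsv: str | None = None
    blocks_tsv: str | None = None
    fpkm_tsv: str | None = None
    qpcr_tsv: str | None = None
    reference_fasta: str | None = None
    reference_labels_tsv: str | None = None
    out_dir: str = "familyscan_out"
    prefix: str = "Fam"
    mw_min_kda: float = 15.0
    mw_max_kda: float = 42.0
    evalue_max: float = 1e-3
    keywords: tuple = identification.DEFAULT_KEYWORDS
    min_coverage_pct: float = 70.0
    min_identity_pct: float = 70.0
    max_intervening: int = 5
    tandem_window_bp: int = 100_000
    promoter_length: int = 1500
    bootstrap_reps: int = 100
    min_support: float = 50.0
    expressed_threshold: float = 1.0
    pseudocount: float = 0.01
    reference_gene: str = "ef1a"
    control_sample: str = "0h"
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["keywords"] = list(self.keywords)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs exist; return the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    genome = gff_models = proteome = None
    if config.genome_fasta and Path(config.genome_fasta).exists():
        genome = genome_io.read_fasta(config.genome_fasta)
    if config.gff3 and genome and Path(config.gff3).exists():
        gff_models = genome_io.read_gff3(config.gff3, genome)
    if config.proteome_fasta and Path(config.proteome_fasta).exists():
        proteome = genome_io.read_fasta(config.proteome_fasta)

    members_models: list[genome_io.GeneModel] = []
    member_proteins: dict[str, str] = {}
    name_map: dict[str, str] = {}

    # --- identify
    if proteome is not None:
        profile = identification.build_profile()
        annotations = None
        if config.annotations_tsv and Path(config.annotations_tsv).exists():
            ann = pd.read_csv(config.annotations_tsv, sep="\t")
            annotations = dict(zip(ann.id, ann.description))
        candidates = identification.gather_candidates(
            proteome, profile, annotations=annotations,
            evalue_max=config.evalue_max, keywords=config.keywords,
        )
        proteins = {r.id: r.residues for r in proteome}
        confirmed = identification.confirm_members(
            candidates, proteins, profile, config.mw_min_kda, config.mw_max_kda)
        member_proteins = {pid: proteins[pid] for pid in confirmed}
        if gff_models:
            members_models = [g for g in gff_models if g.gene_id in member_proteins]
            name_map = identification.assign_names(members_models, config.prefix)
        rows = []
        for pid in confirmed:
            stats = identification.protein_stats(member_proteins[pid])
            rows.append({
                "name": name_map.get(pid, pid), "gene_id": pid,
                "aa": stats.aa_count, "mw_kda": round(stats.mw_da / 1000, 1),
                "pi": round(stats.pi, 2),
            })
        pd.DataFrame(rows).to_csv(out / "members.tsv", sep="\t", index=False)
        report["family_size"] = len(confirmed)
        if members_models:
            per_chrom = pd.Series(
                [g.chromosome for g in members_models]).value_counts().to_dict()
            report["per_chromosome"] = per_chrom
        log.info("identify: %d members", len(confirmed))
    else:
        log.info("identify: skipped (no proteome)")

    # --- structure
    if members_models:
        table = structure.structures_table(members_models)
        table.to_csv(out / "structures.tsv", sep="\t", index=False)
        counts = table.pattern_class.value_counts().to_dict()
        total = len(table)
        report["intron_classes"] = {
            int(cls): {"count": int(cnt), "percent": round(100.0 * cnt / total, 1)}
            for cls, cnt in sorted(counts.items())
        }
        log.info("structure: %d models", total)

    # --- duplication
    if members_models:
        clusters = duplication.find_tandem_clusters(
            members_models, full_annotation=gff_models, proteins=member_proteins,
            max_intervening=config.max_intervening, window_bp=config.tandem_window_bp,
            min_coverage=config.min_coverage_pct, min_identity=config.min_identity_pct,
        )
        pairs = []
        if config.blocks_tsv and Path(config.blocks_tsv).exists():
            blocks = duplication.read_block_table(config.blocks_tsv)
            pairs = duplication.find_segmental_pairs(member_proteins, blocks)
        summary = duplication.duplication_summary(clusters, pairs, len(member_proteins))
        report["duplication"] = summary
        genome_io.write_bed(
            [(c.chromosome, min(s for s, _ in _member_spans(c, members_models)),
              max(e for _, e in _member_spans(c, members_models)),
              "|".join(c.members)) for c in clusters],
            out / "tandem_clusters.bed",
        )
        log.info("duplication: %d tandem genes, %d segmental pairs",
                 summary["tandem_gene_count"], summary["segmental_pair_count"])

    # --- phylogeny
    if member_proteins and len(member_proteins) >= 3:
        seqs = [genome_io.SequenceRecord(pid, seq)
                for pid, seq in sorted(member_proteins.items())]
        labels = {}
        if config.reference_fasta and Path(config.reference_fasta).exists():
            seqs += genome_io.read_fasta(config.reference_fasta)
        if config.reference_labels_tsv and Path(config.reference_labels_tsv).exists():
            lab = pd.read_csv(config.reference_labels_tsv, sep="\t")
            labels = dict(zip(lab.id, lab.subfamily))
        msa = phylogeny.progressive_align(seqs)
        excluded, msa = phylogeny.flag_divergent(seqs, msa)
        tree = phylogeny.bootstrap_support(
            None, n_reps=config.bootstrap_reps, seed=config.seed, msa=msa)
        genome_io.write_newick(tree, out / "family.nwk")
        assignment = phylogeny.assign_subfamilies(tree, labels, config.min_support)
        pd.DataFrame(
            [{"id": k, "subfamily": v} for k, v in sorted(assignment.items())]
        ).to_csv(out / "subfamilies.tsv", sep="\t", index=False)
        tally: dict[str, int] = {}
        for pid in member_proteins:
            if pid in assignment:
                tally[assignment[pid]] = tally.get(assignment[pid], 0) + 1
        report["subfamilies"] = tally
        report["phylogeny_excluded"] = excluded
        log.info("phylogeny: %d leaves, %d excluded", len(msa.ids), len(excluded))

    # --- promoters
    if members_models and genome is not None:
        hits, statuses = promoters.scan_family_promoters(
            members_models, genome, length=config.promoter_length)
        matrix, element_free = promoters.summarize_elements(
            hits, [g.gene_id for g in members_models])
        matrix.to_csv(out / "elements_matrix.tsv", sep="\t")
        report["promoters"] = {
            "scanned": sum(1 for s in statuses if s.available),
            "absent": [s.gene_id for s in statuses if not s.available],
            "element_free": element_free,
            "with_hse": int((matrix["HSE"] > 0).sum()),
        }
        log.info("promoters: %d scanned", report["promoters"]["scanned"])

    # --- expression
    if config.fpkm_tsv and Path(config.fpkm_tsv).exists():
        fpkm = pd.read_csv(config.fpkm_tsv, sep="\t", index_col=0)
        transformed = expression.heatmap_transform(fpkm, config.pseudocount)
        transformed.to_csv(out / "fpkm_log2.tsv", sep="\t")
        _, never = expression.tissue_calls(fpkm, config.expressed_threshold)
        report["expression"] = {"never_expressed": never}
        log.info("expression: %d silent genes", len(never))
    if config.qpcr_tsv and Path(config.qpcr_tsv).exists():
        cq = pd.read_csv(config.qpcr_tsv, sep="\t")
        folds = expression.quantify_qpcr_table(
            cq, config.reference_gene, config.control_sample)
        folds.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
        extreme = sorted(set(
            folds[folds.response_class == expression.RESPONSE_UP_EXTREME]
            .loc[lambda d: d.condition == "heat", "gene"]
        ))
        report.setdefault("expression", {})["heat_up_extreme"] = extreme
        log.info("qPCR: %d extreme heat responders", len(extreme))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _member_spans(cluster, models):
    lookup = {g.gene_id: g for g in models}
    return [(lookup[m].start, lookup[m].end) for m in cluster.members]


def report_summary(report: dict, fmt: str = "tsv") -> str:
    """Render the report as TSV or Markdown lines ('count (pct%)' style)."""
    lines = []
    sep = "\t" if fmt == "tsv" else " | "
    total = report.get("family_size", 0)
    lines.append(sep.join(["section", "key", "value"]))
    lines.append(sep.join(["family", "size", str(total)]))
    for chrom, cnt in sorted(report.get("per_chromosome", {}).items()):
        lines.append(sep.join(["chromosome", str(chrom), str(cnt)]))
    for cls, info in report.get("intron_classes", {}).items():
        lines.append(sep.join([
            "intron_class", str(cls), f"{info['count']} ({info['percent']}%)"]))
    dup = report.get("duplication", {})
    if dup:
        lines.append(sep.join([
            "duplication", "tandem",
            f"{dup['tandem_gene_count']} ({dup['tandem_gene_pct']}%)"]))
        lines.append(sep.join([
            "duplication", "segmental_pairs", str(dup["segmental_pair_count"])]))
    for sub, cnt in sorted(report.get("subfamilies", {}).items()):
        lines.append(sep.join(["subfamily", sub, str(cnt)]))
    return "\n".join(lines) + "\n"
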