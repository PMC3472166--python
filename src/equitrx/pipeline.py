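"""End-to-end orchestration: clustering -> variants -> expression -> switches.

One flat config drives every stage; each stage logs records in/out so the
funnel from raw inputs to final calls is auditable. ``consistency_report``
is a pure arithmetic check over a table of named integer counts — it
recomputes every derived percentage and sum from its printed numerator and
denominator, the way a reader would audit a results section.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from . import expression_deg, isoform_switch, uc_builder, variant_caller
from .gtf import read_gtf, write_gtf
from .synthetic_data import write_vcf
from .uc_builder import percentage

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters; defaults documented in one place."""

    # inputs
    outdir: str = "equitrx_out"
    genome_fasta: str = ""
    reference_gtf: str = ""
    sample_gtf_dir: str = ""
    observations_dir: str = ""
    counts_tsv: str = ""
    sample_sheet: str = ""
    db1_vcf: str = ""
    db2_vcf: str = ""
    # uc stage
    min_orf_nt: int = 300
    min_fpkm: float = 0.0
    # variant stage
    min_depth: int = 4
    min_alt_reads: int = 2
    min_alt_fraction: float = 0.2
    hom_fraction: float = 0.8
    junction_window: int = 10
    min_nonsyn: int = 10
    # expression stage
    fold_threshold: float = 2.0
    min_horses: int = 4
    pseudocount: float = 0.1
    # switch stage
    switch_min_horses: int = 4
    switch_min_fpkm: float = 1.0
    switch_min_ratio: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self, n_horses: int) -> None:
        if self.min_horses > n_horses:
            raise ValueError(
                f"min_horses={self.min_horses} exceeds {n_horses} horses in the design"
            )
        if self.switch_min_horses > n_horses:
            raise ValueError(
                f"switch_min_horses={self.switch_min_horses} exceeds {n_horses} horses"
            )
        for key in ("genome_fasta", "reference_gtf", "sample_gtf_dir",
                    "observations_dir", "counts_tsv", "sample_sheet",
                    "db1_vcf", "db2_vcf"):
            path = getattr(self, key)
            if not path or not Path(path).exists():
                raise ValueError(f"config input {key}={path!r} does not exist")


STAGES = ("cluster", "variants", "express", "switch")


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the pipeline stages in order and write the output bundle.

    ``stages`` must be a prefix-closed subset of the full order; later
    stages consume earlier stages' in-memory results. Returns the summary
    dict (also written as ``summary.json``).
    """
    sheet = pd.read_csv(config.sample_sheet)
    config.validate(sheet.horse.nunique())
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    contigs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(config.genome_fasta, "fasta")
    }
    annotation = read_gtf(config.reference_gtf)
    summary: dict = {"parameters": dataclasses.asdict(config)}

    # ---- stage 1: unigene clusters ---------------------------------------
    transcripts = []
    for sid in sheet.sample_id:
        path = Path(config.sample_gtf_dir) / f"{sid}.gtf"
        models = read_gtf(path, sample_id=sid)
        transcripts.extend(models)
    logger.info("cluster: %d transcript models in", len(transcripts))
    clusters = uc_builder.cluster_transcripts(transcripts)
    clusters, status_counts = uc_builder.classify_against_annotation(
        clusters, annotation
    )
    novel_seqs = {
        c.uc_id: uc_builder.footprint_sequence(c, contigs)
        for c in clusters
        if c.status == "novel"
    }
    kept, discarded = uc_builder.orf_filter(novel_seqs, config.min_orf_nt)
    logger.info(
        "cluster: %d UCs out (%d annotated, %d novel; ORF filter kept %d)",
        len(clusters), status_counts["annotated"], status_counts["novel"], len(kept),
    )
    n_uc = len(clusters)
    summary["uc"] = {
        "n_transcripts": len(transcripts),
        "n_uc": n_uc,
        "n_annotated": status_counts["annotated"],
        "n_novel": status_counts["novel"],
        "pct_annotated": percentage(status_counts["annotated"], n_uc),
        "pct_novel": percentage(status_counts["novel"], n_uc),
        "novel_orf_kept": len(kept),
        "novel_orf_discarded": len(discarded),
        "total_footprint_bp": int(sum(c.footprint_length for c in clusters)),
    }
    # transcript -> UC map (same transcript id maps to one UC)
    uc_of_tid: dict[str, str] = {}
    for c in clusters:
        for m in c.members:
            uc_of_tid[m.transcript_id] = c.uc_id
    if "cluster" == stages[-1]:
        _finish(out, clusters, summary)
        return summary

    # ---- stage 2: variants ------------------------------------------------
    thresholds = variant_caller.CallThresholds(
        min_depth=config.min_depth,
        min_alt_reads=config.min_alt_reads,
        min_alt_fraction=config.min_alt_fraction,
        hom_fraction=config.hom_fraction,
    )
    per_sample_calls = []
    for sid in sheet.sample_id:
        obs = variant_caller.read_observations(
            Path(config.observations_dir) / f"{sid}.tsv"
        )
        per_sample_calls.append(variant_caller.call_sites(obs, sid, thresholds))
    calls = pd.concat(per_sample_calls, ignore_index=True)
    logger.info("variants: %d per-sample candidate calls", len(calls))
    boundaries = variant_caller.exon_boundaries(list(annotation) + transcripts)
    filtered = variant_caller.junction_misalignment_filter(
        calls, boundaries, config.junction_window
    )
    logger.info(
        "variants: junction filter removed %d candidates", len(calls) - len(filtered)
    )
    merged, _presence, specific = variant_caller.merge_nonredundant(filtered, sheet)
    merged, db_summary = variant_caller.compare_to_databases(
        merged, config.db1_vcf, config.db2_vcf
    )
    uc_footprints: dict[str, list] = {}
    for c in clusters:
        uc_footprints.setdefault(c.contig, []).extend(c.footprint)
    merged = variant_caller.annotate_effects(
        merged, annotation, contigs, uc_footprints
    )
    ranking, profiles = variant_caller.density_report(merged, config.min_nonsyn)
    n_snp = int((merged["type"] == "SNP").sum())
    n_indel = int((merged["type"] == "INDEL").sum())
    exonic = int((merged["location"] == "exonic_UC").sum())
    nonsyn = int((merged["effect"] == "non_synonymous").sum())
    syn = int((merged["effect"] == "synonymous").sum())
    summary["variants"] = {
        "candidate_calls": int(len(calls)),
        "after_junction_filter": int(len(filtered)),
        "n_snp": n_snp,
        "n_indel": n_indel,
        "total": n_snp + n_indel,
        "individual_specific": int(len(specific)),
        "shared": int(len(merged) - len(specific)),
        "db": db_summary,
        "exonic_uc": exonic,
        "pct_exonic_uc": percentage(exonic, len(merged)) if len(merged) else None,
        "non_synonymous": nonsyn,
        "synonymous": syn,
        "pct_non_synonymous": percentage(nonsyn, nonsyn + syn) if nonsyn + syn else None,
        "high_density_transcripts": int(len(ranking)),
    }
    vcf_df = merged.assign(
        DB=merged["db_status"],
        EFF=merged["effect"],
        LOC=merged["location"],
        CARRIERS=[",".join(c) for c in merged["carriers"]],
    )
    write_vcf(
        out / "variants.vcf",
        vcf_df,
        {c: len(s) for c, s in contigs.items()},
        info_columns=("DB", "EFF", "LOC", "CARRIERS"),
        info_meta={
            "DB": "database status", "EFF": "coding effect",
            "LOC": "location class", "CARRIERS": "carrying horses",
        },
    )
    ranking.to_csv(out / "nonsyn_density.tsv", sep="\t", index=False)
    profiles.to_csv(out / "nonsyn_profiles.tsv", sep="\t", index=False)
    if "variants" == stages[-1]:
        _finish(out, clusters, summary)
        return summary

    # ---- stage 3: expression ----------------------------------------------
    counts_table = pd.read_csv(config.counts_tsv, sep="\t", index_col="feature_id")
    lengths = counts_table["length"]
    gene_map = counts_table["gene_id"]
    counts = counts_table.drop(columns=["length", "gene_id"])
    counts = counts[list(sheet.sample_id)]
    totals = counts.sum(axis=0)
    tr_fpkm = expression_deg.compute_fpkm(counts, lengths, totals)

    uc_counts = counts.groupby(counts.index.map(uc_of_tid)).sum()
    uc_lengths = pd.Series(
        {c.uc_id: c.footprint_length for c in clusters}, name="length"
    ).loc[uc_counts.index]
    uc_fpkm = expression_deg.compute_fpkm(uc_counts, uc_lengths, totals)
    expressed = uc_builder.tissue_expressed_sets(
        clusters, uc_fpkm, sheet, config.min_fpkm
    )
    status_of = {c.uc_id: c.status for c in clusters}
    degs, deg_summary = expression_deg.call_degs(
        uc_fpkm,
        sheet,
        fold_threshold=config.fold_threshold,
        min_horses=config.min_horses,
        pseudocount=config.pseudocount,
        status=status_of,
    )
    logger.info("express: %d DEG records", len(degs))
    corr = expression_deg.correlation_matrix(uc_fpkm)
    quant = expression_deg.expression_quantiles(uc_fpkm)
    summary["expression"] = {
        "expressed_counts": expressed["counts"],
        "venn": expressed["venn"],
        "quantiles": quant,
        "degs": deg_summary,
    }
    uc_fpkm.to_csv(out / "uc_fpkm.tsv", sep="\t", index_label="uc_id")
    tr_fpkm.to_csv(out / "transcript_fpkm.tsv", sep="\t", index_label="transcript_id")
    corr.to_csv(out / "sample_correlation.tsv", sep="\t", index_label="sample_id")
    expression_deg.degs_to_frame(degs).to_csv(out / "degs.tsv", sep="\t", index=False)
    table = uc_builder.uc_table(clusters, expressed["expressed"])
    table.to_csv(out / "uc_table.tsv", sep="\t", index=False)
    if "express" == stages[-1]:
        _finish(out, clusters, summary, wrote_table=True)
        return summary

    # ---- stage 4: isoform switches ----------------------------------------
    events = isoform_switch.detect_switches(
        tr_fpkm,
        dict(gene_map),
        sheet,
        min_horses=config.switch_min_horses,
        min_fpkm=config.switch_min_fpkm,
        min_ratio=config.switch_min_ratio,
    )
    logger.info("switch: %d events", len(events))
    summary["switches"] = {
        "n_events": len(events),
        "genes": [ev.gene_id for ev in events],
    }
    isoform_switch.switches_to_frame(events).to_csv(
        out / "switch_events.tsv", sep="\t", index=False
    )
    isoform_switch.switch_profiles_long(events).to_csv(
        out / "switch_profiles.tsv", sep="\t", index=False
    )
    _finish(out, clusters, summary, wrote_table=True)
    return summary


def _finish(out: Path, clusters, summary: dict, wrote_table: bool = False) -> None:
    if not wrote_table:
        uc_builder.uc_table(clusters).to_csv(out / "uc_table.tsv", sep="\t", index=False)
    write_gtf(out / "uc_models.gtf", uc_builder.uc_models(clusters))
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# printed-count arithmetic consistency
# ---------------------------------------------------------------------------

# Headline counts printed by the motivating six-horse exercise study; used
# as the default input of `consistency_report` so its arithmetic can be
# audited without the original dataset.
STUDY_COUNTS: dict[str, int] = {
    "total_ucs": 32361,
    "annotated_ucs": 11933,
    "novel_ucs": 20428,
    "expressed_muscle_ucs": 17484,
    "expressed_blood_ucs": 25220,
    "snps": 182722,
    "indels": 7251,
    "novel_snvs": 171558,
    "snps_in_both_dbs": 7316,
    "exonic_snvs": 116650,
    "nonsynonymous_snvs": 67788,
    "individual_specific_snvs": 82476,
    "deg_up_blood": 62,
    "deg_down_blood": 80,
    "deg_up_muscle": 878,
    "deg_down_muscle": 285,
}


def consistency_report(counts: Mapping[str, int]) -> dict[str, float]:
    """Recompute derived percentages and sums from named integer counts.

    Pure function: every output equals ``percentage()`` (or integer
    addition) of the named inputs. Raises ``ValueError`` on a missing
    count.
    """
    required = {
        "total_ucs", "annotated_ucs", "novel_ucs", "snps", "indels",
        "novel_snvs", "snps_in_both_dbs", "exonic_snvs", "nonsynonymous_snvs",
        "deg_up_blood", "deg_down_blood", "deg_up_muscle", "deg_down_muscle",
    }
    missing = required - set(counts)
    if missing:
        raise ValueError(f"missing named counts: {sorted(missing)}")
    c = counts
    total_snvs = c["snps"] + c["indels"]
    return {
        "pct_annotated_ucs": percentage(c["annotated_ucs"], c["total_ucs"]),
        "pct_novel_ucs": percentage(c["novel_ucs"], c["total_ucs"]),
        "total_snvs": float(total_snvs),
        "pct_novel_snvs": percentage(c["novel_snvs"], total_snvs),
        "pct_snps_in_both_dbs": percentage(c["snps_in_both_dbs"], c["snps"]),
        "pct_exonic_snvs": percentage(c["exonic_snvs"], total_snvs),
        "pct_nonsynonymous": percentage(c["nonsynonymous_snvs"], c["exonic_snvs"]),
        "deg_total": float(
            c["deg_up_blood"] + c["deg_down_blood"]
            + c["deg_up_muscle"] + c["deg_down_muscle"]
        ),
    }
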