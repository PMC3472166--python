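"""Unigene-cluster (UC) construction and annotation-aware classification.

A UC is a maximal set of same-contig, same-strand transcript models from
any number of samples connected (transitively) through >= 1 bp of exonic
overlap. Clustering on exonic bases rather than genomic spans keeps nested
antisense or intron-hosted genes apart. Clusters are classified as
annotated or novel against a reference annotation, novel clusters can be
screened by a six-frame ORF-length filter, and per-tissue expressed sets
yield the blood/muscle/annotation Venn breakdown.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .gtf import (
    Interval,
    TranscriptModel,
    intervals_overlap,
    merge_intervals,
    revcomp,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UnigeneCluster:
    """A merged expressed locus built from exon-overlapping transcripts."""

    uc_id: str
    contig: str
    strand: str
    members: tuple[TranscriptModel, ...]
    footprint: tuple[Interval, ...]
    status: str | None = None  # "annotated" | "novel"
    matched_gene_ids: tuple[str, ...] = ()

    @property
    def start(self) -> int:
        return self.footprint[0][0]

    @property
    def end(self) -> int:
        return self.footprint[-1][1]

    @property
    def footprint_length(self) -> int:
        return sum(e - s for s, e in self.footprint)


def percentage(part: int, total: int) -> float:
    """100 * part / total, rounded half-up to two decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= part <= total:
        raise ValueError("part must be within [0, total]")
    return float(
        (Decimal(100 * part) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_transcripts(
    transcripts: Iterable[TranscriptModel],
    on_reject: Callable[[TranscriptModel, str], None] | None = None,
) -> list[UnigeneCluster]:
    """Partition transcript models into unigene clusters.

    Clusters are the connected components of the graph joining same-contig,
    same-strand transcripts that share >= 1 exonic base. Malformed records
    are rejected per-record (logged, or passed to ``on_reject``) rather
    than failing the run. The result is independent of input order: uc_ids
    are assigned by (contig, footprint start, strand).
    """
    valid: list[TranscriptModel] = []
    for t in transcripts:
        try:
            t.validate()
        except ValueError as exc:
            if on_reject is not None:
                on_reject(t, str(exc))
            logger.warning("rejecting transcript %s: %s", t.transcript_id, exc)
            continue
        valid.append(t)
    # deterministic processing order regardless of caller ordering
    valid.sort(key=lambda t: (t.contig, t.strand, t.start, t.end, t.transcript_id,
                              t.sample_id or ""))

    uf = _UnionFind(len(valid))
    groups: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(valid):
        groups.setdefault((t.contig, t.strand), []).append(i)

    for idx_list in groups.values():
        # sweep over exons: any exon starting before the running max end of
        # the current run overlaps something in the run -> same component
        events = sorted(
            (s, e, i) for i in idx_list for (s, e) in valid[i].exons
        )
        run_rep = -1
        run_end = -1
        for s, e, i in events:
            if run_rep >= 0 and s < run_end:
                uf.union(run_rep, i)
                run_end = max(run_end, e)
            else:
                run_rep = i
                run_end = e

    components: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(valid):
        components.setdefault(uf.find(i), []).append(t)

    clusters = []
    for members in components.values():
        footprint = merge_intervals(e for t in members for e in t.exons)
        clusters.append(
            UnigeneCluster(
                uc_id="",
                contig=members[0].contig,
                strand=members[0].strand,
                members=tuple(members),
                footprint=footprint,
            )
        )
    clusters.sort(key=lambda c: (c.contig, c.start, c.strand))
    return [replace(c, uc_id=f"UC{i:05d}") for i, c in enumerate(clusters)]


def _gene_exon_footprints(
    annotation: Sequence[TranscriptModel],
) -> dict[str, tuple[str, str, tuple[Interval, ...]]]:
    """gene_id -> (contig, strand, merged exonic intervals)."""
    per_gene: dict[str, tuple[str, str, list[Interval]]] = {}
    for t in annotation:
        contig, strand, ivs = per_gene.setdefault(t.gene_id, (t.contig, t.strand, []))
        ivs.extend(t.exons)
    return {
        g: (contig, strand, merge_intervals(ivs))
        for g, (contig, strand, ivs) in per_gene.items()
    }


def classify_against_annotation(
    clusters: Sequence[UnigeneCluster],
    annotation: Sequence[TranscriptModel],
) -> tuple[list[UnigeneCluster], dict[str, int]]:
    """Mark each UC annotated/novel by same-strand exonic overlap with genes.

    A UC is ``annotated`` iff its footprint shares >= 1 bp of exonic
    sequence, on the same strand, with any annotated gene; matched gene ids
    are recorded. An empty annotation classifies everything novel (warned).
    """
    if not annotation:
        logger.warning("empty annotation: all clusters classified novel")
    genes = _gene_exon_footprints(annotation)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g, (contig, strand, ivs) in genes.items():
        tree = trees.setdefault((contig, strand), IntervalTree())
        for s, e in ivs:
            tree.addi(s, e, g)
    out = []
    counts = {"annotated": 0, "novel": 0}
    for c in clusters:
        tree = trees.get((c.contig, c.strand))
        matched: set[str] = set()
        if tree is not None:
            for s, e in c.footprint:
                for hit in tree.overlap(s, e):
                    matched.add(hit.data)
        status = "annotated" if matched else "novel"
        counts[status] += 1
        out.append(replace(c, status=status, matched_gene_ids=tuple(sorted(matched))))
    return out, counts


def longest_orf(seq: str) -> int:
    """Longest ATG..stop ORF (nt, stop included) over all six frames."""
    best = 0
    for strand_seq in (seq.upper(), revcomp(seq.upper())):
        for frame in range(3):
            start = None
            for i in range(frame, len(strand_seq) - 2, 3):
                codon = strand_seq[i : i + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if start is not None:
                        best = max(best, i + 3 - start)
                        start = None
                elif codon == "ATG" and start is None:
                    start = i
    return best


def orf_filter(
    sequences: Mapping[str, str], min_orf_nt: int = 300
) -> tuple[set[str], set[str]]:
    """Partition sequences into (kept, discarded) by six-frame ORF length.

    A sequence is kept iff any reading frame on either strand contains a
    complete ORF (ATG through stop, stop included) of >= ``min_orf_nt`` nt.
    """
    if min_orf_nt < 3:
        raise ValueError("min_orf_nt must be >= 3")
    kept, discarded = set(), set()
    for name in sequences:
        (kept if longest_orf(sequences[name]) >= min_orf_nt else discarded).add(name)
    return kept, discarded


def footprint_sequence(cluster: UnigeneCluster, contigs: Mapping[str, str]) -> str:
    """Concatenated footprint sequence (plus-strand orientation)."""
    contig = contigs[cluster.contig]
    if cluster.end > len(contig):
        raise ValueError(f"{cluster.uc_id}: footprint outside genome bounds")
    return "".join(contig[s:e] for s, e in cluster.footprint)


def tissue_expressed_sets(
    clusters: Sequence[UnigeneCluster],
    fpkm: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_fpkm: float = 0.0,
) -> dict:
    """Per-tissue expressed UC sets and the blood/muscle/annotation Venn.

    A UC counts as expressed in a tissue iff its FPKM exceeds ``min_fpkm``
    in at least one sample of that tissue.
    """
    missing = set(sample_sheet.sample_id) - set(fpkm.columns)
    if missing:
        raise ValueError(f"sample sheet samples missing from FPKM matrix: {missing}")
    tissues = sorted(sample_sheet.tissue.unique())
    expressed: dict[str, set[str]] = {}
    for tissue in tissues:
        cols = sample_sheet.loc[sample_sheet.tissue == tissue, "sample_id"]
        sub = fpkm[list(cols)]
        expressed[tissue] = set(sub.index[(sub > min_fpkm).any(axis=1)])
    annotated = {c.uc_id for c in clusters if c.status == "annotated"}
    universe = {c.uc_id for c in clusters}
    blood = expressed.get("blood", set()) & universe
    muscle = expressed.get("muscle", set()) & universe
    venn = {
        "blood_only": len(blood - muscle - annotated),
        "muscle_only": len(muscle - blood - annotated),
        "annotated_only": len(annotated - blood - muscle),
        "blood_muscle": len((blood & muscle) - annotated),
        "blood_annotated": len((blood & annotated) - muscle),
        "muscle_annotated": len((muscle & annotated) - blood),
        "blood_muscle_annotated": len(blood & muscle & annotated),
        "none": len(universe - blood - muscle - annotated),
    }
    return {
        "expressed": expressed,
        "counts": {t: len(expressed[t] & universe) for t in tissues},
        "venn": venn,
    }


def uc_table(clusters: Sequence[UnigeneCluster], expressed: Mapping[str, set[str]] | None = None) -> pd.DataFrame:
    """Tabular UC summary (one row per cluster)."""
    rows = []
    for c in clusters:
        row = {
            "uc_id": c.uc_id,
            "contig": c.contig,
            "strand": c.strand,
            "start": c.start + 1,
            "end": c.end,
            "n_members": len(c.members),
            "footprint_length": c.footprint_length,
            "status": c.status,
            "matched_gene_ids": ",".join(c.matched_gene_ids),
        }
        for tissue in sorted(expressed or {}):
            row[f"expressed_{tissue}"] = c.uc_id in expressed[tissue]
        rows.append(row)
    return pd.DataFrame(rows)


def uc_models(clusters: Sequence[UnigeneCluster]) -> list[TranscriptModel]:
    """One merged-exon transcript model per UC (for GTF export)."""
    return [
        TranscriptModel(
            transcript_id=f"{c.uc_id}.model",
            gene_id=c.uc_id,
            contig=c.contig,
            strand=c.strand,
            exons=c.footprint,
        )
        for c in clusters
    ]
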