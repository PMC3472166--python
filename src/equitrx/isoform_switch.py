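"""Isoform expression-switch detection.

A switch is a reversal of the expression-dominance order between two
splice forms of one gene across the paired timepoints: isoform A dominates
B before exercise and B dominates A after, consistently in at least
``min_horses`` horses of a tissue. Dominance is evaluated on FPKM with a
configurable ratio margin, and the dominant isoform must clear a minimum
FPKM at both timepoints so noise around zero cannot fake a crossing.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .expression_deg import _paired_samples


@dataclass(frozen=True)
class SwitchEvent:
    """A reversed-dominance isoform pair; isoform_a dominates before."""

    gene_id: str
    isoform_a: str
    isoform_b: str
    tissue: str
    supporting_horses: tuple[str, ...]
    # horse -> ((a_before, a_after), (b_before, b_after)) FPKM
    profiles: Mapping[str, tuple[tuple[float, float], tuple[float, float]]]


def detect_switches(
    transcript_fpkm: pd.DataFrame,
    gene_map: Mapping[str, str],
    sample_sheet: pd.DataFrame,
    min_horses: int = 4,
    min_fpkm: float = 1.0,
    min_ratio: float = 1.0,
) -> list[SwitchEvent]:
    """Detect dominance switches between isoform pairs of each gene.

    For isoforms (a, b) of a gene and horse h, orientation "a first" holds
    iff FPKM_a > min_ratio * FPKM_b before AND FPKM_b > min_ratio * FPKM_a
    after, with the dominant isoform >= min_fpkm at both timepoints. An
    event is reported when >= min_horses horses agree on one orientation;
    one event is kept per gene — the pair/tissue with most support, ties
    broken by tissue then lexicographic isoform ids. Genes with fewer than
    two isoforms are skipped; horses lacking a timepoint are excluded.
    """
    if min_ratio <= 0:
        raise ValueError("min_ratio must be > 0")
    isoforms_by_gene: dict[str, list[str]] = {}
    for tid in transcript_fpkm.index:
        gene = gene_map.get(tid)
        if gene is not None:
            isoforms_by_gene.setdefault(gene, []).append(tid)

    candidates: list[SwitchEvent] = []
    for gene in sorted(isoforms_by_gene):
        isoforms = sorted(isoforms_by_gene[gene])
        if len(isoforms) < 2:
            continue
        for tissue in sorted(sample_sheet.tissue.unique()):
            pairs = _paired_samples(sample_sheet, tissue, on_missing="exclude")
            if not pairs:
                continue
            for a, b in itertools.combinations(isoforms, 2):
                support_ab, support_ba = [], []
                profiles: dict[str, tuple] = {}
                for horse in sorted(pairs):
                    before, after = pairs[horse]
                    fa = (float(transcript_fpkm.at[a, before]),
                          float(transcript_fpkm.at[a, after]))
                    fb = (float(transcript_fpkm.at[b, before]),
                          float(transcript_fpkm.at[b, after]))
                    profiles[horse] = (fa, fb)
                    if (
                        fa[0] > min_ratio * fb[0]
                        and fb[1] > min_ratio * fa[1]
                        and fa[0] >= min_fpkm
                        and fb[1] >= min_fpkm
                    ):
                        support_ab.append(horse)
                    elif (
                        fb[0] > min_ratio * fa[0]
                        and fa[1] > min_ratio * fb[1]
                        and fb[0] >= min_fpkm
                        and fa[1] >= min_fpkm
                    ):
                        support_ba.append(horse)
                if len(support_ab) >= len(support_ba):
                    first, second, support = a, b, support_ab
                else:
                    first, second, support = b, a, support_ba
                if len(support) >= min_horses:
                    if first != a:
                        profiles = {h: (pb, pa) for h, (pa, pb) in profiles.items()}
                    candidates.append(
                        SwitchEvent(
                            gene_id=gene,
                            isoform_a=first,
                            isoform_b=second,
                            tissue=tissue,
                            supporting_horses=tuple(support),
                            profiles=profiles,
                        )
                    )
    # keep the best-supported event per gene
    best: dict[str, SwitchEvent] = {}
    for ev in candidates:
        cur = best.get(ev.gene_id)
        if cur is None:
            best[ev.gene_id] = ev
            continue
        key = (-len(ev.supporting_horses), ev.tissue,
               tuple(sorted((ev.isoform_a, ev.isoform_b))))
        cur_key = (-len(cur.supporting_horses), cur.tissue,
                   tuple(sorted((cur.isoform_a, cur.isoform_b))))
        if key < cur_key:
            best[ev.gene_id] = ev
    return [best[g] for g in sorted(best)]


def switches_to_frame(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": ev.gene_id,
                "tissue": ev.tissue,
                "isoform_dominant_before": ev.isoform_a,
                "isoform_dominant_after": ev.isoform_b,
                "n_supporting": len(ev.supporting_horses),
                "supporting_horses": ",".join(ev.supporting_horses),
            }
            for ev in events
        ],
        columns=[
            "gene_id", "tissue", "isoform_dominant_before",
            "isoform_dominant_after", "n_supporting", "supporting_horses",
        ],
    )


def switch_profiles_long(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    """Plot-ready long format: one row per (gene, horse, isoform, timepoint)."""
    rows = []
    for ev in events:
        for horse in sorted(ev.profiles):
            (a_b, a_a), (b_b, b_a) = ev.profiles[horse]
            for iso, before, after in (
                (ev.isoform_a, a_b, a_a),
                (ev.isoform_b, b_b, b_a),
            ):
                rows.append({"gene_id": ev.gene_id, "tissue": ev.tissue,
                             "horse": horse, "isoform": iso,
                             "timepoint": "before", "fpkm": before})
                rows.append({"gene_id": ev.gene_id, "tissue": ev.tissue,
                             "horse": horse, "isoform": iso,
                             "timepoint": "after", "fpkm": after})
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tissue", "horse", "isoform", "timepoint", "fpkm"],
    )
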