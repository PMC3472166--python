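"""RNA-Seq variant discovery from pileup-style site observations.

The caller applies depth / alt-read / alt-fraction gates per sample, a
positional exon-intron boundary misalignment filter (spliced reads that
overhang a splice junction into the intron create clusters of false
alternate alleles near exon edges), merges per-sample calls into a
non-redundant set with per-horse carriers, flags individual-specific
variants, compares the set against two known-SNP databases (matching on
contig, position, ref AND alt), and annotates coding effects by
strand-aware codon substitution.

Observation tables use the schema written by the synthetic generator:
contig, pos (1-based), ref, A, C, G, T, indel_alt, indel_count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .gtf import (
    TranscriptModel,
    genomic_to_spliced,
    revcomp,
    spliced_sequence,
)

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

CALL_COLUMNS = [
    "contig", "pos", "ref", "alt", "type", "depth", "alt_count",
    "alt_fraction", "genotype", "sample_id",
]


@dataclass(frozen=True)
class CallThresholds:
    """Per-site calling gates ("stringent conditions"); all CLI-exposed."""

    min_depth: int = 4
    min_alt_reads: int = 2
    min_alt_fraction: float = 0.2
    hom_fraction: float = 0.8


@dataclass(frozen=True)
class SiteObservation:
    """Per-sample base counts at one genomic site (1-based position)."""

    contig: str
    pos: int
    ref: str
    sample_id: str
    base_counts: Mapping[str, int]
    indel_alt: str | None = None
    indel_count: int = 0


def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"indel_alt": str})
    df["indel_alt"] = df["indel_alt"].fillna(".")
    return df


def call_sites(
    observations: pd.DataFrame,
    sample_id: str,
    thresholds: CallThresholds = CallThresholds(),
) -> pd.DataFrame:
    """Candidate variants for one sample.

    A site is called iff depth >= min_depth, alternate reads >=
    min_alt_reads and alternate fraction >= min_alt_fraction; the genotype
    is hom when the alternate fraction reaches ``hom_fraction``, else het.
    Rows whose reference base is not A/C/G/T are skipped with a log entry.
    """
    obs = observations
    bad = ~obs["ref"].str[0].isin(BASES)
    if bad.any():
        for _, row in obs[bad].iterrows():
            logger.warning(
                "%s: skipping site %s:%d with unknown ref %r",
                sample_id, row.contig, row.pos, row.ref,
            )
        obs = obs[~bad]
    depth = obs[list(BASES)].sum(axis=1) + obs["indel_count"]
    rows = []
    t = thresholds
    for base in BASES:
        is_snp_row = obs["ref"].str.len() == 1
        alt_count = obs[base]
        frac = alt_count / depth.replace(0, np.nan)
        keep = (
            is_snp_row
            & (obs["ref"] != base)
            & (depth >= t.min_depth)
            & (alt_count >= t.min_alt_reads)
            & (frac >= t.min_alt_fraction)
        )
        sub = obs[keep]
        if len(sub):
            rows.append(
                pd.DataFrame(
                    {
                        "contig": sub.contig,
                        "pos": sub.pos,
                        "ref": sub.ref,
                        "alt": base,
                        "type": "SNP",
                        "depth": depth[keep],
                        "alt_count": alt_count[keep],
                        "alt_fraction": frac[keep],
                    }
                )
            )
    frac_i = obs["indel_count"] / depth.replace(0, np.nan)
    keep = (
        (obs["indel_alt"] != ".")
        & (depth >= t.min_depth)
        & (obs["indel_count"] >= t.min_alt_reads)
        & (frac_i >= t.min_alt_fraction)
    )
    sub = obs[keep]
    if len(sub):
        rows.append(
            pd.DataFrame(
                {
                    "contig": sub.contig,
                    "pos": sub.pos,
                    "ref": sub.ref,
                    "alt": sub.indel_alt,
                    "type": "INDEL",
                    "depth": depth[keep],
                    "alt_count": sub.indel_count,
                    "alt_fraction": frac_i[keep],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=CALL_COLUMNS)
    calls = pd.concat(rows, ignore_index=True)
    calls["genotype"] = np.where(
        calls["alt_fraction"] >= t.hom_fraction, "hom", "het"
    )
    calls["sample_id"] = sample_id
    calls = calls.sort_values(["contig", "pos", "alt"], kind="mergesort")
    return calls[CALL_COLUMNS].reset_index(drop=True)


def exon_boundaries(transcripts: Iterable[TranscriptModel]) -> dict[str, np.ndarray]:
    """1-based positions of first/last exonic bases, per contig, sorted."""
    per_contig: dict[str, set[int]] = {}
    for t in transcripts:
        s = per_contig.setdefault(t.contig, set())
        for lo, hi in t.exons:
            s.add(lo + 1)
            s.add(hi)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in per_contig.items()}


def junction_misalignment_filter(
    candidates: pd.DataFrame,
    boundaries: Mapping[str, np.ndarray],
    window_bp: int = 10,
) -> pd.DataFrame:
    """Drop candidates within ``window_bp`` of any exon start/end.

    Purely positional, hence it commutes with the count-based gates, and a
    larger window never retains more candidates.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if candidates.empty:
        return candidates
    keep_mask = np.ones(len(candidates), dtype=bool)
    for contig, sub in candidates.groupby("contig", sort=False):
        b = boundaries.get(contig)
        if b is None or len(b) == 0:
            continue
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(b, pos)
        dist = np.full(len(pos), np.iinfo(np.int64).max)
        left_ok = idx > 0
        dist[left_ok] = np.abs(pos[left_ok] - b[idx[left_ok] - 1])
        right_ok = idx < len(b)
        dist[right_ok] = np.minimum(
            dist[right_ok], np.abs(b[idx[right_ok]] - pos[right_ok])
        )
        keep_mask[candidates.index.get_indexer(sub.index)] = dist > window_bp
    return candidates[keep_mask].reset_index(drop=True)


def merge_nonredundant(
    calls: pd.DataFrame, sample_sheet: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Merge per-sample call sets into non-redundant variants.

    Variants are keyed by (contig, pos, ref, alt); carriers aggregate the
    horses of all calling samples. A variant is individual-specific iff
    every carrying sample belongs to one horse (absence of a call is
    treated as absence of the allele). Conflicting reference alleles at
    one SNP position across samples raise ``ValueError``.

    Returns (merged, presence horse-matrix, individual-specific subset).
    """
    horse_of = dict(zip(sample_sheet.sample_id, sample_sheet.horse))
    if calls.empty:
        empty = pd.DataFrame(
            columns=["contig", "pos", "ref", "alt", "type", "carriers",
                     "samples", "n_horses", "individual_specific"]
        )
        return empty, pd.DataFrame(), empty

    snps = calls[calls["type"] == "SNP"]
    ref_per_pos = snps.groupby(["contig", "pos"])["ref"].nunique()
    if (ref_per_pos > 1).any():
        where = ref_per_pos[ref_per_pos > 1].index[0]
        raise ValueError(f"conflicting reference allele at {where[0]}:{where[1]}")

    calls = calls.assign(horse=calls["sample_id"].map(horse_of))
    if calls["horse"].isna().any():
        missing = sorted(calls.loc[calls["horse"].isna(), "sample_id"].unique())
        raise ValueError(f"samples absent from sample sheet: {missing}")

    grouped = calls.groupby(["contig", "pos", "ref", "alt", "type"], sort=True)
    rows = []
    for (contig, pos, ref, alt, vtype), sub in grouped:
        horses = tuple(sorted(sub["horse"].unique()))
        rows.append(
            {
                "contig": contig, "pos": pos, "ref": ref, "alt": alt,
                "type": vtype,
                "carriers": horses,
                "samples": tuple(sorted(sub["sample_id"].unique())),
                "n_horses": len(horses),
                "individual_specific": len(horses) == 1,
            }
        )
    merged = pd.DataFrame(rows).sort_values(
        ["contig", "pos", "ref", "alt"], kind="mergesort"
    ).reset_index(drop=True)

    horses = sorted(sample_sheet.horse.unique())
    presence = pd.DataFrame(
        [[h in row.carriers for h in horses] for row in merged.itertuples()],
        columns=horses,
        index=pd.MultiIndex.from_frame(merged[["contig", "pos", "ref", "alt"]]),
    )
    specific = merged[merged["individual_specific"]].reset_index(drop=True)
    return merged, presence, specific


def _load_vcf_keys(path: str | Path) -> set[tuple[str, int, str, str]]:
    keys = set()
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            keys.add((rec.CHROM, rec.POS, rec.REF, alt))
    return keys


def compare_to_databases(
    merged: pd.DataFrame, db1_path: str | Path, db2_path: str | Path
) -> tuple[pd.DataFrame, dict]:
    """Assign db_status (novel / db1_only / db2_only / both) per variant.

    A database match requires identical contig, position, reference AND
    alternate allele; positional-only matching would inflate the overlap.
    """
    from .uc_builder import percentage

    k1, k2 = _load_vcf_keys(db1_path), _load_vcf_keys(db2_path)
    status = []
    for row in merged.itertuples():
        key = (row.contig, int(row.pos), row.ref, row.alt)
        in1, in2 = key in k1, key in k2
        status.append(
            "both" if in1 and in2
            else "db1_only" if in1
            else "db2_only" if in2
            else "novel"
        )
    out = merged.assign(db_status=status)
    n = len(out)
    counts = out["db_status"].value_counts().to_dict()
    summary = {
        "total": n,
        "novel": counts.get("novel", 0),
        "db1_only": counts.get("db1_only", 0),
        "db2_only": counts.get("db2_only", 0),
        "both": counts.get("both", 0),
    }
    if n:
        summary["pct_novel"] = percentage(summary["novel"], n)
        summary["pct_both"] = percentage(summary["both"], n)
    return out, summary


# ---------------------------------------------------------------------------
# coding-effect annotation
# ---------------------------------------------------------------------------

class _CdsIndex:
    """Per-contig lookup from genomic position to transcript CDS context."""

    def __init__(self, annotation: Sequence[TranscriptModel], contigs: Mapping[str, str]):
        self.trees: dict[str, IntervalTree] = {}
        self.cds_seq: dict[str, str] = {}
        self.tx: dict[str, TranscriptModel] = {}
        self.bad_frame: set[str] = set()
        for t in annotation:
            if not t.cds:
                continue
            seq = spliced_sequence(contigs[t.contig], t.cds, t.strand)
            if len(seq) % 3 != 0:
                logger.warning(
                    "CDS length of %s not divisible by 3; marking NA", t.transcript_id
                )
                self.bad_frame.add(t.transcript_id)
                continue
            self.cds_seq[t.transcript_id] = seq
            self.tx[t.transcript_id] = t
            tree = self.trees.setdefault(t.contig, IntervalTree())
            for s, e in t.cds:
                tree.addi(s, e, t.transcript_id)

    def hits(self, contig: str, pos0: int) -> list[str]:
        tree = self.trees.get(contig)
        if tree is None:
            return []
        return sorted(h.data for h in tree.overlap(pos0, pos0 + 1))


def annotate_effects(
    merged: pd.DataFrame,
    annotation: Sequence[TranscriptModel],
    contigs: Mapping[str, str],
    uc_footprints: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Classify each variant's coding effect.

    SNPs inside an annotated CDS are substituted into their codon
    (strand-aware) and translated: synonymous iff the amino acid is
    unchanged in every overlapped CDS, non-synonymous otherwise. Indels in
    a CDS are non-synonymous. Variants outside any CDS but inside a UC
    exon footprint are non-coding (location ``exonic_UC``); everything
    else is location ``other`` with effect NA.

    Adds columns: location, effect, transcript_effects (tuple of
    (transcript_id, effect, cds_offset)).
    """
    index = _CdsIndex(annotation, contigs)
    uc_trees: dict[str, IntervalTree] = {}
    for contig, ivs in (uc_footprints or {}).items():
        tree = uc_trees.setdefault(contig, IntervalTree())
        for s, e in ivs:
            tree.addi(s, e)

    locations, effects, tx_effects = [], [], []
    for row in merged.itertuples():
        pos0 = int(row.pos) - 1
        hits = index.hits(row.contig, pos0)
        in_uc = bool(
            row.contig in uc_trees and uc_trees[row.contig].overlap(pos0, pos0 + 1)
        )
        per_tx = []
        for tid in hits:
            t = index.tx[tid]
            if row.type == "INDEL":
                per_tx.append((tid, "non_synonymous", genomic_to_spliced(t.cds, t.strand, pos0)))
                continue
            i = genomic_to_spliced(t.cds, t.strand, pos0)
            if i is None:
                continue
            cds = index.cds_seq[tid]
            ref_b = row.ref if t.strand == "+" else revcomp(row.ref)
            alt_b = row.alt if t.strand == "+" else revcomp(row.alt)
            if cds[i] != ref_b:
                logger.warning(
                    "reference mismatch for %s at %s:%s (CDS has %s, variant ref %s)",
                    tid, row.contig, row.pos, cds[i], ref_b,
                )
                continue
            codon_start = (i // 3) * 3
            codon = cds[codon_start : codon_start + 3]
            new_codon = codon[: i % 3] + alt_b + codon[i % 3 + 1 :]
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(new_codon).translate())
            per_tx.append(
                (tid, "synonymous" if aa_ref == aa_alt else "non_synonymous", i)
            )
        if per_tx:
            location = "exonic_UC" if in_uc else "other"
            effect = (
                "non_synonymous"
                if any(e == "non_synonymous" for _, e, _ in per_tx)
                else "synonymous"
            )
        elif in_uc:
            location, effect = "exonic_UC", "non_coding"
        else:
            location, effect = "other", "NA"
        locations.append(location)
        effects.append(effect)
        tx_effects.append(tuple(per_tx))
    return merged.assign(
        location=locations, effect=effects, transcript_effects=tx_effects
    )


def density_report(
    annotated: pd.DataFrame, min_nonsyn: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcripts ranked by non-synonymous variant count (>= min_nonsyn).

    Also returns a per-horse profile: each variant's transcript-relative
    CDS offset and effect class, one row per carrying horse, for the
    reported transcripts.
    """
    tally: dict[str, dict[str, int]] = {}
    profile_rows = []
    for row in annotated.itertuples():
        for tid, eff, offset in row.transcript_effects:
            d = tally.setdefault(tid, {"non_synonymous": 0, "synonymous": 0})
            if eff in d:
                d[eff] += 1
            for horse in row.carriers:
                profile_rows.append(
                    {
                        "transcript_id": tid, "horse": horse,
                        "contig": row.contig, "pos": row.pos,
                        "cds_offset": offset, "effect": eff,
                    }
                )
    ranking = pd.DataFrame(
        [
            {"transcript_id": tid, "n_nonsynonymous": d["non_synonymous"],
             "n_synonymous": d["synonymous"]}
            for tid, d in tally.items()
            if d["non_synonymous"] >= min_nonsyn
        ],
        columns=["transcript_id", "n_nonsynonymous", "n_synonymous"],
    ).sort_values(
        ["n_nonsynonymous", "transcript_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    keep = set(ranking.transcript_id)
    profiles = pd.DataFrame(
        [r for r in profile_rows if r["transcript_id"] in keep],
        columns=["transcript_id", "horse", "contig", "pos", "cds_offset", "effect"],
    )
    if len(profiles):
        profiles = profiles.sort_values(
            ["transcript_id", "horse", "pos"], kind="mergesort"
        ).reset_index(drop=True)
    return ranking, profiles
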