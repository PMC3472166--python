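"""FPKM quantification and fold-change-voting differential expression.

Expression is normalized as FPKM (fragments per kilobase of exon model per
million mapped fragments). Differential expression follows a per-horse
voting rule on the paired design: a feature is differentially expressed in
a tissue iff its after/before FPKM fold change is strictly greater than
the threshold (up) or strictly less than its reciprocal (down) in at least
``min_horses`` of the six horses. A pseudocount added to both terms keeps
folds finite at zero expression. With six horses and ``min_horses >= 4``
the up and down sets are provably disjoint.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed feature in one tissue."""

    feature_id: str
    tissue: str
    direction: str  # "up" | "down"
    supporting_horses: tuple[str, ...]
    fold_changes: Mapping[str, float]  # horse -> fold
    status: str | None = None  # annotated/novel when known


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM[f, s] = counts[f, s] * 1e9 / (length[f] * total[s]).

    ``totals`` defaults to the per-sample column sums; the transform is
    exactly invertible given lengths and totals.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive effective length")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be > 0")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def fpkm_to_counts(
    fpkm: pd.DataFrame, lengths: pd.Series, totals: pd.Series
) -> pd.DataFrame:
    """Algebraic inverse of :func:`compute_fpkm`."""
    return fpkm.mul(lengths.reindex(fpkm.index), axis=0).mul(
        totals.reindex(fpkm.columns), axis=1
    ) / 1e9


def correlation_matrix(fpkm: pd.DataFrame, transform: str = "log1p") -> pd.DataFrame:
    """Sample-by-sample Pearson correlation on log(x+1) expression.

    Raw FPKM correlations are dominated by a handful of extreme features;
    the log transform is the conventional remedy. Constant columns yield
    NA against every partner.
    """
    if len(fpkm) < 2:
        raise ValueError("need >= 2 features for correlations")
    x = np.log1p(fpkm) if transform == "log1p" else fpkm.copy()
    return x.corr(method="pearson")


def expression_quantiles(fpkm: pd.DataFrame) -> dict[str, float]:
    """Quartiles of the per-feature mean FPKM (linear interpolation)."""
    if fpkm.empty:
        raise ValueError("empty expression matrix")
    means = fpkm.mean(axis=1).to_numpy()
    q25, q50, q75 = np.percentile(means, [25, 50, 75])
    return {"q25": float(q25), "median": float(q50), "q75": float(q75)}


def _paired_samples(
    sample_sheet: pd.DataFrame, tissue: str, on_missing: str
) -> dict[str, tuple[str, str]]:
    """horse -> (before sample, after sample) for one tissue."""
    sub = sample_sheet[sample_sheet.tissue == tissue]
    pairs = {}
    for horse, rows in sub.groupby("horse"):
        before = rows.loc[rows.timepoint == "before", "sample_id"]
        after = rows.loc[rows.timepoint == "after", "sample_id"]
        if len(before) != 1 or len(after) != 1:
            msg = f"horse {horse} lacks a before/after pair in {tissue}"
            if on_missing == "exclude":
                logger.warning("%s; horse excluded", msg)
                continue
            raise ValueError(msg)
        pairs[horse] = (before.iloc[0], after.iloc[0])
    return pairs


def call_degs(
    fpkm: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    fold_threshold: float = 2.0,
    min_horses: int = 4,
    pseudocount: float = 0.1,
    status: Mapping[str, str] | None = None,
    on_missing: str = "error",
) -> tuple[list[DEGRecord], dict]:
    """Per-horse fold-change voting DEG caller.

    For each horse the fold is (FPKM_after + pseudocount) / (FPKM_before +
    pseudocount). "More than ``fold_threshold``-fold" is read strictly:
    up needs fold > threshold, down needs fold < 1/threshold, each in at
    least ``min_horses`` horses of that tissue.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    n_horses_total = sample_sheet.horse.nunique()
    if min_horses > n_horses_total:
        raise ValueError(
            f"min_horses={min_horses} exceeds the {n_horses_total} horses available"
        )
    records: list[DEGRecord] = []
    summary_counts: dict[str, dict[str, int]] = {}
    for tissue in sorted(sample_sheet.tissue.unique()):
        pairs = _paired_samples(sample_sheet, tissue, on_missing)
        horses = sorted(pairs)
        folds = pd.DataFrame(
            {
                h: (fpkm[pairs[h][1]] + pseudocount)
                / (fpkm[pairs[h][0]] + pseudocount)
                for h in horses
            }
        )
        up_votes = folds.gt(fold_threshold)
        down_votes = folds.lt(1.0 / fold_threshold)
        for direction, votes in (("up", up_votes), ("down", down_votes)):
            hit = votes.sum(axis=1) >= min_horses
            for fid in folds.index[hit]:
                supporters = tuple(h for h in horses if votes.at[fid, h])
                records.append(
                    DEGRecord(
                        feature_id=fid,
                        tissue=tissue,
                        direction=direction,
                        supporting_horses=supporters,
                        fold_changes={h: float(folds.at[fid, h]) for h in horses},
                        status=(status or {}).get(fid),
                    )
                )
        summary_counts[tissue] = {
            "up": int((up_votes.sum(axis=1) >= min_horses).sum()),
            "down": int((down_votes.sum(axis=1) >= min_horses).sum()),
        }
    raw_total = len(records)
    dedup_total = len({r.feature_id for r in records})
    novelty: dict[str, dict[str, int]] = {}
    if status is not None:
        for r in records:
            tiss = novelty.setdefault(r.tissue, {})
            key = r.status or "unknown"
            tiss[key] = tiss.get(key, 0) + 1
    summary = {
        "per_tissue": summary_counts,
        "total": raw_total,
        "total_deduplicated": dedup_total,
        "novelty_breakdown": novelty,
        "fold_threshold": fold_threshold,
        "min_horses": min_horses,
        "pseudocount": pseudocount,
    }
    return records, summary


def degs_to_frame(records: Sequence[DEGRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "feature_id": r.feature_id,
                "tissue": r.tissue,
                "direction": r.direction,
                "n_supporting": len(r.supporting_horses),
                "supporting_horses": ",".join(r.supporting_horses),
                "status": r.status or "",
                **{f"fold_{h}": v for h, v in sorted(r.fold_changes.items())},
            }
        )
    return pd.DataFrame(rows)


def crossref_gene_lists(
    records: Sequence[DEGRecord],
    known_genes: pd.DataFrame,
    feature_map: Mapping[str, str] | None = None,
    expressed: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Cross-reference DEG calls against a table of known genes.

    ``known_genes`` needs a ``gene_id`` column and may carry an expected
    ``direction``. ``feature_map`` maps gene ids to feature ids; identity
    by default. Unmappable ids are listed with mappable=False rather than
    silently dropped.
    """
    by_feature: dict[str, DEGRecord] = {}
    for r in records:
        by_feature.setdefault(r.feature_id, r)
    rows = []
    for row in known_genes.itertuples(index=False):
        gene = row.gene_id
        feature = (feature_map or {}).get(gene, gene if feature_map is None else None)
        mappable = feature is not None
        rec = by_feature.get(feature) if mappable else None
        expected = getattr(row, "direction", None)
        agreement = None
        if rec is not None and expected is not None:
            agreement = "agree" if rec.direction == expected else "disagree"
        out = {
            "gene_id": gene,
            "feature_id": feature or "",
            "mappable": mappable,
            "is_deg": rec is not None,
            "deg_tissue": rec.tissue if rec else "",
            "deg_direction": rec.direction if rec else "",
            "direction_agreement": agreement or "",
        }
        for tissue in sorted(expressed or {}):
            out[f"expressed_{tissue}"] = bool(mappable and feature in expressed[tissue])
        rows.append(out)
    return pd.DataFrame(rows)
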