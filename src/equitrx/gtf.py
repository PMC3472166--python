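"""Transcript models and minimal GTF input/output.

All coordinates held in memory are 0-based half-open; GTF files are read
and written in the format's 1-based inclusive convention. The reader keeps
only ``exon`` and ``CDS`` features, which is all a transcript model needs.
"""
from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

Interval = tuple[int, int]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Union of intervals: sorted, with touching/overlapping runs fused."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def intervals_overlap(a: Sequence[Interval], b: Sequence[Interval]) -> bool:
    """True iff the two sorted interval lists share >= 1 base."""
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i][1] <= b[j][0]:
            i += 1
        elif b[j][1] <= a[i][0]:
            j += 1
        else:
            return True
    return False


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware multi-exon transcript model on one contig.

    ``exons`` (and ``cds``, when present) are sorted, non-overlapping
    0-based half-open intervals. ``sample_id`` records which sample the
    model was assembled from; reference-annotation transcripts leave it
    ``None``.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]
    sample_id: str | None = None
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(sorted(tuple(e) for e in self.exons)))
        object.__setattr__(self, "cds", tuple(sorted(tuple(c) for c in self.cds)))

    # -- derived geometry ---------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def key(self) -> tuple[str | None, str]:
        return (self.sample_id, self.transcript_id)

    def validate(self) -> None:
        """Raise ``ValueError`` if the model violates its invariants."""
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")
            prev_end = e
        if self.spliced_length < 1:
            raise ValueError(f"{self.transcript_id}: zero exonic length")
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS interval ({s},{e}) outside exons"
                )


def spliced_to_genomic(
    exons: Sequence[Interval], strand: str, s: int, e: int
) -> tuple[Interval, ...]:
    """Map a spliced-coordinate interval [s, e) to genomic intervals.

    Spliced coordinate 0 is the transcript 5' end, so minus-strand
    transcripts walk their exons right to left.
    """
    order = exons if strand == "+" else tuple(reversed(exons))
    out = []
    cum = 0
    for gs, ge in order:
        length = ge - gs
        lo, hi = max(s, cum), min(e, cum + length)
        if lo < hi:
            if strand == "+":
                out.append((gs + lo - cum, gs + hi - cum))
            else:
                out.append((ge - (hi - cum), ge - (lo - cum)))
        cum += length
    return tuple(sorted(out))


def genomic_to_spliced(exons: Sequence[Interval], strand: str, pos: int) -> int | None:
    """Spliced (5'-based) offset of genomic position ``pos``, or None if intronic."""
    order = exons if strand == "+" else tuple(reversed(exons))
    cum = 0
    for gs, ge in order:
        if gs <= pos < ge:
            return cum + (pos - gs if strand == "+" else ge - 1 - pos)
        cum += ge - gs
    return None


def spliced_sequence(contig_seq: str, exons: Sequence[Interval], strand: str) -> str:
    """Transcript (5'->3') sequence from a contig string."""
    seq = "".join(contig_seq[s:e] for s, e in exons)
    return seq if strand == "+" else revcomp(seq)


# -- GTF I/O ----------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path, sample_id: str | None = None) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Only ``exon`` and ``CDS`` rows are used; transcripts are returned in a
    canonical (contig, start, transcript_id) order.
    """
    exons: dict[str, list[Interval]] = defaultdict(list)
    cds: dict[str, list[Interval]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GTF line: {line[:80]!r}")
            contig, _, feature, start, end, _, strand, _, attrs = cols
            if feature not in ("exon", "CDS"):
                continue
            a = _parse_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}: {feature} row lacks transcript_id")
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            prev = meta.get(tid)
            cur = (contig, strand, a.get("gene_id", tid))
            if prev is not None and prev[:2] != cur[:2]:
                raise ValueError(f"{path}: transcript {tid} spans contigs/strands")
            meta[tid] = cur
            (exons if feature == "exon" else cds)[tid].append(iv)
    models = []
    for tid, exon_list in exons.items():
        contig, strand, gene = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                contig=contig,
                strand=strand,
                exons=tuple(exon_list),
                cds=tuple(cds.get(tid, ())),
                sample_id=sample_id,
            )
        )
    models.sort(key=lambda t: (t.contig, t.start, t.transcript_id))
    return models


def write_gtf(
    path: str | Path, transcripts: Iterable[TranscriptModel], source: str = "equitrx"
) -> None:
    """Write transcript models as GTF (1-based inclusive), CDS frame included."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.contig, t.start, t.transcript_id)):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.contig}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            # frame: bases to skip before the first complete codon, accumulated
            # in transcription order (descending intervals on the minus strand)
            order = t.cds if t.strand == "+" else tuple(reversed(t.cds))
            cum = 0
            frames = {}
            for s, e in order:
                frames[(s, e)] = (3 - cum % 3) % 3
                cum += e - s
            for s, e in t.cds:
                fh.write(
                    f"{t.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t"
                    f"{frames[(s, e)]}\t{attrs}\n"
                )
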