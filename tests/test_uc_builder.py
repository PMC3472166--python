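"""Clustering vs a brute-force overlap oracle, classification, ORF filter."""
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import equitrx as ex
from equitrx.gtf import TranscriptModel, intervals_overlap
from equitrx.uc_builder import (
    classify_against_annotation,
    cluster_transcripts,
    footprint_sequence,
    longest_orf,
    orf_filter,
    percentage,
    tissue_expressed_sets,
)


def _tm(tid, exons, strand="+", contig="chr1", sample="s1", gene=None):
    return TranscriptModel(tid, gene or tid, contig, strand, tuple(exons), sample)


def _random_transcripts(rng, n=200, contigs=3):
    out = []
    for i in range(n):
        contig = f"chr{rng.integers(1, contigs + 1)}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        pos = int(rng.integers(0, 20_000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(20, 400))
        out.append(_tm(f"t{i}", exons, strand, contig, f"s{rng.integers(1, 4)}"))
    return out


def _oracle_partition(transcripts):
    """O(n^2) pairwise-overlap union-find, independent of the sweep code."""
    parent = list(range(len(transcripts)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(transcripts)):
        for j in range(i + 1, len(transcripts)):
            a, b = transcripts[i], transcripts[j]
            if a.contig != b.contig or a.strand != b.strand:
                continue
            if intervals_overlap(a.exons, b.exons):
                parent[find(j)] = find(i)
    groups = {}
    for i, t in enumerate(transcripts):
        groups.setdefault(find(i), set()).add(t.key)
    return {frozenset(g) for g in groups.values()}


def test_overlapping_same_strand_transcripts_form_one_cluster():
    clusters = cluster_transcripts(
        [_tm("a", [(100, 200)]), _tm("b", [(150, 300)], sample="s2")]
    )
    assert len(clusters) == 1
    assert clusters[0].footprint == ((100, 300),)


def test_opposite_strands_never_merge():
    clusters = cluster_transcripts(
        [_tm("a", [(100, 200)], "+"), _tm("b", [(150, 300)], "-")]
    )
    assert len(clusters) == 2


def test_span_overlap_without_exon_overlap_does_not_merge():
    # b sits entirely inside a's intron
    a = _tm("a", [(100, 200), (500, 600)])
    b = _tm("b", [(300, 400)])
    assert len(cluster_transcripts([a, b])) == 2


def test_clustering_matches_pairwise_oracle():
    rng = np.random.default_rng(42)
    transcripts = _random_transcripts(rng)
    clusters = cluster_transcripts(transcripts)
    got = {frozenset(m.key for m in c.members) for c in clusters}
    assert got == _oracle_partition(transcripts)


def test_malformed_transcripts_rejected_per_record():
    bad = TranscriptModel("bad", "bad", "chr1", "+", ((50, 10),))
    rejected = []
    clusters = cluster_transcripts(
        [_tm("ok", [(0, 100)]), bad], on_reject=lambda t, msg: rejected.append(t)
    )
    assert len(clusters) == 1
    assert [t.transcript_id for t in rejected] == ["bad"]


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_clustering_is_order_invariant_partition(seed):
    rng = np.random.default_rng(seed)
    transcripts = _random_transcripts(rng, n=40)
    clusters = cluster_transcripts(transcripts)
    # partition: every transcript in exactly one cluster
    keys = [m.key for c in clusters for m in c.members]
    assert sorted(keys) == sorted(t.key for t in transcripts)
    # order invariance, including identical uc_id assignment
    perm = list(transcripts)
    rng.shuffle(perm)
    again = cluster_transcripts(perm)
    assert [(c.uc_id, frozenset(m.key for m in c.members)) for c in clusters] == [
        (c.uc_id, frozenset(m.key for m in c.members)) for c in again
    ]
    # footprint bounds
    for c in clusters:
        total = sum(m.spliced_length for m in c.members)
        longest = max(m.spliced_length for m in c.members)
        assert longest <= c.footprint_length <= total


class TestClassification:
    REF = [TranscriptModel("r1", "gene1", "chr1", "+", ((100, 200), (400, 500)),
                           cds=((120, 180),))]

    def test_same_strand_exon_overlap_is_annotated(self):
        clusters = cluster_transcripts([_tm("a", [(150, 250)])])
        out, counts = classify_against_annotation(clusters, self.REF)
        assert out[0].status == "annotated"
        assert out[0].matched_gene_ids == ("gene1",)
        assert counts == {"annotated": 1, "novel": 0}

    def test_intergenic_cluster_is_novel(self):
        clusters = cluster_transcripts([_tm("a", [(5000, 5100)])])
        out, counts = classify_against_annotation(clusters, self.REF)
        assert out[0].status == "novel"

    def test_intron_contained_cluster_is_novel(self):
        clusters = cluster_transcripts([_tm("a", [(250, 350)])])
        out, _ = classify_against_annotation(clusters, self.REF)
        assert out[0].status == "novel"

    def test_empty_annotation_warns_all_novel(self):
        clusters = cluster_transcripts([_tm("a", [(150, 250)])])
        out, counts = classify_against_annotation(clusters, [])
        assert counts == {"annotated": 0, "novel": 1}

    def test_corpus_classification_matches_planted_novelty(self, corpus):
        transcripts = [
            t for ms in corpus.sample_transcripts.values() for t in ms
        ]
        clusters = cluster_transcripts(transcripts)
        out, _ = classify_against_annotation(clusters, corpus.genome.annotation)
        truth = dict(
            zip(corpus.truth.novelty_truth.transcript_id,
                corpus.truth.novelty_truth.status)
        )
        for c in out:
            statuses = {truth[m.transcript_id] for m in c.members}
            assert len(statuses) == 1  # placements are unambiguous
            assert c.status == statuses.pop()


def _oracle_longest_orf(seq):
    """Regex six-frame scan, independent of the codon-walk implementation."""
    from equitrx.gtf import revcomp

    best = 0
    for s in (seq.upper(), revcomp(seq.upper())):
        for frame in range(3):
            codons = [s[i: i + 3] for i in range(frame, len(s) - 2, 3)]
            joined = " ".join(codons)
            for m in re.finditer(r"ATG( [ACGT]{3})*? (TAA|TAG|TGA)", joined):
                best = max(best, (len(m.group(0)) + 1) // 4 * 3)
    return best


class TestOrfFilter:
    def test_minimal_complete_orf_kept(self):
        kept, discarded = orf_filter({"x": "ATGAAATAA"}, min_orf_nt=9)
        assert kept == {"x"} and not discarded

    def test_no_start_codon_discarded(self):
        # no ATG in any frame on either strand (and no CAT on the forward strand)
        seq = "CCGCCGCCGCCGCCGCCG"
        kept, discarded = orf_filter({"x": seq}, min_orf_nt=3)
        assert discarded == {"x"}

    def test_random_sequences_match_bruteforce_scanner(self):
        rng = np.random.default_rng(7)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), 1000))
            for i in range(100)
        }
        for min_nt in (150, 300):
            kept, _ = orf_filter(seqs, min_nt)
            oracle_kept = {k for k, s in seqs.items()
                           if _oracle_longest_orf(s) >= min_nt}
            assert kept == oracle_kept

    def test_longest_orf_agrees_with_oracle_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            s = "".join(rng.choice(list("ACGT"), 300))
            assert longest_orf(s) == _oracle_longest_orf(s)

    def test_footprint_outside_genome_bounds_errors(self, corpus):
        c = cluster_transcripts([_tm("a", [(10**9, 10**9 + 10)])])[0]
        with pytest.raises(ValueError, match="bounds"):
            footprint_sequence(c, corpus.genome.contigs)


class TestPercentage:
    @pytest.mark.parametrize(
        "part,total,expected",
        [
            (11933, 32361, 36.87),
            (20428, 32361, 63.13),
            (0, 32361, 0.0),
            (7316, 182722, 4.00),
            (116650, 189973, 61.40),
            (67788, 116650, 58.11),
            (171558, 189973, 90.31),
            (1, 8, 12.5),
            (1, 3, 33.33),
        ],
    )
    def test_round_half_up_two_decimals(self, part, total, expected):
        assert percentage(part, total) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percentage(1, 0)
        with pytest.raises(ValueError):
            percentage(5, 3)


class TestTissueExpression:
    def _setup(self, rng):
        clusters = cluster_transcripts(
            [_tm(f"t{i}", [(i * 1000, i * 1000 + 100)]) for i in range(20)]
        )
        clusters, _ = classify_against_annotation(clusters, [])
        sheet = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "horse": [f"H{i % 4}" for i in range(8)],
                "tissue": ["blood"] * 4 + ["muscle"] * 4,
                "timepoint": ["before", "after"] * 4,
            }
        )
        fpkm = pd.DataFrame(
            rng.exponential(1.0, (20, 8)) * (rng.random((20, 8)) > 0.4),
            index=[c.uc_id for c in clusters],
            columns=sheet.sample_id,
        )
        return clusters, fpkm, sheet

    def test_zero_everywhere_is_in_neither_set(self):
        rng = np.random.default_rng(0)
        clusters, fpkm, sheet = self._setup(rng)
        fpkm.iloc[0] = 0.0
        res = tissue_expressed_sets(clusters, fpkm, sheet, min_fpkm=0.0)
        uc = fpkm.index[0]
        assert uc not in res["expressed"]["blood"]
        assert uc not in res["expressed"]["muscle"]

    def test_single_muscle_sample_makes_muscle_only(self):
        rng = np.random.default_rng(1)
        clusters, fpkm, sheet = self._setup(rng)
        fpkm.iloc[1] = 0.0
        fpkm.iloc[1, 5] = 3.0  # one muscle sample
        res = tissue_expressed_sets(clusters, fpkm, sheet, min_fpkm=0.0)
        uc = fpkm.index[1]
        assert uc in res["expressed"]["muscle"]
        assert uc not in res["expressed"]["blood"]

    def test_sets_match_bruteforce_scan_and_venn_sums(self):
        rng = np.random.default_rng(2)
        clusters, fpkm, sheet = self._setup(rng)
        res = tissue_expressed_sets(clusters, fpkm, sheet, min_fpkm=0.5)
        for tissue in ("blood", "muscle"):
            cols = [s for s, t in zip(sheet.sample_id, sheet.tissue) if t == tissue]
            oracle = {
                f for f in fpkm.index
                if max(fpkm.at[f, c] for c in cols) > 0.5
            }
            assert res["expressed"][tissue] == oracle
        assert sum(res["venn"].values()) == len(clusters)

    def test_sample_sheet_mismatch_errors(self):
        rng = np.random.default_rng(3)
        clusters, fpkm, sheet = self._setup(rng)
        sheet = pd.concat(
            [sheet, pd.DataFrame([{"sample_id": "ghost", "horse": "H9",
                                   "tissue": "blood", "timepoint": "before"}])]
        )
        with pytest.raises(ValueError):
            tissue_expressed_sets(clusters, fpkm, sheet)
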