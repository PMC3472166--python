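"""Calling gates, the junction misalignment filter, merging and effects."""
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from equitrx.gtf import TranscriptModel, spliced_sequence
from equitrx.synthetic_data import OBS_COLUMNS, write_vcf
from equitrx.variant_caller import (
    CallThresholds,
    annotate_effects,
    call_sites,
    compare_to_databases,
    density_report,
    exon_boundaries,
    junction_misalignment_filter,
    merge_nonredundant,
)


def _obs(rows):
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


SHEET = pd.DataFrame(
    {
        "sample_id": [f"H{h}_{t}_{p}" for h in (1, 2) for t in ("blood", "muscle")
                      for p in ("before", "after")],
        "horse": [f"H{h}" for h in (1, 2) for _ in range(4)],
        "tissue": ["blood", "blood", "muscle", "muscle"] * 2,
        "timepoint": ["before", "after"] * 4,
    }
)


class TestCallSites:
    def test_balanced_site_is_het(self):
        obs = _obs([("chr1", 100, "A", 15, 0, 15, 0, ".", 0)])
        calls = call_sites(obs, "s1")
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row.alt, row.type, row.genotype) == ("G", "SNP", "het")

    def test_depth_below_threshold_not_called(self):
        obs = _obs([("chr1", 100, "A", 1, 0, 2, 0, ".", 0)])
        assert call_sites(obs, "s1", CallThresholds(min_depth=4)).empty

    def test_high_fraction_is_hom(self):
        obs = _obs([("chr1", 100, "A", 1, 0, 29, 0, ".", 0)])
        assert call_sites(obs, "s1").iloc[0].genotype == "hom"

    def test_unknown_ref_base_skipped(self):
        obs = _obs([("chr1", 100, "N", 0, 0, 30, 0, ".", 0),
                    ("chr1", 200, "A", 0, 30, 0, 0, ".", 0)])
        calls = call_sites(obs, "s1")
        assert list(calls.pos) == [200]

    def test_indels_called_through_same_gates(self):
        obs = _obs([("chr1", 100, "A", 14, 0, 0, 0, "AGG", 16),
                    ("chr1", 200, "AT", 29, 0, 0, 0, "A", 1)])
        calls = call_sites(obs, "s1")
        assert list(calls.type) == ["INDEL"]
        assert calls.iloc[0].alt == "AGG"

    def test_raising_any_threshold_never_adds_calls(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(300):
            depth = rng.integers(0, 60)
            alt = rng.integers(0, depth + 1)
            rows.append(("chr1", 10 + i, "A", depth - alt, alt, 0, 0, ".", 0))
        obs = _obs(rows)
        base = CallThresholds()
        baseline_keys = set(map(tuple, call_sites(obs, "s")[["pos", "alt"]].values))
        for stricter in (
            CallThresholds(min_depth=10),
            CallThresholds(min_alt_reads=5),
            CallThresholds(min_alt_fraction=0.4),
        ):
            keys = set(map(tuple, call_sites(obs, "s", stricter)[["pos", "alt"]].values))
            assert keys <= baseline_keys


class TestJunctionFilter:
    TX = [TranscriptModel("t1", "g1", "chr1", "+", ((100, 200), (300, 400)))]

    def _cand(self, positions):
        return pd.DataFrame(
            {"contig": "chr1", "pos": positions, "ref": "A", "alt": "G",
             "type": "SNP", "sample_id": "s1"}
        )

    def test_near_exon_end_removed_interior_retained(self):
        bounds = exon_boundaries(self.TX)
        # 1-based boundary positions are 101, 200, 301, 400
        cands = self._cand([197, 150])  # 3 bp from exon end; 49 bp interior
        out = junction_misalignment_filter(cands, bounds, window_bp=10)
        assert list(out.pos) == [150]

    def test_monotone_in_window(self):
        bounds = exon_boundaries(self.TX)
        cands = self._cand(list(range(101, 200)))
        prev = None
        for w in (0, 2, 5, 10, 20, 49):
            kept = set(junction_misalignment_filter(cands, bounds, w).pos)
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_commutes_with_count_gates(self):
        rng = np.random.default_rng(6)
        rows = [("chr1", int(p), "A", int(d - a), int(a), 0, 0, ".", 0)
                for p, d, a in zip(rng.integers(90, 410, 200),
                                   rng.integers(1, 50, 200),
                                   rng.integers(0, 20, 200))]
        obs = _obs(rows).drop_duplicates(["contig", "pos"])
        bounds = exon_boundaries(self.TX)
        # filter-then-call equals call-then-filter (the filter is positional)
        a = junction_misalignment_filter(call_sites(obs, "s"), bounds, 10)
        b = call_sites(junction_misalignment_filter(obs, bounds, 10), "s")
        assert set(zip(a.pos, a.alt)) == set(zip(b.pos, b.alt))


class TestMerge:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["contig", "pos", "ref", "alt", "type", "sample_id"]
        )

    def test_three_samples_two_horses_not_individual_specific(self):
        calls = self._calls([
            ("chr1", 10, "A", "G", "SNP", "H1_blood_before"),
            ("chr1", 10, "A", "G", "SNP", "H1_muscle_after"),
            ("chr1", 10, "A", "G", "SNP", "H2_blood_before"),
        ])
        merged, presence, specific = merge_nonredundant(calls, SHEET)
        assert len(merged) == 1
        assert merged.iloc[0].carriers == ("H1", "H2")
        assert not merged.iloc[0].individual_specific
        assert specific.empty

    def test_single_horse_both_tissues_is_individual_specific(self):
        calls = self._calls([
            ("chr1", 10, "A", "G", "SNP", "H1_blood_before"),
            ("chr1", 10, "A", "G", "SNP", "H1_muscle_before"),
        ])
        merged, _, specific = merge_nonredundant(calls, SHEET)
        assert len(specific) == 1
        assert merged.iloc[0].carriers == ("H1",)

    def test_conflicting_reference_alleles_error(self):
        calls = self._calls([
            ("chr1", 10, "A", "G", "SNP", "H1_blood_before"),
            ("chr1", 10, "C", "G", "SNP", "H2_blood_before"),
        ])
        with pytest.raises(ValueError, match="conflicting"):
            merge_nonredundant(calls, SHEET)

    def test_counts_match_bruteforce_set_algebra(self):
        rng = np.random.default_rng(9)
        rows = []
        for _ in range(400):
            pos = int(rng.integers(1, 60))
            sid = SHEET.sample_id[int(rng.integers(0, len(SHEET)))]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt != "A":
                rows.append(("chr1", pos, "A", alt, "SNP", sid))
        calls = self._calls(rows).drop_duplicates()
        merged, presence, specific = merge_nonredundant(calls, SHEET)
        # independent dict-based oracle
        horse_of = dict(zip(SHEET.sample_id, SHEET.horse))
        oracle: dict[tuple, set] = {}
        for r in calls.itertuples():
            oracle.setdefault((r.contig, r.pos, r.ref, r.alt), set()).add(
                horse_of[r.sample_id]
            )
        assert len(merged) == len(oracle)
        assert len(specific) == sum(1 for v in oracle.values() if len(v) == 1)
        assert len(specific) + int((~merged.individual_specific).sum()) == len(merged)
        for r in merged.itertuples():
            assert set(r.carriers) == oracle[(r.contig, r.pos, r.ref, r.alt)]
        assert presence.to_numpy().sum() == sum(len(v) for v in oracle.values())


class TestDatabases:
    def _merged(self, keys):
        return pd.DataFrame(
            [{"contig": c, "pos": p, "ref": r, "alt": a, "type": "SNP"}
             for c, p, r, a in keys]
        )

    def test_status_assignment(self, tmp_path):
        db1 = pd.DataFrame([{"contig": "chr1", "pos": 10, "ref": "A", "alt": "G"},
                            {"contig": "chr1", "pos": 30, "ref": "T", "alt": "C"}])
        db2 = pd.DataFrame([{"contig": "chr1", "pos": 10, "ref": "A", "alt": "G"}])
        write_vcf(tmp_path / "1.vcf", db1, {"chr1": 1000})
        write_vcf(tmp_path / "2.vcf", db2, {"chr1": 1000})
        merged = self._merged([
            ("chr1", 10, "A", "G"),   # both
            ("chr1", 30, "T", "C"),   # db1 only
            ("chr1", 50, "G", "A"),   # neither
            ("chr1", 10, "A", "T"),   # same position, different alt -> novel
        ])
        out, summary = compare_to_databases(merged, tmp_path / "1.vcf", tmp_path / "2.vcf")
        status = dict(zip(out.pos.astype(int).astype(str) + out.alt, out.db_status))
        assert status == {"10G": "both", "30C": "db1_only", "50A": "novel",
                          "10T": "novel"}
        assert summary["total"] == 4 and summary["both"] == 1
        assert summary["pct_both"] == 25.0


def _toy_coding_genome():
    """Two genes (one per strand) with spliced CDS on a 600 bp contig."""
    rng = np.random.default_rng(13)
    seq = list("".join(rng.choice(list("ACGT"), 600)))
    # plus-strand gene: CDS split over two exons
    cds_plus = "ATGGGAGAAACCCTTTGTGACTAA"  # 8 codons
    seq[100:112] = cds_plus[:12]
    seq[150:162] = cds_plus[12:]
    # minus-strand gene: CDS on one exon, reverse complemented
    cds_minus = "ATGCCTAGGTTACGATGA"
    rc = str(Seq(cds_minus).reverse_complement())
    seq[300 : 300 + len(rc)] = rc
    contigs = {"chr1": "".join(seq)}
    tx = [
        TranscriptModel("p1", "gp", "chr1", "+", ((100, 112), (150, 162)),
                        cds=((100, 112), (150, 162))),
        TranscriptModel("m1", "gm", "chr1", "-", ((300, 300 + len(rc)),),
                        cds=((300, 300 + len(rc)),)),
    ]
    return contigs, tx


class TestEffects:
    def _variant(self, pos, ref, alt):
        return pd.DataFrame([
            {"contig": "chr1", "pos": pos, "ref": ref, "alt": alt, "type": "SNP",
             "carriers": ("H1",)}
        ])

    def test_third_codon_position_synonymous(self):
        contigs, tx = _toy_coding_genome()
        # codon 2 is GGA (Gly); its third base is genomic position 106 (1-based)
        out = annotate_effects(self._variant(106, "A", "G"), tx, contigs)
        assert out.iloc[0].effect == "synonymous"  # GGA -> GGG, still Gly

    def test_first_codon_position_nonsynonymous(self):
        contigs, tx = _toy_coding_genome()
        out = annotate_effects(self._variant(104, "G", "A"), tx, contigs)
        assert out.iloc[0].effect == "non_synonymous"  # GGA -> AGA, Gly -> Arg

    def test_minus_strand_codon_built_on_transcript_strand(self):
        contigs, tx = _toy_coding_genome()
        # last genomic base of the minus gene is the CDS's first base (A of ATG)
        pos = 300 + 18  # 1-based position of genomic interval end
        out = annotate_effects(self._variant(pos, contigs["chr1"][pos - 1], "A"),
                               tx, contigs)
        assert out.iloc[0].effect in ("synonymous", "non_synonymous")

    def test_indel_in_cds_is_nonsynonymous(self):
        contigs, tx = _toy_coding_genome()
        v = self._variant(105, "A", "AT")
        v["type"] = "INDEL"
        out = annotate_effects(v, tx, contigs)
        assert out.iloc[0].effect == "non_synonymous"

    def test_noncoding_inside_uc_footprint(self):
        contigs, tx = _toy_coding_genome()
        out = annotate_effects(
            self._variant(500, contigs["chr1"][499], "A"), tx, contigs,
            uc_footprints={"chr1": [(480, 520)]},
        )
        assert out.iloc[0].effect == "non_coding"
        assert out.iloc[0].location == "exonic_UC"

    def test_outside_everything_is_na(self):
        contigs, tx = _toy_coding_genome()
        out = annotate_effects(self._variant(500, contigs["chr1"][499], "A"),
                               tx, contigs)
        assert out.iloc[0].effect == "NA"
        assert out.iloc[0].location == "other"

    def test_cds_length_not_multiple_of_three_marked_na(self, caplog):
        contigs, tx = _toy_coding_genome()
        broken = [TranscriptModel("b1", "gb", "chr1", "+", ((100, 111),),
                                  cds=((100, 111),))]
        out = annotate_effects(self._variant(106, "A", "G"), broken, contigs)
        assert out.iloc[0].effect == "NA"


class TestDensityReport:
    def _annotated(self, tx_effects):
        return pd.DataFrame([
            {"contig": "chr1", "pos": 10 + i, "ref": "A", "alt": "G",
             "type": "SNP", "carriers": ("H1",), "transcript_effects": te}
            for i, te in enumerate(tx_effects)
        ])

    def test_threshold_boundary_inclusive(self):
        at = self._annotated([(("t1", "non_synonymous", i),) for i in range(3)])
        ranking, profiles = density_report(at, min_nonsyn=3)
        assert list(ranking.transcript_id) == ["t1"]
        assert ranking.iloc[0].n_nonsynonymous == 3
        ranking2, _ = density_report(at, min_nonsyn=4)
        assert ranking2.empty

    def test_planted_high_density_transcript_tops_ranking(self):
        rng = np.random.default_rng(3)
        effects = [(("hot", "non_synonymous", i),) for i in range(20)]
        for i in range(30):
            tid = f"t{rng.integers(0, 5)}"
            eff = "non_synonymous" if rng.random() < 0.5 else "synonymous"
            effects.append(((tid, eff, i),))
        at = self._annotated(effects)
        ranking, profiles = density_report(at, min_nonsyn=1)
        assert ranking.iloc[0].transcript_id == "hot"
        # brute-force tally agreement
        tally = {}
        for te in effects:
            for tid, eff, _ in te:
                if eff == "non_synonymous":
                    tally[tid] = tally.get(tid, 0) + 1
        got = dict(zip(ranking.transcript_id, ranking.n_nonsynonymous))
        assert got == {k: v for k, v in tally.items() if v >= 1}
        assert set(profiles.transcript_id) <= set(ranking.transcript_id)
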