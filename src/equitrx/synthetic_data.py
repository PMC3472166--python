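"""Self-contained synthetic study generator.

Emulates the data layout of a paired exercise transcriptome study — six
horses, blood and muscle, sampled before and after exercise (24 samples) —
at desk scale: a toy genome with annotated multi-exon genes, per-sample
transcript models (all annotated transcripts plus planted novel loci),
per-sample pileup-style site observations carrying planted genotypes and
junction-adjacent misalignment artifacts, a fragment-count matrix with
planted fold-change effects and isoform dominance switches, and two
known-SNP databases with controllable overlap.

Every planted signal is recorded in ground-truth tables so downstream
stages can be scored by parameter recovery. All randomness flows from one
integer seed through named ``numpy`` generator streams; the same seed
yields byte-identical output files.
"""
from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gtf import (
    Interval,
    TranscriptModel,
    merge_intervals,
    revcomp,
    spliced_to_genomic,
    write_gtf,
)

TISSUES = ("blood", "muscle")
TIMEPOINTS = ("before", "after")
DEFAULT_HORSES = ("H1", "H2", "H3", "H4", "H5", "H6")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

# named generator streams hanging off the master seed
_STREAM_GENOME = 1
_STREAM_SAMPLES = 2
_STREAM_COUNTS = 3
_STREAM_SITES = 4
_STREAM_DATABASES = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    sample_id: str
    horse: str
    tissue: str
    timepoint: str


@dataclass(frozen=True)
class StudyDesign:
    """The 6-horse x 2-tissue x 2-timepoint paired design."""

    horses: tuple[str, ...] = DEFAULT_HORSES
    tissues: tuple[str, ...] = TISSUES
    timepoints: tuple[str, ...] = TIMEPOINTS
    seed: int = 0

    def samples(self) -> list[Sample]:
        return [
            Sample(f"{h}_{ti}_{tp}", h, ti, tp)
            for h in self.horses
            for ti in self.tissues
            for tp in self.timepoints
        ]

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples()],
            columns=["sample_id", "horse", "tissue", "timepoint"],
        )


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    contigs: dict[str, str]
    annotation: list[TranscriptModel]

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.contigs):
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) sense codons + a stop; translates cleanly."""
    body = rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def generate_genome(
    n_contigs: int = 2,
    contig_length: int = 200_000,
    n_genes: int = 40,
    seed: int = 0,
) -> Genome:
    """Random genome with non-overlapping multi-exon, multi-isoform genes.

    Each gene has 2-8 exons and 1-3 isoforms; the full-length isoform
    carries a valid CDS (starts ATG, ends at a stop, length divisible by
    three, no internal stops) pasted into the genome strand-aware.
    Raises ``ValueError`` when the requested genes cannot be packed.
    """
    if contig_length < 50_000:
        raise ValueError("contig_length must be >= 50 kb")
    if n_genes < 2 * n_contigs:
        raise ValueError("need at least 2 genes per contig")
    rng = _rng(seed, _STREAM_GENOME)
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1

    contigs: dict[str, bytearray] = {}
    annotation: list[TranscriptModel] = []
    gi = 0
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        seq = _random_bases(rng, contig_length)
        cursor = int(rng.integers(500, 1500))
        for _ in range(per_contig[ci]):
            n_exons = int(rng.integers(2, 9))
            exon_lens = rng.integers(150, 401, n_exons)
            intron_lens = rng.integers(80, 401, max(n_exons - 1, 0))
            span = int(exon_lens.sum() + intron_lens.sum())
            start = cursor + int(rng.integers(300, 801))
            if start + span > contig_length - 500:
                raise ValueError(
                    f"infeasible packing: gene {gi} does not fit on {name} "
                    f"(need {start + span + 500} bp, have {contig_length})"
                )
            exons: list[Interval] = []
            pos = start
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"

            # design the mature mRNA of the full-length isoform, embed a CDS
            spliced_len = int(exon_lens.sum())
            cds_offset = int(rng.integers(30, 61))
            max_codons = (spliced_len - cds_offset - 30) // 3
            n_codons = int(rng.integers(40, max_codons + 1))
            mrna = list(_random_bases(rng, spliced_len).decode())
            cds_seq = _random_cds(rng, n_codons)
            mrna[cds_offset : cds_offset + 3 * n_codons] = cds_seq
            mrna_str = "".join(mrna)

            # paste the mRNA back into the genome, exon by exon
            order = exons if strand == "+" else list(reversed(exons))
            cum = 0
            for gs, ge in order:
                chunk = mrna_str[cum : cum + ge - gs]
                if strand == "-":
                    chunk = revcomp(chunk)
                seq[gs:ge] = chunk.encode()
                cum += ge - gs

            cds_genomic = spliced_to_genomic(
                tuple(exons), strand, cds_offset, cds_offset + 3 * n_codons
            )

            gene_id = f"G{gi:04d}"
            n_iso = int(rng.integers(1, 4))
            iso_exon_sets: list[tuple[Interval, ...]] = [tuple(exons)]
            droppable = list(range(1, n_exons - 1)) or [n_exons - 1]
            rng.shuffle(droppable)
            for k in range(min(n_iso - 1, len(droppable))):
                subset = tuple(
                    e for j, e in enumerate(exons) if j != droppable[k]
                )
                iso_exon_sets.append(subset)
            for iso_idx, iso_exons in enumerate(iso_exon_sets, start=1):
                annotation.append(
                    TranscriptModel(
                        transcript_id=f"{gene_id}.{iso_idx}",
                        gene_id=gene_id,
                        contig=name,
                        strand=strand,
                        exons=iso_exons,
                        cds=cds_genomic if iso_idx == 1 else (),
                    )
                )
            cursor = start + span
            gi += 1
        contigs[name] = seq.decode()
    return Genome(contigs=contigs, annotation=annotation)


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------

@dataclass
class TruthTables:
    """Ground truth for every planted signal (one row per planted item)."""

    deg_truth: pd.DataFrame       # feature_id, tissue, direction, horse, multiplier
    genotype_truth: pd.DataFrame  # horse, contig, pos, ref, alt, genotype
    artifact_sites: pd.DataFrame  # contig, pos, ref, alt, carrier_samples
    switch_truth: pd.DataFrame    # gene_id, isoform_a, isoform_b, tissue
    novelty_truth: pd.DataFrame   # transcript_id, status

    def __post_init__(self) -> None:
        geno = set(zip(self.genotype_truth.contig, self.genotype_truth.pos))
        art = set(zip(self.artifact_sites.contig, self.artifact_sites.pos))
        if geno & art:
            raise ValueError("artifact sites must be disjoint from genotype sites")


@dataclass
class CorpusConfig:
    """Generator knobs; defaults are the study conditions every test assumes."""

    n_contigs: int = 2
    contig_length: int = 200_000
    n_genes: int = 40
    n_novel_loci: int = 12
    # expression
    deg_per_tissue: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"blood": (4, 5), "muscle": (8, 3)}
    )  # tissue -> (n up, n down)
    effect: float = 4.0
    noise_cv: float = 0.1
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.2
    isoform_skew: tuple[float, float] = (2.0, 5.0)
    n_switch_genes: int = 4
    switch_ratio: float = 5.0
    # variants
    n_truth_sites: int = 200
    indel_fraction: float = 0.04
    n_background_sites: int = 200
    n_artifact_sites: int = 40
    depth_mean: float = 30.0
    base_error: float = 0.01
    junction_window: int = 10
    interior_margin: int = 5
    # databases
    db_overlap: tuple[float, float] = (0.5, 0.3)
    db_extra: int = 150
    seed: int = 0


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Median-1 multiplicative noise with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(shape)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return np.exp(rng.normal(0.0, sigma, shape))


def simulate_counts(
    design: StudyDesign,
    n_features: int = 2000,
    deg_per_tissue: Mapping[str, tuple[int, int]] | None = None,
    effect: float = 4.0,
    noise_cv: float = 0.1,
    baseline_log_mean: float = float(np.log(200.0)),
    baseline_log_sd: float = 1.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Feature x sample fragment-count matrix with planted fold changes.

    Each feature draws a log-normal baseline mean; a planted DEG multiplies
    the after-exercise mean of its tissue by ``effect`` (up) or ``1/effect``
    (down) in every horse, then multiplicative log-normal noise at
    coefficient of variation ``noise_cv`` is applied.

    Returns ``(counts, lengths, deg_truth)``.
    """
    if effect <= 0:
        raise ValueError("effect multiplier must be > 0")
    if deg_per_tissue is None:
        deg_per_tissue = {"blood": (50, 50), "muscle": (50, 50)}
    rng = _rng(seed, _STREAM_COUNTS)
    samples = design.samples()
    features = [f"F{i:05d}" for i in range(n_features)]
    lengths = pd.Series(
        rng.integers(500, 5001, n_features), index=features, name="length"
    )
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, n_features))

    n_deg_total = sum(u + d for u, d in deg_per_tissue.values())
    if n_deg_total > n_features:
        raise ValueError("more planted DEGs than features")
    chosen = rng.choice(n_features, size=n_deg_total, replace=False)
    truth_rows = []
    assignments: dict[int, tuple[str, str]] = {}
    cursor = 0
    for tissue in sorted(deg_per_tissue):
        n_up, n_down = deg_per_tissue[tissue]
        for direction, n in (("up", n_up), ("down", n_down)):
            for idx in chosen[cursor : cursor + n]:
                assignments[int(idx)] = (tissue, direction)
                mult = effect if direction == "up" else 1.0 / effect
                for h in design.horses:
                    truth_rows.append(
                        {
                            "feature_id": features[int(idx)],
                            "tissue": tissue,
                            "direction": direction,
                            "horse": h,
                            "multiplier": mult,
                        }
                    )
            cursor += n

    mean = np.tile(baseline[:, None], (1, len(samples)))
    for j, s in enumerate(samples):
        if s.timepoint != "after":
            continue
        for idx, (tissue, direction) in assignments.items():
            if s.tissue == tissue:
                mean[idx, j] *= effect if direction == "up" else 1.0 / effect
    counts = mean * _lognormal_noise(rng, noise_cv, mean.shape)
    counts_df = pd.DataFrame(
        counts, index=features, columns=[s.sample_id for s in samples]
    )
    deg_truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "tissue", "direction", "horse", "multiplier"]
    )
    return counts_df, lengths, deg_truth


# ---------------------------------------------------------------------------
# full corpus
# ---------------------------------------------------------------------------

@dataclass
class Corpus:
    config: CorpusConfig
    design: StudyDesign
    genome: Genome
    sample_transcripts: dict[str, list[TranscriptModel]]
    counts: pd.DataFrame
    lengths: pd.Series
    gene_map: pd.Series  # transcript_id -> gene/locus id
    observations: dict[str, pd.DataFrame]
    truth: TruthTables
    db1: pd.DataFrame
    db2: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the whole corpus as plain-text files; returns the path map."""
        out = Path(outdir)
        (out / "samples").mkdir(parents=True, exist_ok=True)
        (out / "observations").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome_fasta"] = out / "genome.fa"
        self.genome.write_fasta(paths["genome_fasta"])
        paths["reference_gtf"] = out / "reference.gtf"
        write_gtf(paths["reference_gtf"], self.genome.annotation)
        paths["sample_sheet"] = out / "sample_sheet.csv"
        self.design.sample_sheet().to_csv(paths["sample_sheet"], index=False)
        for sid in sorted(self.sample_transcripts):
            write_gtf(out / "samples" / f"{sid}.gtf", self.sample_transcripts[sid])
        paths["sample_gtf_dir"] = out / "samples"
        for sid in sorted(self.observations):
            self.observations[sid].to_csv(
                out / "observations" / f"{sid}.tsv", sep="\t", index=False
            )
        paths["observations_dir"] = out / "observations"
        paths["counts_tsv"] = out / "counts.tsv"
        counts = self.counts.copy()
        counts.insert(0, "length", self.lengths)
        counts.insert(1, "gene_id", self.gene_map)
        counts.to_csv(paths["counts_tsv"], sep="\t", index_label="feature_id")
        for name in (
            "deg_truth",
            "genotype_truth",
            "artifact_sites",
            "switch_truth",
            "novelty_truth",
        ):
            getattr(self.truth, name).to_csv(
                out / "truth" / f"{name}.tsv", sep="\t", index=False
            )
        paths["db1_vcf"] = out / "db1.vcf"
        paths["db2_vcf"] = out / "db2.vcf"
        write_vcf(paths["db1_vcf"], self.db1, self.genome.contig_lengths())
        write_vcf(paths["db2_vcf"], self.db2, self.genome.contig_lengths())
        return paths


def _place_novel_loci(
    genome: Genome, n_loci: int, rng: np.random.Generator
) -> list[TranscriptModel]:
    """Single-isoform novel loci in intergenic gaps, clear of gene footprints."""
    occupied: dict[str, list[Interval]] = {c: [] for c in genome.contigs}
    for t in genome.annotation:
        occupied[t.contig].append((t.start, t.end))
    gaps: list[tuple[str, int, int]] = []
    for contig in sorted(genome.contigs):
        merged = merge_intervals(occupied[contig])
        edges = [500] + [e for _, e in merged]
        ends = [s for s, _ in merged] + [len(genome.contigs[contig]) - 500]
        for lo, hi in zip(edges, ends):
            if hi - lo >= 3000:
                gaps.append((contig, lo + 300, hi - 300))
    loci: list[TranscriptModel] = []
    gap_idx = 0
    for j in range(n_loci):
        if gap_idx >= len(gaps):
            break
        contig, lo, hi = gaps[gap_idx]
        n_exons = int(rng.integers(1, 4))
        exon_lens = rng.integers(150, 401, n_exons)
        intron_lens = rng.integers(100, 301, max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        if lo + span > hi:
            gap_idx += 1
            continue
        exons = []
        pos = lo
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        locus = f"NOV{j:03d}"
        loci.append(
            TranscriptModel(
                transcript_id=f"{locus}.1",
                gene_id=locus,
                contig=contig,
                strand=strand,
                exons=tuple(exons),
            )
        )
        gaps[gap_idx] = (contig, lo + span + 500, hi)
    return loci


OBS_COLUMNS = ["contig", "pos", "ref", "A", "C", "G", "T", "indel_alt", "indel_count"]


def _allele_probs(f: float, err: float, ref: str, alt: str) -> np.ndarray:
    """Per-base read probabilities at a biallelic site with alt fraction f."""
    p = np.full(4, err / 3.0)
    bases = "ACGT"
    p[bases.index(ref)] = (1.0 - f) * (1.0 - err) + f * err / 3.0
    p[bases.index(alt)] = f * (1.0 - err) + (1.0 - f) * err / 3.0
    return p / p.sum()


def generate_samples(
    design: StudyDesign, config: CorpusConfig, genome: Genome
) -> Corpus:
    """Build the full 24-sample corpus around a generated genome.

    See the module docstring for what is planted; every planted signal is
    recorded in the returned :class:`TruthTables`.
    """
    if config.effect <= 0:
        raise ValueError("effect multiplier must be > 0")
    rng_s = _rng(config.seed, _STREAM_SAMPLES)
    rng_c = _rng(config.seed, _STREAM_COUNTS)
    rng_v = _rng(config.seed, _STREAM_SITES)
    samples = design.samples()
    sample_ids = [s.sample_id for s in samples]

    # --- transcript models per sample -------------------------------------
    novel = _place_novel_loci(genome, config.n_novel_loci, rng_s)
    carriers: dict[str, list[str]] = {}
    for t in novel:
        k = int(rng_s.integers(3, len(samples) + 1))
        picked = sorted(rng_s.choice(sample_ids, size=k, replace=False))
        carriers[t.transcript_id] = list(picked)
    sample_transcripts: dict[str, list[TranscriptModel]] = {}
    for s in samples:
        models = [
            dataclasses.replace(t, sample_id=s.sample_id, cds=())
            for t in genome.annotation
        ]
        models += [
            dataclasses.replace(t, sample_id=s.sample_id)
            for t in novel
            if s.sample_id in carriers[t.transcript_id]
        ]
        sample_transcripts[s.sample_id] = models
    novelty_truth = pd.DataFrame(
        [{"transcript_id": t.transcript_id, "status": "annotated"}
         for t in genome.annotation]
        + [{"transcript_id": t.transcript_id, "status": "novel"} for t in novel],
        columns=["transcript_id", "status"],
    )

    # --- counts (transcript level) -----------------------------------------
    all_transcripts = list(genome.annotation) + novel
    tids = [t.transcript_id for t in all_transcripts]
    gene_map = pd.Series(
        {t.transcript_id: t.gene_id for t in all_transcripts}, name="gene_id"
    ).loc[tids]
    lengths = pd.Series(
        {t.transcript_id: t.spliced_length for t in all_transcripts}, name="length"
    ).loc[tids]

    by_gene: dict[str, list[str]] = {}
    for t in all_transcripts:
        by_gene.setdefault(t.gene_id, []).append(t.transcript_id)

    multi_iso = sorted(g for g, ts in by_gene.items() if len(ts) >= 2 and not g.startswith("NOV"))
    switch_genes = sorted(
        rng_c.choice(multi_iso, size=min(config.n_switch_genes, len(multi_iso)), replace=False)
    )
    switch_tissue = {g: TISSUES[int(rng_c.integers(0, 2))] for g in switch_genes}
    switch_truth = pd.DataFrame(
        [
            {
                "gene_id": g,
                "isoform_a": by_gene[g][0],
                "isoform_b": by_gene[g][1],
                "tissue": switch_tissue[g],
            }
            for g in switch_genes
        ],
        columns=["gene_id", "isoform_a", "isoform_b", "tissue"],
    )

    deg_candidates = sorted(
        g for g in by_gene if g not in set(switch_genes) and not g.startswith("NOV")
    )
    n_deg_total = sum(u + d for u, d in config.deg_per_tissue.values())
    if n_deg_total > len(deg_candidates):
        raise ValueError("more planted DEGs than eligible genes")
    chosen = list(rng_c.choice(deg_candidates, size=n_deg_total, replace=False))
    deg_assign: dict[str, tuple[str, str]] = {}
    cursor = 0
    truth_rows = []
    for tissue in sorted(config.deg_per_tissue):
        n_up, n_down = config.deg_per_tissue[tissue]
        for direction, n in (("up", n_up), ("down", n_down)):
            for g in chosen[cursor : cursor + n]:
                deg_assign[g] = (tissue, direction)
                mult = config.effect if direction == "up" else 1.0 / config.effect
                for h in design.horses:
                    truth_rows.append(
                        {"feature_id": g, "tissue": tissue, "direction": direction,
                         "horse": h, "multiplier": mult}
                    )
            cursor += n
    deg_truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "tissue", "direction", "horse", "multiplier"]
    )

    # per-gene expression rate (fragments per kb), with skewed major/minor
    # isoform usage: successive isoforms drop by a 2-5x factor so dominance
    # order within a gene is stable under the multiplicative noise
    rate: dict[str, float] = {}
    for g in sorted(by_gene):
        r = float(np.exp(rng_c.normal(config.baseline_log_mean, config.baseline_log_sd)))
        for k, t in enumerate(by_gene[g]):
            if k > 0:
                r /= float(rng_c.uniform(*config.isoform_skew))
            rate[t] = r
    # switch genes get a strong shared rate so dominance is unambiguous;
    # count means scale with transcript length so the planted ratio holds
    # on the FPKM scale, where the switch detector operates
    for g in switch_genes:
        base = float(np.exp(rng_c.normal(np.log(2000.0), 0.3)))
        rate[by_gene[g][0]] = base
        rate[by_gene[g][1]] = base / config.switch_ratio
    baseline = pd.Series({t: rate[t] * lengths[t] / 1000.0 for t in tids}).loc[tids]

    mean = np.tile(baseline.to_numpy()[:, None], (1, len(samples)))
    tid_index = {t: i for i, t in enumerate(tids)}
    for j, s in enumerate(samples):
        for g, (tissue, direction) in deg_assign.items():
            if s.tissue == tissue and s.timepoint == "after":
                mult = config.effect if direction == "up" else 1.0 / config.effect
                for t in by_gene[g]:
                    mean[tid_index[t], j] *= mult
        for g in switch_genes:
            if s.tissue == switch_tissue[g] and s.timepoint == "after":
                a, b = by_gene[g][0], by_gene[g][1]
                # reverse dominance: a drops, b rises
                mean[tid_index[a], j] /= config.switch_ratio
                mean[tid_index[b], j] *= config.switch_ratio
    # novel transcripts express only in their carrier samples
    for t in novel:
        for j, sid in enumerate(sample_ids):
            if sid not in carriers[t.transcript_id]:
                mean[tid_index[t.transcript_id], j] = 0.0
    counts = mean * _lognormal_noise(rng_c, config.noise_cv, mean.shape)
    counts_df = pd.DataFrame(counts, index=tids, columns=sample_ids)

    # --- variant sites ------------------------------------------------------
    geno_truth, artifact_df, observations = _generate_sites(
        design, config, genome, novel, carriers, rng_v
    )

    truth = TruthTables(
        deg_truth=deg_truth,
        genotype_truth=geno_truth,
        artifact_sites=artifact_df,
        switch_truth=switch_truth,
        novelty_truth=novelty_truth,
    )

    db1, db2 = generate_snp_databases(
        geno_truth,
        overlap_fractions=config.db_overlap,
        n_extra=config.db_extra,
        seed=config.seed,
        genome=genome,
    )

    return Corpus(
        config=config,
        design=design,
        genome=genome,
        sample_transcripts=sample_transcripts,
        counts=counts_df,
        lengths=lengths,
        gene_map=gene_map,
        observations=observations,
        truth=truth,
        db1=db1,
        db2=db2,
    )


def _generate_sites(
    design: StudyDesign,
    config: CorpusConfig,
    genome: Genome,
    novel: list[TranscriptModel],
    carriers: Mapping[str, list[str]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    samples = design.samples()
    margin = config.junction_window + config.interior_margin

    # interior exonic positions, clear of every exon boundary by > margin
    interior: list[tuple[str, int]] = []
    merged_exons: dict[str, tuple[Interval, ...]] = {}
    for contig in sorted(genome.contigs):
        ivs = [e for t in genome.annotation if t.contig == contig for e in t.exons]
        merged_exons[contig] = merge_intervals(ivs)
        for s, e in merged_exons[contig]:
            interior.extend((contig, p) for p in range(s + margin, e - margin))
    need = config.n_truth_sites + config.n_background_sites
    if need > len(interior):
        raise ValueError("not enough interior exonic positions for requested sites")
    picked = rng.choice(len(interior), size=need, replace=False)
    truth_pos = sorted(interior[i] for i in picked[: config.n_truth_sites])
    background_pos = sorted(interior[i] for i in picked[config.n_truth_sites :])

    bases = "ACGT"
    geno_rows = []
    site_defs = []  # (contig, pos0, ref, alt, kind, per-horse fraction)
    for contig, pos0 in truth_pos:
        ref = genome.contigs[contig][pos0]
        is_indel = rng.random() < config.indel_fraction
        if is_indel:
            if rng.random() < 0.5:  # insertion after pos
                ins = "".join(bases[i] for i in rng.integers(0, 4, int(rng.integers(1, 4))))
                vref, valt = ref, ref + ins
            else:  # deletion of the next 1-3 bases
                k = int(rng.integers(1, 4))
                vref, valt = genome.contigs[contig][pos0 : pos0 + 1 + k], ref
        else:
            alts = [b for b in bases if b != ref]
            vref, valt = ref, alts[int(rng.integers(0, 3))]
        genotypes = {}
        for h in design.horses:
            g = ("rr", "ra", "aa")[int(rng.choice(3, p=[0.45, 0.40, 0.15]))]
            genotypes[h] = g
        if all(g == "rr" for g in genotypes.values()):
            genotypes[design.horses[int(rng.integers(0, len(design.horses)))]] = "ra"
        for h in design.horses:
            geno_rows.append(
                {"horse": h, "contig": contig, "pos": pos0 + 1, "ref": vref,
                 "alt": valt, "genotype": genotypes[h]}
            )
        site_defs.append((contig, pos0, vref, valt, "indel" if is_indel else "snp", genotypes))
    geno_truth = pd.DataFrame(
        geno_rows, columns=["horse", "contig", "pos", "ref", "alt", "genotype"]
    )

    # junction-adjacent artifact sites: within the window of a transcript's
    # exon boundary, spurious alternate allele at 20-40% fraction, present
    # only in samples carrying that transcript
    all_models = list(genome.annotation) + list(novel)
    boundary_slots = []  # (contig, pos0, transcript_id)
    taken = {(c, p) for c, p in truth_pos} | {(c, p) for c, p in background_pos}
    for t in all_models:
        for s, e in t.exons:
            boundary_slots.append((t.contig, s, t.transcript_id, +1))
            boundary_slots.append((t.contig, e - 1, t.transcript_id, -1))
    rng.shuffle(boundary_slots)
    artifact_rows = []
    art_defs = []
    used: set[tuple[str, int]] = set()
    for contig, edge, tid, inward in boundary_slots:
        if len(art_defs) >= config.n_artifact_sites:
            break
        pos0 = edge + inward * int(rng.integers(0, config.junction_window))
        if (contig, pos0) in taken or (contig, pos0) in used:
            continue
        used.add((contig, pos0))
        ref = genome.contigs[contig][pos0]
        alt = [b for b in bases if b != ref][int(rng.integers(0, 3))]
        frac = float(rng.uniform(0.2, 0.4))
        if tid in carriers:
            carrier_samples = list(carriers[tid])
        else:
            carrier_samples = [s.sample_id for s in samples]
        artifact_rows.append(
            {"contig": contig, "pos": pos0 + 1, "ref": ref, "alt": alt,
             "carrier_samples": ",".join(sorted(carrier_samples))}
        )
        art_defs.append((contig, pos0, ref, alt, frac, set(carrier_samples)))
    artifact_df = pd.DataFrame(
        artifact_rows, columns=["contig", "pos", "ref", "alt", "carrier_samples"]
    )

    # per-sample pileup-style observations
    frac_of = {"rr": 0.0, "ra": 0.5, "aa": 1.0}
    observations: dict[str, pd.DataFrame] = {}
    for s in samples:
        rows = []
        for contig, pos0, vref, valt, kind, genotypes in site_defs:
            f = frac_of[genotypes[s.horse]]
            depth = int(rng.poisson(config.depth_mean))
            if kind == "snp":
                counts = rng.multinomial(
                    depth, _allele_probs(f, config.base_error, vref, valt)
                )
                rows.append((contig, pos0 + 1, vref, *counts.tolist(), ".", 0))
            else:
                n_indel = int(rng.binomial(depth, f * (1.0 - config.base_error)))
                counts = rng.multinomial(
                    depth - n_indel,
                    _allele_probs(0.0, config.base_error, vref[0], "ACGT"[("ACGT".index(vref[0]) + 1) % 4]),
                )
                rows.append((contig, pos0 + 1, vref, *counts.tolist(), valt, n_indel))
        for contig, pos0 in background_pos:
            ref = genome.contigs[contig][pos0]
            depth = int(rng.poisson(config.depth_mean))
            counts = rng.multinomial(
                depth,
                _allele_probs(0.0, config.base_error, ref, "ACGT"[("ACGT".index(ref) + 1) % 4]),
            )
            rows.append((contig, pos0 + 1, ref, *counts.tolist(), ".", 0))
        for contig, pos0, ref, alt, frac, carrier_samples in art_defs:
            if s.sample_id not in carrier_samples:
                continue
            depth = int(rng.poisson(config.depth_mean))
            counts = rng.multinomial(
                depth, _allele_probs(frac, config.base_error, ref, alt)
            )
            rows.append((contig, pos0 + 1, ref, *counts.tolist(), ".", 0))
        df = pd.DataFrame(rows, columns=OBS_COLUMNS)
        df = df.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
        observations[s.sample_id] = df
    return geno_truth, artifact_df, observations


# ---------------------------------------------------------------------------
# SNP databases
# ---------------------------------------------------------------------------

def generate_snp_databases(
    genotype_truth: pd.DataFrame,
    overlap_fractions: tuple[float, float] = (0.5, 0.3),
    n_extra: int = 150,
    seed: int = 0,
    genome: Genome | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two known-SNP tables overlapping the truth set by given fractions.

    Each truth variant enters each database independently with that
    database's overlap fraction; ``n_extra`` decoy sites absent from the
    truth are added per database. Returns two variant tables with columns
    contig, pos (1-based), ref, alt.
    """
    for f in overlap_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("overlap fractions must be in [0, 1]")
    rng = _rng(seed, _STREAM_DATABASES)
    truth = (
        genotype_truth[["contig", "pos", "ref", "alt"]]
        .drop_duplicates()
        .sort_values(["contig", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    taken = set(zip(truth.contig, truth.pos))
    dbs = []
    for frac in overlap_fractions:
        keep = rng.random(len(truth)) < frac
        rows = truth[keep].copy()
        extras = []
        if genome is not None:
            contigs = sorted(genome.contigs)
            while len(extras) < n_extra:
                c = contigs[int(rng.integers(0, len(contigs)))]
                p0 = int(rng.integers(100, len(genome.contigs[c]) - 100))
                if (c, p0 + 1) in taken:
                    continue
                taken_key = (c, p0 + 1)
                ref = genome.contigs[c][p0]
                alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                extras.append({"contig": c, "pos": p0 + 1, "ref": ref, "alt": alt})
        db = pd.concat([rows, pd.DataFrame(extras, columns=rows.columns)], ignore_index=True)
        db = db.drop_duplicates(["contig", "pos", "ref", "alt"])
        db = db.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
        dbs.append(db)
    return dbs[0], dbs[1]


def write_vcf(
    path: str | Path,
    variants: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    info_columns: Sequence[str] = (),
    info_meta: Mapping[str, str] | None = None,
) -> None:
    """Write a variant table (contig, pos, ref, alt [+ info columns]) as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=equitrx\n")
        for c in sorted(contig_lengths):
            fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        for k in info_columns:
            desc = (info_meta or {}).get(k, k)
            fh.write(
                f'##INFO=<ID={k},Number=1,Type=String,Description="{desc}">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = variants.sort_values(["contig", "pos", "ref", "alt"], kind="mergesort")
        for row in ordered.itertuples(index=False):
            if info_columns:
                info = ";".join(f"{k}={getattr(row, k)}" for k in info_columns)
            else:
                info = "."
            fh.write(
                f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n"
            )


def generate_corpus(config: CorpusConfig | None = None) -> Corpus:
    """Generate the default 24-sample corpus from a single config/seed."""
    config = config or CorpusConfig()
    design = StudyDesign(seed=config.seed)
    genome = generate_genome(
        n_contigs=config.n_contigs,
        contig_length=config.contig_length,
        n_genes=config.n_genes,
        seed=config.seed,
    )
    return generate_samples(design, config, genome)
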