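# Methods

`equitrx` re-implements, as a tested library, the post-alignment analysis
stack of a paired-design bulk RNA-Seq study: six animals, two tissues
(blood, muscle), sampled before and after exercise — 24 samples in all.
The stages run in the order a practitioner would: transcript-model
clustering, variant discovery, expression quantification and differential
calling, and isoform dominance-switch detection. Because the original raw
sequence (≈1.3 billion reads against a full horse reference) is far beyond
desk scale, the package ships a synthetic-data generator that emulates the
*structure* of the study and records every planted signal, so each stage
is validated by parameter recovery rather than by re-deriving the original
dataset.

## Unigene clusters

Transcript models assembled per sample are pooled across all 24 samples
and partitioned into *unigene clusters* (UCs): the connected components of
the graph joining same-contig, same-strand transcripts that share at least
one exonic base. Two choices were genuinely open and are fixed as package
policy:

* **Overlap is counted on exonic bases, not genomic spans.** Span overlap
  would fuse a gene with anything nested in its introns, including
  antisense neighbours; exonic overlap keeps them apart. Strands never
  merge.
* **Coordinates are 0-based half-open internally**; GTF I/O converts to
  and from the format's 1-based inclusive convention at the boundary.
  This keeps interval arithmetic unambiguous.

Clustering is implemented as a single sorted sweep per (contig, strand)
with a union–find over transcripts, O(E log E) in the number of exons, and
is order-independent: UC identifiers are assigned by a canonical
(contig, footprint start, strand) sort, so permuting the input yields
byte-identical output.

A UC is *annotated* when its footprint shares ≥ 1 exonic bp, same strand,
with any reference gene; otherwise *novel*. Novel clusters can be screened
by a six-frame ORF filter: a footprint is kept iff some reading frame on
either strand contains a complete ORF (ATG through stop, stop codon
included in the length) of at least `min_orf_nt` nucleotides. The
threshold is not fixed by any published value; the default of 300 nt
(100 codons) is the conventional cutoff for "plausibly coding" and is a
configuration flag. A UC counts as *expressed* in a tissue iff its FPKM
exceeds `min_fpkm` (default 0, i.e. any positive evidence) in at least one
sample of that tissue; "expressed" has no standard definition and the
threshold is exposed.

## Variant discovery

Input is pileup-style per-sample site observations (contig, 1-based
position, reference allele, per-base read counts, optional indel allele
and count). Calling applies per-site gates; the defaults are deliberate
stand-ins for unpublished pipeline settings and are all CLI-exposed:

| parameter          | default | meaning                                    |
|--------------------|---------|--------------------------------------------|
| `min_depth`        | 4       | total reads required at the site           |
| `min_alt_reads`    | 2       | reads supporting the alternate allele      |
| `min_alt_fraction` | 0.2     | alternate allele fraction                  |
| `hom_fraction`     | 0.8     | fraction at or above which a call is hom   |
| `junction_window`  | 10 bp   | exclusion zone around exon starts/ends     |

The **exon–intron boundary misalignment filter** removes any candidate
within `junction_window` bp of an exon start or end (boundaries taken from
the reference annotation *and* all sample transcript models). Spliced
reads that overhang a junction into the intron produce clusters of false
alternate alleles exactly there; the filter is purely positional, so it
commutes with the count gates and is monotone in the window.

Per-sample calls are merged into a non-redundant set keyed by
(contig, pos, ref, alt); multi-allelic sites decompose into one record per
alternate allele. A variant is *individual-specific* iff every carrying
sample belongs to one horse — judged on called presence only, ignoring
coverage dropout, which is what a call-set comparison can honestly do and
is flagged as a caveat. Database comparison against two known-SNP VCFs
requires identity of contig, position, reference **and** alternate allele;
positional matching alone inflates overlap. Coding effects are annotated
by strand-aware codon substitution inside annotated CDS (synonymous iff
the amino acid is unchanged in every overlapped CDS); indels in CDS are
non-synonymous; CDS whose length is not a multiple of three are warned
about and excluded (effect NA). Indels pass through the same gates and
merge but never enter codon logic, mirroring how substitutions and indels
are reported separately.

## Expression and differential calling

Expression is FPKM: `FPKM[f,s] = counts[f,s] x 1e9 / (length[f] x
total[s])`, exactly invertible given lengths and totals. Sample
correlations use Pearson on `log(x+1)` values, since raw-FPKM correlations
are dominated by a handful of extreme features.

Differential expression follows a per-horse voting rule on the paired
design. For horse *h* in tissue *t*:

    fold(f, h) = (FPKM_after(f, h) + c) / (FPKM_before(f, h) + c)

with pseudocount `c = 0.1` (how zero expression was handled is not
published; the pseudocount bounds folds and is configurable). A feature is
an up-DEG iff `fold > 2` in ≥ 4 of the 6 horses, a down-DEG iff
`fold < 1/2` in ≥ 4 horses; "more than two fold" is read strictly
(`>`, not `>=`). With 6 horses and `min_horses >= 4`, the up and down sets
are disjoint by pigeonhole. Whether folds should be computed on FPKM or
raw counts is unstated in the source material; FPKM is used, and since
both timepoints of a horse share the feature length the choice only
matters through library-size normalisation. DEG totals are reported both
raw (per tissue-direction, summed) and deduplicated across tissues,
because the study's own printed totals disagree with the arithmetic sum of
its per-tissue counts (62 + 80 + 878 + 285 = 1,305 against two different
printed totals); both numbers are emitted rather than silently picking
one.

## Isoform dominance switches

For each gene with ≥ 2 isoforms, each isoform pair (a, b), tissue and
horse: orientation "a first" holds iff `FPKM_a > r x FPKM_b` before *and*
`FPKM_b > r x FPKM_a` after, with the dominant isoform ≥ `min_fpkm`
(default 1) at both timepoints. An event is reported when ≥ `min_horses`
(default 4, matching the DEG voting spirit) horses agree on one
orientation; one event per gene is kept — most support wins, ties broken
by tissue then lexicographic isoform ids. The dominance margin `r`
defaults to 1.0 (strict dominance) since the published description of the
pattern is qualitative. Pairwise comparison is used rather than a full
ranking because the phenomenon of interest is two forms trading places.

## The synthetic study generator

The generator emulates the study's *design*, not its sequences: 24
samples (6 horses x {blood, muscle} x {before, after}), a toy genome
(default 2 x 200 kb contigs, 40 genes of 2–8 exons and 1–3 isoforms, each
gene with a valid CDS pasted strand-aware into the genome), novel
single-isoform loci placed in intergenic space, and two known-SNP
databases with controllable truth overlap plus decoy sites.

Counts are deliberately negative-binomial-free: per-gene log-normal
expression rates (median 200 fragments/kb, log-sd 1.2) with multiplicative
log-normal sample noise at CV 0.1, because this gives closed-form
expectations and an exact noiseless limit for oracle tests. Isoform usage
within a gene is skewed — successive isoforms drop by a uniform 2–5x
factor — matching the major/minor isoform structure of real transcriptomes
and making within-gene dominance well-defined rather than a coin flip
under noise. Planted DEGs multiply the after-exercise mean of one tissue
by 4 (up) or 1/4 (down) in all six horses; planted switches set a 5x
dominance ratio on the FPKM scale that reverses after exercise. Site
observations draw depth from Poisson(30) and distribute reads
multinomially with a 1% uniform base-error rate — a typical RNA-Seq pileup
regime at desk scale. Junction artifacts are planted within the 10 bp
window of a transcript's exon boundary at 20–40% allele fraction, only in
samples carrying that transcript; true variant sites are placed at least
`junction_window + 5` bp from every exon boundary, so the positional
filter separates the two classes by construction. All randomness flows
from one seed through named generator streams; the same seed yields a
byte-identical corpus.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level errors and alignment, coverage that
tracks expression, linkage between nearby variants, overdispersed
(negative-binomial) counts, batch effects, and genes overlapping on the
same strand. The recovery rates on this corpus certify the correctness of
the *rules* (gates, filters, voting, dominance logic), not the field
performance of the pipeline on real alignments.

## Problem sizes and numerical choices

The validation suite and the acceptance script use: 200 random transcripts
against a brute-force O(n²) clustering oracle; 2,000 features with 200
planted DEGs for the voting rule; a corpus with 60 genes, 1,000 planted
variant sites and 100 junction artifacts for the caller; 500 random
planted coding SNPs against a translate-whole-CDS-and-diff oracle; and the
default 4-switch corpus for dominance detection. These sizes give every
rate a denominator of hundreds to thousands while keeping a full run in
seconds.

Percentages are computed as `100 x part / total` rounded half-up to two
decimals via decimal arithmetic, matching how headline percentages are
conventionally printed. Ties in cluster and event ordering are broken by
canonical sorts so all outputs are reproducible byte-for-byte. Degenerate
inputs fail loudly: infeasible gene packing, effect multipliers ≤ 0,
conflicting reference alleles at one site, unknown reference bases
(skipped per record with a log entry), empty annotation (warned, all
novel), missing timepoints (error by default, per-horse exclusion when
requested).

## Known limitations

* The original study's exact filter parameters, ORF cutoff, "expressed"
  threshold and switch-consistency rule live in an unpublished supplement;
  every corresponding default here is a declared stand-in, exposed as
  configuration.
* Individual-specific status ignores coverage dropout (no reference-call
  vs no-data distinction).
* Effect annotation considers single-nucleotide substitutions codon by
  codon; multi-nucleotide haplotypes within one codon are not composed.
* The headline dataset results of the motivating study (32,361 UCs,
  189,973 SNVs, the DEG lists) require the original reads and reference
  and are not reproducible here; the package instead reproduces the
  arithmetic relations among the printed counts and validates every rule
  by parameter recovery.
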