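# Methods

## Scope and model

isoquantbench treats isoform quantification as a measurement problem with a
known answer: a synthetic truth table fixes every transcript's fragment
count per sample, a simulator turns those counts into paired-end reads whose
source transcript is logged, and quantifiers are scored against the truth
with the pseudocount-adjusted metric |logFC| = |log₂((y+1)/(x+1))|. The
pseudocount keeps the metric finite at zero counts and makes |logFC| = 0 the
exact-recovery point; log base 2 is used everywhere.

## Synthetic truth

Per-gene expression means are log-normal (defaults: meanlog 5.0, sdlog 1.0,
so a mean of ≈245 fragments per gene, giving ≈4000 fragments per sample on
the 20-gene toy fixture — chosen so a desk-scale dataset still produces
hundreds of ambiguous fragments per sample). Replicate counts are negative
binomial with var = m + φm² (φ = 0.1); φ = 0 degrades to Poisson. A
configurable fraction of genes (default 0.2) is silent in both conditions,
which supplies the null isoforms the FDR lower bound needs. Differential
expression: 10% of expressed genes by default, fold-change 4 in a random
direction, applied to the second condition's mean. Isoform proportions
(PSI): one Dirichlet(1) base vector per gene, shared by both conditions
except for a differentially spliced fraction (default 0.074 of multi-isoform
genes, i.e. roughly the share of genes carrying condition-dependent splicing
in a liver-vs-hippocampus-like design) whose second-condition vector is
redrawn until the largest entry-wise shift is ≥ 0.2.

Per-sample variability is added by perturbing each PSI entry by an
independent uniform(0, 0.025) magnitude with random sign, clamping to [0,1],
and renormalizing to sum exactly to 1. Renormalization was chosen over
pairwise compensation for simplicity. Note the post-renormalization
deviation of entry *i* is bounded by (ε + xᵢ·k·ε)/(1 − k·ε) for a k-isoform
gene with raw bound ε = 0.025 — for two isoforms this is within 2ε, but for
large k with same-sign draws it can exceed 2ε; the tests assert the exact
bound. Transcript counts are allocated from gene counts by a multinomial
draw with PSI probabilities, so isoform counts always sum exactly to the
gene count. Genes whose isoforms are all shorter than 200 bases receive zero
expression when an annotation is supplied (configurable), since such
transcripts are shorter than a typical sequencing fragment.

## Read simulation

Fragment lengths follow a triangular(min, mode, max) distribution — the
simplest distribution honoring the three conventional numbers 100/250/500 —
truncated at the transcript length; transcripts shorter than the minimum
yield the whole transcript with a warning. Fragment starts are uniform, or
under 3′ bias weighted by w(s) ∝ exp(λ·s/L) with λ = 2 by default; this is
an explicit emulation of empirically observed positional bias, not a fitted
curve. Each fragment comes from the unspliced pre-mRNA with probability
`intron_freq` (per-fragment Bernoulli, independent of transcript), else from
the spliced sequence. Mate 1 is the first `read_length` bases of the sense
strand, mate 2 the reverse complement of the last; both truncate to short
fragments. Sequencing errors flip each sequenced base to a uniformly chosen
different base with probability `error_rate`; N bases are reported as N and
never substituted. Quality strings are constant (no downstream statistic
uses them).

Polymorphisms are haploid and per sample: substitutions at `sub_freq` per
base and 1–3 bp insertions/deletions initiated at `indel_freq` per base,
equiprobably insertion or deletion. Because indels shift genomic
coordinates, each sample carries a per-chromosome liftover map (cumulative
indel offsets; exon boundaries falling inside a deletion clamp to the
deletion start) through which annotation exons are re-extracted from the
mutated genome.

The idealized preset sets error, substitution, indel and intron rates all to
zero with uniform coverage — the configuration under which every emitted
read is an exact substring of its source transcript, giving quantifiers
their best case. The realistic preset uses error 0.005, substitutions 0.001,
indels 0.0001, intron signal 0.05 and 3′ bias.

FASTQ read ids are opaque per-sample serials; the transcript of origin
appears only in the origin log, so a quantifier under test cannot exploit
read names.

## Quantifiers and alignment

The unit of counting is the fragment (read pair); both mates must support
the same candidate transcript, and mates' candidate sets are intersected.
The bundled `exact_match_align` is a brute-force, fixture-scale
transcriptome aligner: a transcript is a candidate when mate 1 and
revcomp(mate 2) occur with a consistent span within the configured fragment
range (strand-specific orientation assumed; an edit-distance budget via
edlib handles error-mode reads). Real datasets would use a production
aligner and enter through the SAM reader instead.

NRP is deliberately non-iterative: the second pass proportions ambiguous
fragments using the frozen first-pass unambiguous counts (no EM), falling
back to transcript lengths when all candidates have zero unambiguous
support. Ambiguity across genes is treated identically to ambiguity between
sibling isoforms. Total assigned mass equals the number of aligned
fragments. The unambiguous-only counter is the conservative baseline: it
never overshoots and strictly undercounts in the presence of ambiguity.

## Evaluation choices

- Percentiles are nearest-rank (curve monotone by construction).
- Clustering: correlation distance 1 − Pearson r on per-transcript mean
  expression (or cross-condition logFC vectors), average linkage; both are
  configurable, and the dendrogram is exported as Newick.
- The expressed-isoform filter drops genes with no expressed isoform but
  keeps zero-truth isoforms that have an expressed sibling, since those are
  exactly the ones quantifiers spuriously inflate.
- The discordant set ranks transcripts by mean |logFC| across replicates
  (default n = 2000; boundary ties break by transcript id).
- KS enrichment compares the discordant foreground to the whole
  transcriptome per property; Bonferroni factor = properties × methods in
  the run (just the property count when a single method is evaluated).
- Compression complexity is the DEFLATE (zlib level 9) compressed-to-raw
  byte ratio of the spliced sequence. Any fixed lossless compressor induces
  the same low-complexity ⇒ low-ratio ordering the analysis needs; the
  level is exposed. Hexamer entropy uses overlapping 6-mers, log base 2.
  Both are computed on spliced (mature) sequence, not pre-mRNA.
- `simple_de` is a deliberately plain DE stand-in for exercising the
  concordance machinery: exact two-sided Mann–Whitney U per transcript
  between condition replicates, Benjamini–Hochberg q-values, ranking by
  (q, then larger |logFC|, then transcript id) — the tie-break matters
  because isoform DE tools report many exactly-zero p-values. All-tied
  count vectors get p = 1 directly (the tie-corrected normal approximation
  degenerates there). External DE tables are taken at face value as
  q-values.
- The FDR lower bound uses transcripts with zero truth in every replicate of
  both conditions: #{null rejected}/#{rejected}, defined as 0 when nothing
  is rejected.

## Toy fixtures and what passing tests show

`make_toy_fixture` plants the structures the evaluation depends on: sibling
isoforms sharing a 650-base anchor exon (longer than the maximum fragment,
so ambiguous fragments are guaranteed), single-isoform genes with no shared
sequence (so exact truth recovery is achievable and testable), one intron
whose sequence is a T-homopolymer sentinel (so intron-signal reads are
recognizable), and spliced lengths from 200 to 5000 bases. One gene per
chromosome; all output is deterministic in the seed, byte for byte.

The generator emulates the statistical structure of a two-tissue replicate
design — count dispersion, shared PSI with small per-sample jitter, a DE/DS
subset, null isoforms — but not everything about real data: no GC or
priming bias, no sequence-dependent coverage, no unannotated splicing, no
homology between genes beyond the planted shared exons, and empirical PSI
distributions are replaced by Dirichlet draws. Passing tests therefore
demonstrate correctness of the machinery and the direction/calibration of
the documented effects at toy scale, not performance claims about any real
organism's transcriptome.

## Annotation perturbations

"Unexpressed" means zero true count in every sample of the dataset, so one
perturbed annotation serves the whole experiment. `remove_top_isoforms`
applies to every gene with at least one expressed isoform, including
single-isoform genes (whose gene then disappears); the maximum is taken over
summed counts with ties broken by smallest transcript id for determinism.

## Numerical and degenerate-input conventions

PSI columns must sum to 1 within 1e-9; NRP mass conservation is tested to
1e-6; Spearman on a constant vector returns NaN with a warning rather than
an arbitrary value; percentile curves reject empty inputs; KS enrichment
requires a foreground of at least two transcripts; clustering requires two
methods and rejects constant feature vectors. Every random draw flows
through a numpy Generator seeded from one integer plus a CRC32-hashed stage
name, so stages are independent but the whole pipeline is reproducible from
a single seed (the manifest records it).

## Problem sizes

Defaults are desk-scale by design: 20-gene fixtures, ~4000 fragments per
sample, three replicates per condition (six for DE examples), a
500-transcript synthetic property table for calibration checks, and 200
resampling seeds for the KS type-I test. All are parameters, and the same
code paths run unchanged at larger sizes.

## Known limitations

- The fixture aligner is O(pairs × transcripts) and meant for toy genomes.
- The 3′-bias curve, count distributions and PSI distributions are
  parametric stand-ins, not fits to empirical data.
- Libraries are assumed strand-specific end to end.
- No TPM/FPKM normalization, gene-level DE, or plotting; outputs are tables
  (TSV/Newick/JSON) intended for downstream tooling.
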