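# isoquantbench

Benchmarking full-length transcript-isoform quantification from short-read
RNA-Seq, with simulated data whose ground truth is known read-by-read.

Isoform quantification is hard because reads (~100 bases) are much shorter
than transcripts (often >1000 bases), so a large share of reads is ambiguous
between sibling isoforms of a gene. This package is for people evaluating
quantifiers (kallisto, Salmon, RSEM, Cufflinks, HTSeq, featureCounts, ...):
it generates two-condition, multi-replicate expression truth, simulates
strand-specific paired-end reads with a per-read origin log, provides two
analytically transparent baseline quantifiers, and computes the evaluation
statistics that make methods comparable.

## What it computes

**Accuracy metric.** For a transcript with true count *x* and estimated
count *y*,

&nbsp;&nbsp;&nbsp;&nbsp;|logFC| = |log₂((y + 1) / (x + 1))|

(pseudocount 1 in numerator and denominator). A value of 0 is a perfect
estimate; ±10 is roughly a 1000-fold error. Summaries: nearest-rank
percentile curves of |logFC| over expressed isoforms, per-sample Spearman
correlations, per-bin means by number of expressed isoforms, and
hierarchical clustering of methods with correlation distance
(1 − Pearson *r*, average linkage).

**Baseline quantifiers.** Naive read proportioning (NRP): pass 1 counts
fragments mapping unambiguously to each transcript (*c₁…cₙ*); pass 2 gives a
fragment ambiguous among {T₁…Tₙ} to each Tᵢ in proportion *cᵢ* / Σ*c*, or
*lᵢ* / Σ*l* (transcript lengths) when all *cᵢ* = 0. The unambiguous-only
counter discards ambiguous fragments entirely, so it undercounts wherever
isoforms share sequence. External quantifiers' tables are ingested, never
re-implemented.

**Simulator.** Each transcript with true count *c* yields exactly *c*
fragments: triangular fragment lengths (default 100/250/500), uniform or
3′-biased starts, 5% pre-mRNA (intron signal) fragments, per-sample haploid
SNPs/indels, and per-base sequencing errors — or the idealized preset with
none of these. Truth: log-normal per-gene means, negative-binomial replicate
noise, per-gene PSI vectors perturbed per sample by ±uniform(0, 0.025) and
renormalized to sum to 1, with configurable fractions of differentially
expressed and differentially spliced genes.

**Enrichment and DE concordance.** Two-sample Kolmogorov–Smirnov tests
(Bonferroni-corrected over properties × methods) comparing the most
discordant transcripts against the transcriptome for five properties:
length, exon count, sibling-isoform count, hexamer entropy, and compression
complexity (DEFLATE compressed/raw ratio). Differential expression
concordance: Jaccard index of top-*n* DE lists (truth vs estimates),
q-value count curves, and a lower bound on the realized FDR from
transcripts with zero true expression in every replicate of both conditions
(any DE call on them is a certain false positive).

## Worked example

```bash
python examples/02_nrp_vs_unambiguous_quantification.py
```

```
4057 fragments aligned (2230 ambiguous), 0 unaligned
NRP               total mass   4057.0 (truth 4057), mean |logFC| 0.782
unambiguous-only  total mass   1827.0 (truth 4057), mean |logFC| 1.690
```

On a 20-gene toy genome whose sibling isoforms share a 650-base anchor exon,
over half the idealized fragments are ambiguous. NRP conserves the aligned
mass exactly and lands at a mean |logFC| of 0.78; the unambiguous-only
counter throws those 2230 fragments away, recovering only 1827 of 4057, and
its mean |logFC| more than doubles — the undercounting failure mode of
naive counting on multi-isoform genes. The other scripts in `examples/`
cover simulation with origin logs, property enrichment, DE concordance, and
annotation-perturbation experiments; `isoquantbench run` executes the whole
pipeline from the shell with a manifest for byte-reproducible reruns.

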