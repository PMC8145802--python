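"""Programmatic toy genomes with planted multi-isoform structure.

The generated fixtures let the whole pipeline run at desk scale with no
downloads: random chromosome sequences carrying genes with 1-4 isoforms,
sibling isoforms that share a long anchor exon (so ambiguous fragments are
guaranteed), one gene whose intron is a distinctive homopolymer sentinel
(so intron-signal reads are recognizable), and spliced lengths spanning
roughly 200-5000 bases.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import stage_rng
from .annotation import AnnotationSet, GenomeSequence, TranscriptModel, write_gtf
from .truth import TruthConfig

DEFAULT_ISOFORM_COUNTS = (1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 4, 4, 2, 2, 3, 1, 1, 4, 2)
_SINGLE_EXON_LENGTHS = (200, 1200, 5000, 800, 2500, 400)


@dataclass
class ToyFixture:
    genome: GenomeSequence
    annotation: AnnotationSet
    truth_config: TruthConfig
    intron_sentinel_gene: str | None = None
    seed: int = 0

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": self.genome.to_fasta(out_dir / "genome.fa"),
            "gtf": write_gtf(self.annotation, out_dir / "annotation.gtf"),
        }
        return paths


def _random_seq(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(length)))


def make_toy_fixture(
    isoform_counts: Sequence[int] = DEFAULT_ISOFORM_COUNTS,
    seed: int = 0,
    anchor_exon_length: int = 650,
    intron_sentinel: bool = True,
    flank: int = 50,
) -> ToyFixture:
    """Build a deterministic toy genome + annotation.

    One gene per chromosome. Multi-isoform genes have k + 1 exons; isoform 1
    uses them all and isoform j (j >= 2) skips exon j, so every sibling pair
    shares the first ("anchor") exon, whose length exceeds the default
    maximum fragment size — fragments drawn inside it cannot be assigned
    unambiguously. Single-isoform genes are single-exon with lengths cycling
    through 200..5000 bases. The first multi-exon gene's first intron is a
    T-homopolymer sentinel when ``intron_sentinel`` is set.

    Raises ValueError for an infeasible request (any isoform count < 1).
    """
    counts = list(isoform_counts)
    if not counts or any(int(k) < 1 for k in counts):
        raise ValueError("isoform_counts must be a non-empty list of integers >= 1")

    rng = stage_rng(seed, "toy-fixture")
    sequences: dict[str, str] = {}
    models: list[TranscriptModel] = []
    sentinel_gene: str | None = None
    single_exon_cycle = 0

    for gi, k in enumerate(counts, start=1):
        k = int(k)
        gene_id = f"g{gi:02d}"
        chrom = f"chr{gi:02d}"
        if k == 1:
            exon_len = _SINGLE_EXON_LENGTHS[single_exon_cycle % len(_SINGLE_EXON_LENGTHS)]
            single_exon_cycle += 1
            n_exons = 1
            exon_lengths = [exon_len]
        else:
            n_exons = k + 1
            exon_lengths = [anchor_exon_length] + [
                int(rng.integers(150, 600)) for _ in range(n_exons - 1)
            ]
        intron_lengths = [int(rng.integers(60, 300)) for _ in range(n_exons - 1)]

        pieces = [_random_seq(rng, flank)]
        exon_coords: list[tuple[int, int]] = []
        cursor = flank
        for e in range(n_exons):
            exon_seq = _random_seq(rng, exon_lengths[e])
            pieces.append(exon_seq)
            exon_coords.append((cursor, cursor + exon_lengths[e]))
            cursor += exon_lengths[e]
            if e < n_exons - 1:
                if (
                    intron_sentinel
                    and sentinel_gene is None
                    and e == 0
                    and n_exons > 1
                ):
                    intron_seq = "T" * intron_lengths[e]
                    sentinel_gene = gene_id
                else:
                    intron_seq = _random_seq(rng, intron_lengths[e])
                pieces.append(intron_seq)
                cursor += intron_lengths[e]
        pieces.append(_random_seq(rng, flank))
        sequences[chrom] = "".join(pieces)

        for j in range(1, k + 1):
            if k == 1 or j == 1:
                exons = tuple(exon_coords)
            else:
                exons = tuple(
                    coord for e, coord in enumerate(exon_coords) if e != j - 1
                )
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t{j}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand="+",
                    exons=exons,
                )
            )

    annotation = AnnotationSet.from_transcripts(models)
    truth_config = TruthConfig(n_genes=len(counts), seed=seed)
    return ToyFixture(
        genome=GenomeSequence(sequences),
        annotation=annotation,
        truth_config=truth_config,
        intron_sentinel_gene=sentinel_gene,
        seed=seed,
    )
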