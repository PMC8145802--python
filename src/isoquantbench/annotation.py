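"""Genome sequences, transcript models and annotation perturbations.

Internal coordinates are 0-based half-open throughout; the GTF reader/writer
converts to and from the 1-based inclusive convention at the boundary.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, GtfParseError

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One spliced isoform: an ordered set of disjoint exons on a chromosome.

    Exons are (start, end) genomic intervals, 0-based half-open, sorted
    ascending by start and pairwise disjoint.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs at least one exon")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"{self.transcript_id}: empty or inverted exon ({start}, {end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({start}, {end})"
                )
            prev_end = end
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint: first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class GenomeSequence:
    """Plain chromosome sequences over the alphabet {A, C, G, T, N}."""

    sequences: dict[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path) -> Path:
        """Write all chromosomes, wrapped at 60 columns."""
        path = Path(path)
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")
        return path


@dataclass
class AnnotationSet:
    """All transcript models plus the gene → isoform grouping."""

    transcripts: dict[str, TranscriptModel]
    genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            self.genes = self._group_genes(self.transcripts)
        for gene_id, tx_ids in self.genes.items():
            if len(set(tx_ids)) != len(tx_ids):
                raise ValueError(f"gene {gene_id} lists duplicate transcripts")
            for tx in tx_ids:
                if self.transcripts[tx].gene_id != gene_id:
                    raise ValueError(f"transcript {tx} assigned to two genes")

    @staticmethod
    def _group_genes(transcripts: Mapping[str, TranscriptModel]) -> dict[str, list[str]]:
        genes: dict[str, list[str]] = {}
        for tx_id in sorted(transcripts):
            genes.setdefault(transcripts[tx_id].gene_id, []).append(tx_id)
        return genes

    @classmethod
    def from_transcripts(cls, models: Iterable[TranscriptModel]) -> "AnnotationSet":
        return cls({m.transcript_id: m for m in models})

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def subset(self, keep_ids: Iterable[str]) -> "AnnotationSet":
        keep = set(keep_ids)
        missing = keep - set(self.transcripts)
        if missing:
            raise KeyError(f"unknown transcripts: {sorted(missing)[:5]}")
        return AnnotationSet({t: m for t, m in self.transcripts.items() if t in keep})

    def siblings(self, transcript_id: str) -> list[str]:
        model = self.transcripts[transcript_id]
        return [t for t in self.genes[model.gene_id] if t != transcript_id]


_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def read_gtf(path) -> AnnotationSet:
    """Parse exon features from an Ensembl-dialect GTF into an AnnotationSet.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention. Non-exon features and comment lines are ignored.

    Raises
    ------
    GtfParseError
        For a malformed line (naming its line number) or an exon record
        lacking gene_id / transcript_id attributes.
    """
    collected: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, found {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            attributes = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attributes:
                raise GtfParseError(f"line {lineno}: exon record without transcript_id")
            if "gene_id" not in attributes:
                raise GtfParseError(f"line {lineno}: exon record without gene_id")
            tx_id = attributes["transcript_id"]
            entry = collected.setdefault(
                tx_id,
                {"gene_id": attributes["gene_id"], "chrom": chrom, "strand": strand,
                 "exons": []},
            )
            if (entry["gene_id"], entry["chrom"], entry["strand"]) != (
                attributes["gene_id"], chrom, strand,
            ):
                raise GtfParseError(
                    f"line {lineno}: transcript {tx_id} has inconsistent "
                    "gene/chromosome/strand across exon lines"
                )
            entry["exons"].append((start1 - 1, end1))
    models = []
    for tx_id, entry in collected.items():
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=entry["gene_id"],
                    chrom=entry["chrom"],
                    strand=entry["strand"],
                    exons=tuple(sorted(entry["exons"])),
                )
            )
        except ValueError as exc:
            raise GtfParseError(str(exc)) from None
    return AnnotationSet.from_transcripts(models)


def write_gtf(annotation: AnnotationSet, path) -> Path:
    """Write exon features, converting back to 1-based inclusive coordinates."""
    path = Path(path)
    with open(path, "w") as handle:
        for gene_id in sorted(annotation.genes):
            for tx_id in annotation.genes[gene_id]:
                model = annotation.transcripts[tx_id]
                for start, end in model.exons:
                    handle.write(
                        "\t".join(
                            [
                                model.chrom,
                                "isoquantbench",
                                "exon",
                                str(start + 1),
                                str(end),
                                ".",
                                model.strand,
                                ".",
                                f'gene_id "{gene_id}"; transcript_id "{tx_id}";',
                            ]
                        )
                        + "\n"
                    )
    return path


def _check_bounds(model: TranscriptModel, genome: GenomeSequence) -> str:
    if model.chrom not in genome:
        raise CoordinateError(f"{model.transcript_id}: unknown chromosome {model.chrom}")
    chrom_seq = genome[model.chrom]
    last_end = model.exons[-1][1]
    if model.exons[0][0] < 0 or last_end > len(chrom_seq):
        raise CoordinateError(
            f"{model.transcript_id}: exon outside chromosome {model.chrom} "
            f"(length {len(chrom_seq)})"
        )
    return chrom_seq


def spliced_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """Mature mRNA sequence: exon substrings concatenated in genomic order,
    reverse-complemented for minus-strand transcripts."""
    chrom_seq = _check_bounds(model, genome)
    seq = "".join(chrom_seq[s:e] for s, e in model.exons)
    return reverse_complement(seq) if model.strand == "-" else seq


def premrna_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """Unspliced pre-mRNA: the contiguous genomic span, strand-adjusted."""
    chrom_seq = _check_bounds(model, genome)
    start, end = model.span
    seq = chrom_seq[start:end]
    return reverse_complement(seq) if model.strand == "-" else seq


def _total_counts(truth) -> Mapping[str, float]:
    """Accept a TruthTable or any transcript → total-count mapping."""
    if hasattr(truth, "total_counts"):
        return truth.total_counts().to_dict()
    return dict(truth)


def remove_unexpressed_isoforms(annotation: AnnotationSet, truth) -> AnnotationSet:
    """Drop every isoform with zero true count in all samples.

    Genes left with no surviving isoform disappear entirely. Transcripts
    absent from the truth table count as unexpressed.
    """
    totals = _total_counts(truth)
    keep = [t for t in annotation.transcripts if totals.get(t, 0) > 0]
    return annotation.subset(keep)


def remove_top_isoforms(annotation: AnnotationSet, truth) -> AnnotationSet:
    """Drop the highest-expressed isoform of every expressed gene.

    Expression is the true count summed across samples; ties go to the
    lexicographically smallest transcript_id so the operation is
    deterministic. Genes with no expressed isoform are left untouched;
    single-isoform expressed genes lose their only isoform and vanish.
    """
    totals = _total_counts(truth)
    drop: set[str] = set()
    for gene_id, tx_ids in annotation.genes.items():
        expressed = [(tx, totals.get(tx, 0)) for tx in tx_ids if totals.get(tx, 0) > 0]
        if not expressed:
            continue
        top = min(expressed, key=lambda item: (-item[1], item[0]))[0]
        drop.add(top)
    return annotation.subset([t for t in annotation.transcripts if t not in drop])
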