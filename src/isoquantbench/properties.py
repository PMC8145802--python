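"""Structural and sequence properties of transcripts.

These are the covariates tested for enrichment among poorly quantified
transcripts: spliced length, exon count, number of sibling isoforms,
hexamer (6-mer) Shannon entropy, and lossless-compression complexity.
"""
from __future__ import annotations

import zlib
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet, GenomeSequence, spliced_sequence
from .errors import UndefinedPropertyError

PROPERTY_COLUMNS = [
    "length",
    "exon_count",
    "sibling_count",
    "hexamer_entropy",
    "compression_complexity",
]


def hexamer_entropy(sequence: str, k: int = 6) -> float:
    """Shannon entropy (bits) of the overlapping k-mer frequency distribution.

    Bounded by log2(min(4^k, len(sequence) - k + 1)), with equality iff the
    observed k-mers are uniformly distributed.
    """
    if len(sequence) < k:
        raise UndefinedPropertyError(
            f"hexamer entropy undefined for sequences shorter than {k} bases"
        )
    counts = Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))
    return float(stats.entropy(np.fromiter(counts.values(), dtype=float), base=2))


def compression_complexity(sequence: str, level: int = 9) -> float:
    """Compressed-to-raw byte ratio under DEFLATE at a fixed level.

    Low values flag repetitive, low-complexity sequence; the ratio is
    deterministic for a given input. The specific compressor is a documented
    package choice — any fixed lossless compressor preserves the ordering the
    enrichment analysis relies on.
    """
    if not sequence:
        raise UndefinedPropertyError("compression complexity undefined for empty sequence")
    raw = sequence.encode("ascii")
    return len(zlib.compress(raw, level)) / len(raw)


def build_property_table(
    annotation: AnnotationSet, genome: GenomeSequence
) -> pd.DataFrame:
    """One row per transcript with the five enrichment properties.

    Entropy and compression complexity are computed on the spliced (mature)
    transcript sequence; sibling_count is the number of other isoforms of the
    same gene.
    """
    rows = {}
    for tx_id in annotation.transcript_ids:
        model = annotation.transcripts[tx_id]
        seq = spliced_sequence(model, genome)
        rows[tx_id] = {
            "length": model.spliced_length,
            "exon_count": model.exon_count,
            "sibling_count": len(annotation.genes[model.gene_id]) - 1,
            "hexamer_entropy": hexamer_entropy(seq),
            "compression_complexity": compression_complexity(seq),
        }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=PROPERTY_COLUMNS)
    table.index.name = "transcript_id"
    return table


def write_property_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_property_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript_id")
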