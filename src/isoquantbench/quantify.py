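"""Fragment alignment and the built-in quantifiers.

Two baseline quantifiers operate on transcriptome alignments: naive read
proportioning (NRP), which distributes each ambiguous fragment over its
candidate transcripts in proportion to their unambiguous counts c_i
(falling back to transcript lengths l_i when all c_i are zero), and an
unambiguous-only counter that simply discards ambiguous fragments. Outputs
of external tools (kallisto, Salmon, RSEM, Cufflinks, HTSeq, featureCounts)
are ingested as tables, never re-implemented.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, reverse_complement
from .errors import DialectError


@dataclass(frozen=True)
class FragmentAlignment:
    """One aligned fragment and the transcripts it is consistent with."""

    fragment_id: str
    candidates: frozenset
    positions: tuple = ()  # optional ((transcript_id, start, span), ...)

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("a FragmentAlignment needs at least one candidate")

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def exact_match_align(
    pairs: Iterable[tuple[str, str, str]],
    transcript_seqs: Mapping[str, str],
    frag_min: int = 100,
    frag_max: int = 500,
    max_mismatches: int = 0,
) -> tuple[list[FragmentAlignment], list[str]]:
    """Brute-force transcriptome alignment of read pairs at fixture scale.

    A transcript is a candidate when mate1 and revcomp(mate2) both occur in
    its sequence (sense orientation; libraries are strand-specific) with a
    consistent fragment span inside [frag_min, frag_max] — the lower bound
    relaxes to the transcript length for transcripts shorter than frag_min.
    With ``max_mismatches`` > 0 the occurrence search tolerates that many
    edits per mate (edlib); otherwise matching is exact.

    Returns (aligned fragments, ids of unaligned fragments).
    """
    if max_mismatches > 0:
        import edlib

        def occurrences(seq, read):
            res = edlib.align(read, seq, mode="HW", task="locations", k=max_mismatches)
            if res["editDistance"] < 0:
                return []
            return sorted({max(0, end + 1 - len(read)) for _, end in res["locations"]})
    else:
        occurrences = _occurrences

    aligned: list[FragmentAlignment] = []
    unaligned: list[str] = []
    items = sorted(transcript_seqs.items())
    for fragment_id, mate1, mate2 in pairs:
        m2 = reverse_complement(mate2)
        candidates = []
        positions = []
        for tx_id, seq in items:
            lo = min(frag_min, len(seq))
            starts1 = occurrences(seq, mate1)
            if not starts1:
                continue
            starts2 = occurrences(seq, m2)
            if not starts2:
                continue
            hit = None
            for p1 in starts1:
                for p2 in starts2:
                    span = p2 + len(m2) - p1
                    if p2 >= p1 and lo <= span <= frag_max:
                        hit = (p1, span)
                        break
                if hit:
                    break
            if hit:
                candidates.append(tx_id)
                positions.append((tx_id, hit[0], hit[1]))
        if candidates:
            aligned.append(
                FragmentAlignment(fragment_id, frozenset(candidates), tuple(positions))
            )
        else:
            unaligned.append(fragment_id)
    return aligned, unaligned


def unambiguous_counts(alignments: Iterable[FragmentAlignment]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for aln in alignments:
        if not aln.ambiguous:
            (tx,) = aln.candidates
            counts[tx] = counts.get(tx, 0) + 1
    return counts


def nrp_quantify(
    alignments: Sequence[FragmentAlignment],
    transcript_lengths: Mapping[str, int],
) -> pd.Series:
    """Naive read proportioning.

    Pass 1 counts fragments that map unambiguously to each transcript (c_i).
    Pass 2 distributes every ambiguous fragment over its candidate set
    {T_1..T_n}: transcript T_i receives c_i / (c_1 + ... + c_n), or, when all
    candidate c's are zero, l_i / (l_1 + ... + l_n) with l_i the transcript
    length. Total assigned mass equals the number of aligned fragments.
    """
    unamb = unambiguous_counts(alignments)
    estimates = {tx: 0.0 for tx in transcript_lengths}
    for tx, c in unamb.items():
        if tx not in estimates:
            raise KeyError(f"aligned transcript {tx} has no known length")
        estimates[tx] += c
    for aln in alignments:
        if not aln.ambiguous:
            continue
        cand = sorted(aln.candidates)
        cs = np.array([unamb.get(tx, 0) for tx in cand], dtype=float)
        if cs.sum() > 0:
            weights = cs / cs.sum()
        else:
            ls = np.array([transcript_lengths[tx] for tx in cand], dtype=float)
            weights = ls / ls.sum()
        for tx, w in zip(cand, weights):
            estimates[tx] += w
    return pd.Series(estimates, name="est_count").sort_index()


def unambiguous_quantify(
    alignments: Sequence[FragmentAlignment],
    transcripts: Iterable[str] | None = None,
) -> pd.Series:
    """Count only fragments with a single candidate; discard the rest.

    Conservative by construction: its total never exceeds the number of
    aligned fragments, and it undercounts whenever ambiguity exists.
    """
    counts = unambiguous_counts(alignments)
    if transcripts is not None:
        base = {tx: 0.0 for tx in transcripts}
        base.update({tx: float(c) for tx, c in counts.items() if tx in base})
        counts = base
    return pd.Series(counts, dtype=float, name="est_count").sort_index()


@dataclass
class QuantTable:
    """One quantification method's estimated counts, transcripts x samples."""

    method: str
    counts: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("estimated counts must be non-negative")
        self.counts = self.counts.sort_index()

    @classmethod
    def from_series(cls, method: str, per_sample: Mapping[str, pd.Series]) -> "QuantTable":
        frame = pd.DataFrame(per_sample).fillna(0.0)
        frame.index.name = "transcript_id"
        return cls(method, frame)

    def reindex(self, annotation: AnnotationSet | Iterable[str]) -> "QuantTable":
        """Cover every annotated transcript; missing ones become 0."""
        ids = (
            annotation.transcript_ids
            if isinstance(annotation, AnnotationSet)
            else sorted(annotation)
        )
        extra = set(ids) - set(self.counts.index)
        if extra:
            warnings.warn(
                f"{self.method}: {len(extra)} annotated transcripts missing from "
                "the quantifier output; filled with 0",
                stacklevel=2,
            )
        return QuantTable(self.method, self.counts.reindex(ids, fill_value=0.0))

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def mean_expression(self) -> pd.Series:
        return self.counts.mean(axis=1)

    def to_tsv(self, path) -> Path:
        path = Path(path)
        long = self.counts.stack().rename("est_count").reset_index()
        long.columns = ["transcript_id", "sample_id", "est_count"]
        long.insert(0, "method", self.method)
        long.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path) -> "QuantTable":
        long = pd.read_csv(path, sep="\t")
        needed = {"method", "transcript_id", "sample_id", "est_count"}
        if not needed <= set(long.columns):
            raise DialectError(
                f"quant table needs columns {sorted(needed)}, found {list(long.columns)}"
            )
        counts = long.pivot(index="transcript_id", columns="sample_id", values="est_count")
        return cls(str(long["method"].iloc[0]), counts.fillna(0.0))


_SIMPLE_DIALECTS = {
    "kallisto": ("target_id", "est_counts"),
    "salmon": ("Name", "NumReads"),
    "rsem": ("transcript_id", "expected_count"),
}


def read_external_quant(
    path,
    dialect: str,
    annotation: AnnotationSet | None = None,
    sample_id: str = "S1",
    method: str | None = None,
) -> QuantTable:
    """Ingest one external quantifier's per-sample output table.

    Supported dialects: kallisto (est_counts), salmon (NumReads), rsem
    (expected_count), cufflinks (isoforms.count_tracking, *_count column),
    htseq (headerless two-column), featurecounts ('#'-commented, last
    column), generic (transcript_id/est_count header or plain two columns).
    An unrecognized column layout raises DialectError naming the headers
    found. With an annotation, missing transcripts are filled with 0.
    """
    method = method or dialect
    if dialect in _SIMPLE_DIALECTS:
        id_col, count_col = _SIMPLE_DIALECTS[dialect]
        table = pd.read_csv(path, sep="\t")
        _require_columns(table, [id_col, count_col], dialect)
        series = table.set_index(id_col)[count_col].astype(float)
    elif dialect == "cufflinks":
        table = pd.read_csv(path, sep="\t")
        _require_columns(table, ["tracking_id"], dialect)
        count_cols = [c for c in table.columns if c.endswith("_count")]
        if not count_cols:
            raise DialectError(
                f"cufflinks dialect needs a *_count column; found {list(table.columns)}"
            )
        series = table.set_index("tracking_id")[count_cols[0]].astype(float)
    elif dialect == "htseq":
        table = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "count"])
        table = table[~table["transcript_id"].astype(str).str.startswith("__")]
        series = table.set_index("transcript_id")["count"].astype(float)
    elif dialect == "featurecounts":
        table = pd.read_csv(path, sep="\t", comment="#")
        _require_columns(table, ["Geneid"], dialect)
        series = table.set_index("Geneid")[table.columns[-1]].astype(float)
    elif dialect == "generic":
        table = pd.read_csv(path, sep="\t")
        if {"transcript_id", "est_count"} <= set(table.columns):
            series = table.set_index("transcript_id")["est_count"].astype(float)
        elif table.shape[1] >= 2:
            table = pd.read_csv(path, sep="\t", header=None)
            series = table.set_index(0)[1].astype(float)
        else:
            raise DialectError(
                f"generic dialect needs two columns; found {list(table.columns)}"
            )
    else:
        raise DialectError(f"unknown dialect {dialect!r}")
    series.index = series.index.astype(str)
    quant = QuantTable.from_series(method, {sample_id: series})
    if annotation is not None:
        quant = quant.reindex(annotation)
    return quant


def _require_columns(table: pd.DataFrame, columns: Sequence[str], dialect: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise DialectError(
            f"{dialect} dialect expects columns {list(columns)}; "
            f"found {list(table.columns)}"
        )


def read_sam_alignments(path) -> list[FragmentAlignment]:
    """Load multi-mapped transcriptome alignments from SAM/BAM.

    Candidates for a fragment are all reference transcripts reported for it;
    when both mates are present the candidate set is the intersection of
    their per-mate sets (mates must agree). Relies on the aligner reporting
    multi-mappers (e.g. secondary alignments).
    """
    import pysam

    mate_refs: dict[str, tuple[set, set]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for record in handle:
            if record.is_unmapped or record.reference_name is None:
                continue
            slot = 1 if record.is_paired and record.is_read2 else 0
            mate_refs.setdefault(record.query_name, (set(), set()))[slot].add(
                record.reference_name
            )
    alignments = []
    for fragment_id in sorted(mate_refs):
        refs1, refs2 = mate_refs[fragment_id]
        if refs1 and refs2:
            candidates = refs1 & refs2
        else:
            candidates = refs1 or refs2
        if candidates:
            alignments.append(FragmentAlignment(fragment_id, frozenset(candidates)))
    return alignments
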