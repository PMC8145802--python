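"""Strand-specific paired-end read simulation with known per-read origin.

Given a truth table and an annotation, each transcript with true count c
yields exactly c fragments. Fragments come from the spliced sequence, or from
the unspliced pre-mRNA with probability ``intron_freq`` (intron signal).
Fragment lengths follow a triangular distribution (min, mode, max); fragment
starts are uniform or 3'-biased. Per-sample haploid polymorphisms (SNPs and
short indels) are planted in the genome before sequence extraction, and
per-base sequencing errors are applied to the mates. The origin of every read
is logged, which is what makes the output usable as benchmarking ground
truth.
"""
from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, replace
from math import exp, log
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import as_rng, stage_rng
from .annotation import (
    AnnotationSet,
    GenomeSequence,
    TranscriptModel,
    premrna_sequence,
    reverse_complement,
    spliced_sequence,
)
from .errors import CoordinateError, TruthAnnotationMismatchError

_BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[ord(_b)] = _i
_BASE_BYTES = np.frombuffer(_BASES.encode(), dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the simulator; probabilities are per base or per fragment.

    ``frag_min/frag_mode/frag_max`` parameterize the triangular fragment-length
    distribution; ``coverage_bias`` is "uniform" or "three_prime" with
    exponential positional weight exp(bias_strength * p / L).
    """

    error_rate: float = 0.005
    sub_freq: float = 0.001
    indel_freq: float = 0.0001
    intron_freq: float = 0.05
    frag_min: int = 100
    frag_mode: int = 250
    frag_max: int = 500
    read_length: int = 100
    strand_specific: bool = True
    coverage_bias: str = "uniform"
    bias_strength: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "sub_freq", "indel_freq", "intron_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (1 <= self.frag_min <= self.frag_mode <= self.frag_max):
            raise ValueError("require 1 <= frag_min <= frag_mode <= frag_max")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.coverage_bias not in ("uniform", "three_prime"):
            raise ValueError(f"unknown coverage_bias {self.coverage_bias!r}")

    @classmethod
    def idealized(cls, **overrides) -> "SimulationConfig":
        """No errors, no polymorphisms, no intron signal, uniform coverage."""
        base = dict(
            error_rate=0.0, sub_freq=0.0, indel_freq=0.0, intron_freq=0.0,
            coverage_bias="uniform",
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def realistic(cls, **overrides) -> "SimulationConfig":
        """Errors, polymorphisms, 5% intron signal and 3'-biased coverage."""
        base = dict(
            error_rate=0.005, sub_freq=0.001, indel_freq=0.0001, intron_freq=0.05,
            coverage_bias="three_prime",
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int       # reference coordinate, 0-based
    ref: str       # "" for insertions
    alt: str       # "" for deletions
    kind: str      # sub | ins | del


class CoordinateMap:
    """Reference → mutated-genome coordinate liftover for one chromosome.

    Positions inside a deletion are clamped to the deletion start so exon
    boundaries remain valid after lifting.
    """

    def __init__(self, variants: list[Variant]):
        points: list[tuple[int, int]] = []
        self._deletions: list[tuple[int, int]] = []
        for v in variants:
            if v.kind == "ins":
                points.append((v.pos + 1, len(v.alt)))
            elif v.kind == "del":
                k = len(v.ref)
                points.append((v.pos + k, -k))
                self._deletions.append((v.pos, v.pos + k))
        points.sort()
        self._thresholds = [p for p, _ in points]
        self._cumulative = np.cumsum([d for _, d in points]).tolist()
        self._del_starts = [s for s, _ in self._deletions]

    def lift(self, pos: int) -> int:
        i = bisect.bisect_right(self._del_starts, pos) - 1
        if i >= 0:
            start, end = self._deletions[i]
            if start < pos < end:
                pos = start
        j = bisect.bisect_right(self._thresholds, pos)
        return pos + (self._cumulative[j - 1] if j else 0)


@dataclass
class PolymorphismResult:
    genome: GenomeSequence
    variants: list[Variant]
    maps: dict[str, CoordinateMap]

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.chrom, v.pos, v.ref, v.alt, v.kind) for v in self.variants],
            columns=["chrom", "pos", "ref", "alt", "kind"],
        )


def apply_polymorphisms(
    genome: GenomeSequence, config: SimulationConfig, rng
) -> PolymorphismResult:
    """Plant per-sample SNPs and short (1-3 bp) indels in a genome copy.

    Each base is substituted independently with probability ``sub_freq`` (to a
    uniformly chosen different base; N bases are never substituted). Indel
    events start with probability ``indel_freq`` per base, insertion or
    deletion equiprobable. Returns the mutated genome, the variant log in
    reference coordinates, and a coordinate liftover per chromosome.
    """
    rng = as_rng(rng)
    new_sequences: dict[str, str] = {}
    variants: list[Variant] = []
    maps: dict[str, CoordinateMap] = {}
    for chrom in genome.chrom_names:
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        chrom_variants: list[Variant] = []

        if config.sub_freq > 0:
            mask = rng.random(arr.size) < config.sub_freq
            idx = np.nonzero(mask & (_BASE_INDEX[arr] >= 0))[0]
            if idx.size:
                cur = _BASE_INDEX[arr[idx]].astype(np.int64)
                alt = (cur + rng.integers(1, 4, size=idx.size)) % 4
                refs = arr[idx].copy()
                arr[idx] = _BASE_BYTES[alt]
                for p, r, a in zip(idx.tolist(), refs.tolist(), arr[idx].tolist()):
                    chrom_variants.append(Variant(chrom, p, chr(r), chr(a), "sub"))

        indel_variants: list[Variant] = []
        if config.indel_freq > 0:
            positions = np.nonzero(rng.random(arr.size) < config.indel_freq)[0]
            blocked = -1
            for p in positions.tolist():
                if p <= blocked:
                    continue
                length = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # insertion after position p
                    ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
                    indel_variants.append(Variant(chrom, p, "", ins, "ins"))
                    blocked = p
                else:  # deletion of [p, p + length), clipped to the chromosome
                    end = min(p + length, arr.size)
                    ref = seq[p:end]
                    indel_variants.append(Variant(chrom, p, ref, "", "del"))
                    blocked = end - 1

        pieces: list[bytes] = []
        cursor = 0
        for v in indel_variants:
            if v.kind == "ins":
                pieces.append(arr[cursor : v.pos + 1].tobytes())
                pieces.append(v.alt.encode("ascii"))
                cursor = v.pos + 1
            else:
                pieces.append(arr[cursor : v.pos].tobytes())
                cursor = v.pos + len(v.ref)
        pieces.append(arr[cursor:].tobytes())
        new_sequences[chrom] = b"".join(pieces).decode("ascii")

        chrom_variants.extend(indel_variants)
        chrom_variants.sort(key=lambda v: v.pos)
        variants.extend(chrom_variants)
        maps[chrom] = CoordinateMap(indel_variants)
    return PolymorphismResult(GenomeSequence(new_sequences), variants, maps)


def draw_fragment(transcript_length: int, config: SimulationConfig, rng) -> tuple[int, int]:
    """Draw one (start, length) fragment on a transcript.

    Length is triangular(frag_min, frag_mode, frag_max) truncated at the
    transcript length; a transcript shorter than frag_min yields the whole
    transcript (with a warning). Starts are uniform, or weighted toward the
    3' end by exp(bias_strength * p / L) under three_prime bias.
    """
    rng = as_rng(rng)
    if transcript_length < config.frag_min:
        warnings.warn(
            f"transcript shorter ({transcript_length}) than frag_min "
            f"({config.frag_min}); using the whole transcript",
            stacklevel=2,
        )
        return 0, transcript_length
    if config.frag_min == config.frag_max:
        length = min(config.frag_min, transcript_length)
    else:
        length = int(round(rng.triangular(config.frag_min, config.frag_mode, config.frag_max)))
        length = max(config.frag_min, min(length, config.frag_max, transcript_length))
    max_start = transcript_length - length
    if max_start == 0:
        return 0, length
    if config.coverage_bias == "uniform":
        start = int(rng.integers(0, max_start + 1))
    else:
        # inverse-CDF sample of w(s) ∝ exp(lam * s / L) on [0, max_start]
        lam = config.bias_strength
        u = rng.random()
        scale = lam * max_start / transcript_length
        if abs(scale) < 1e-12:
            start = int(rng.integers(0, max_start + 1))
        else:
            s = (transcript_length / lam) * log(1.0 + u * (exp(scale) - 1.0))
            start = min(int(s), max_start)
    return start, length


def sequence_read_pair(
    fragment: str, config: SimulationConfig, rng
) -> tuple[str, str]:
    """Sequence both ends of a fragment.

    Mate 1 is the first ``read_length`` bases of the (sense-strand) fragment;
    mate 2 is the reverse complement of the last ``read_length`` bases. Both
    truncate to the fragment when it is shorter. Each sequenced base is
    miscalled independently with probability ``error_rate`` (to a uniformly
    chosen different base; N stays N).
    """
    if not fragment:
        raise ValueError("fragment must be non-empty")
    rng = as_rng(rng)
    rl = min(config.read_length, len(fragment))
    mate1 = fragment[:rl]
    mate2 = reverse_complement(fragment[-rl:])
    if config.error_rate > 0:
        mate1 = _miscall(mate1, config.error_rate, rng)
        mate2 = _miscall(mate2, config.error_rate, rng)
    return mate1, mate2


def _miscall(read: str, rate: float, rng) -> str:
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    idx = np.nonzero(mask & (_BASE_INDEX[arr] >= 0))[0]
    if idx.size:
        cur = _BASE_INDEX[arr[idx]].astype(np.int64)
        arr[idx] = _BASE_BYTES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
    return arr.tobytes().decode("ascii")


@dataclass
class ReadSetBundle:
    """Simulated reads for one sample plus the per-read origin log."""

    sample_id: str
    pairs: list[tuple[str, str, str]]     # (read_id, mate1, mate2)
    origin: pd.DataFrame                  # read_id, sample_id, transcript_id, ...
    realized_counts: pd.Series            # transcript -> fragments emitted
    variants: pd.DataFrame | None = None
    fastq1: Path | None = None
    fastq2: Path | None = None

    def __post_init__(self):
        if len(self.pairs) != len(self.origin):
            raise ValueError("origin log and read pairs disagree in length")
        if len(self.pairs) != int(self.realized_counts.sum()):
            raise ValueError("realized counts do not sum to the number of pairs")

    def write_fastq(self, out_dir) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p1 = out_dir / f"{self.sample_id}_1.fastq"
        p2 = out_dir / f"{self.sample_id}_2.fastq"
        with open(p1, "w") as h1, open(p2, "w") as h2:
            for read_id, m1, m2 in self.pairs:
                h1.write(f"@{read_id}/1\n{m1}\n+\n{'I' * len(m1)}\n")
                h2.write(f"@{read_id}/2\n{m2}\n+\n{'I' * len(m2)}\n")
        self.fastq1, self.fastq2 = p1, p2
        return p1, p2

    def write_origin(self, path) -> Path:
        path = Path(path)
        self.origin.to_csv(path, sep="\t", index=False)
        return path


def read_fastq_pairs(path1, path2) -> list[tuple[str, str, str]]:
    """Load paired 4-line FASTQ files back into (read_id, mate1, mate2)."""
    def _records(path):
        with open(path) as handle:
            lines = [line.rstrip("\n") for line in handle]
        for i in range(0, len(lines), 4):
            rid = lines[i][1:].split("/")[0].split()[0]
            yield rid, lines[i + 1]

    pairs = []
    for (id1, seq1), (id2, seq2) in zip(_records(path1), _records(path2)):
        if id1 != id2:
            raise ValueError(f"unpaired FASTQ records: {id1} vs {id2}")
        pairs.append((id1, seq1, seq2))
    return pairs


ORIGIN_COLUMNS = [
    "read_id", "sample_id", "transcript_id",
    "fragment_start", "fragment_length", "from_premrna",
]


def simulate_sample(
    annotation: AnnotationSet,
    genome: GenomeSequence,
    sample_counts: Mapping[str, int] | pd.Series,
    config: SimulationConfig,
    sample_id: str,
) -> ReadSetBundle:
    """Simulate one sample: exactly ``count`` fragments per transcript.

    A fresh haploid polymorphism draw is made for the sample (unless both
    sub_freq and indel_freq are zero), annotation exons are lifted through
    the indel coordinate map, and fragments are drawn per transcript from the
    spliced sequence or, with probability intron_freq, the pre-mRNA.
    Deterministic given (config.seed, sample_id).
    """
    rng = stage_rng(config.seed, "sample", sample_id)
    counts = pd.Series(dict(sample_counts)).astype(int)
    expressed = counts[counts > 0].sort_index()
    missing = set(expressed.index) - set(annotation.transcripts)
    if missing:
        raise TruthAnnotationMismatchError(
            f"expressed transcripts absent from annotation: {sorted(missing)[:5]}"
        )

    if config.sub_freq > 0 or config.indel_freq > 0:
        poly = apply_polymorphisms(genome, config, rng)
        sample_genome, maps = poly.genome, poly.maps
        variant_frame = poly.variant_frame()
    else:
        sample_genome, maps, variant_frame = genome, None, None

    pairs: list[tuple[str, str, str]] = []
    origin_rows: list[tuple] = []
    serial = 0
    for tx_id, count in expressed.items():
        model = annotation.transcripts[tx_id]
        if maps is not None:
            model = _lift_model(model, maps[model.chrom])
        spliced = spliced_sequence(model, sample_genome)
        premrna = (
            premrna_sequence(model, sample_genome) if config.intron_freq > 0 else None
        )
        for _ in range(int(count)):
            from_premrna = bool(
                config.intron_freq > 0 and rng.random() < config.intron_freq
            )
            source = premrna if from_premrna else spliced
            start, length = draw_fragment(len(source), config, rng)
            fragment = source[start : start + length]
            mate1, mate2 = sequence_read_pair(fragment, config, rng)
            read_id = f"{sample_id}.{serial:07d}"
            serial += 1
            pairs.append((read_id, mate1, mate2))
            origin_rows.append(
                (read_id, sample_id, tx_id, start, length, from_premrna)
            )
    origin = pd.DataFrame(origin_rows, columns=ORIGIN_COLUMNS)
    realized = expressed.copy()
    return ReadSetBundle(
        sample_id=sample_id,
        pairs=pairs,
        origin=origin,
        realized_counts=realized,
        variants=variant_frame,
    )


def _lift_model(model: TranscriptModel, cmap: CoordinateMap) -> TranscriptModel:
    lifted = []
    for start, end in model.exons:
        s, e = cmap.lift(start), cmap.lift(end)
        if e > s:
            lifted.append((s, e))
    if not lifted:
        raise CoordinateError(
            f"{model.transcript_id}: all exons deleted by sample polymorphisms"
        )
    return replace(model, exons=tuple(lifted))
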