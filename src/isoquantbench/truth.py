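"""Synthetic two-condition, multi-replicate ground truth.

This module stands in for empirically derived expression profiles: each gene
gets a per-condition mean expression (log-normal across genes) with
negative-binomial replicate-to-replicate noise, a per-gene PSI (percent
spliced included) vector shared across samples with a small uniform
per-sample perturbation, a configurable fraction of genes with
condition-dependent PSI (differential splicing), and a configurable fraction
of truly differentially expressed genes. Transcript-level true fragment
counts are allocated from gene counts by a multinomial draw with PSI
probabilities, so isoform counts always sum exactly to their gene's count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import as_rng, stage_rng
from .annotation import AnnotationSet


@dataclass
class TruthConfig:
    """Parameters of the synthetic ground truth.

    Defaults give a small two-tissue design with three biological replicates
    per condition, ~7.4% of multi-isoform genes differentially spliced and
    10% of expressed genes differentially expressed at 4-fold.
    """

    n_genes: int = 100
    isoform_count_probs: Sequence[float] = (0.45, 0.30, 0.15, 0.10)  # P(1..4 isoforms)
    replicates_per_condition: int = 3
    conditions: tuple[str, str] = ("A", "B")
    log_mean: float = 5.0       # natural-log mean of per-gene expression means
    log_sigma: float = 1.0      # natural-log sd of per-gene expression means
    nb_dispersion: float = 0.1  # var = m + dispersion * m^2; 0 -> Poisson
    unexpressed_gene_fraction: float = 0.2
    ds_fraction: float = 0.074  # genes with condition-dependent PSI
    ds_min_shift: float = 0.2   # minimum max-entry PSI difference between conditions
    de_fraction: float = 0.1
    de_effect: float = 4.0      # fold-change of DE genes between conditions
    psi_jitter: float = 0.025   # half-width of the per-sample PSI perturbation
    psi_alpha: float = 1.0      # Dirichlet concentration for base PSI vectors
    min_transcript_length: int = 200  # genes whose isoforms are all shorter get 0
    seed: int = 0

    def __post_init__(self):
        for name in ("unexpressed_gene_fraction", "ds_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        probs = np.asarray(self.isoform_count_probs, dtype=float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("isoform_count_probs must be a probability vector")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}{i + 1}"
            for cond in self.conditions
            for i in range(self.replicates_per_condition)
        ]

    def condition_of(self) -> pd.Series:
        mapping = {
            f"{cond}{i + 1}": cond
            for cond in self.conditions
            for i in range(self.replicates_per_condition)
        }
        return pd.Series(mapping, name="condition")


@dataclass
class GeneExpression:
    """Per-sample gene counts plus the DE assignment that produced them."""

    counts: pd.DataFrame          # genes x samples, non-negative ints
    condition: pd.Series          # sample_id -> condition label
    de_genes: frozenset


@dataclass
class PsiMatrix:
    """Per-gene isoform proportions, per sample, after perturbation."""

    samples: list[str]
    isoforms: dict[str, list[str]]          # gene -> ordered transcript ids
    values: dict[str, np.ndarray]           # gene -> (n_isoforms, n_samples)
    ds_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for gene, mat in self.values.items():
            if mat.shape != (len(self.isoforms[gene]), len(self.samples)):
                raise ValueError(f"PSI matrix shape mismatch for gene {gene}")
            sums = mat.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError(f"PSI columns for gene {gene} do not sum to 1")
            if mat.min() < 0 or mat.max() > 1:
                raise ValueError(f"PSI entries for gene {gene} outside [0, 1]")

    def vector(self, gene: str, sample: str) -> np.ndarray:
        return self.values[gene][:, self.samples.index(sample)]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for gene in sorted(self.values):
            for i, tx in enumerate(self.isoforms[gene]):
                for j, sample in enumerate(self.samples):
                    records.append((gene, tx, sample, self.values[gene][i, j]))
        return pd.DataFrame(
            records, columns=["gene_id", "transcript_id", "sample_id", "psi"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class TruthTable:
    """Long-format per-sample, per-transcript true fragment counts."""

    df: pd.DataFrame  # sample_id, transcript_id, gene_id, true_count, condition

    COLUMNS = ["sample_id", "transcript_id", "gene_id", "true_count", "condition"]

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        if (self.df["true_count"] < 0).any():
            raise ValueError("true counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def condition_of(self) -> pd.Series:
        return (
            self.df[["sample_id", "condition"]]
            .drop_duplicates()
            .set_index("sample_id")["condition"]
        )

    def counts_matrix(self) -> pd.DataFrame:
        """Transcripts x samples matrix of true counts (absent = 0)."""
        return (
            self.df.pivot_table(
                index="transcript_id",
                columns="sample_id",
                values="true_count",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
        )

    def total_counts(self) -> pd.Series:
        return self.df.groupby("transcript_id")["true_count"].sum().sort_index()

    def sample_counts(self, sample_id: str) -> pd.Series:
        sub = self.df[self.df["sample_id"] == sample_id]
        return sub.set_index("transcript_id")["true_count"].sort_index()

    def gene_of(self) -> pd.Series:
        return (
            self.df[["transcript_id", "gene_id"]]
            .drop_duplicates()
            .set_index("transcript_id")["gene_id"]
        )

    def to_tsv(self, path) -> None:
        self.df[self.COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


def sample_gene_counts(
    config: TruthConfig,
    gene_ids: Sequence[str] | None = None,
    rng=None,
) -> GeneExpression:
    """Draw per-sample gene counts for a two-condition replicate design.

    Per-gene means are log-normal; a configured fraction of genes is silenced
    in both conditions; DE genes have their second-condition mean multiplied
    or divided by the configured effect; per-sample counts are negative
    binomial around the condition mean.
    """
    rng = as_rng(stage_rng(config.seed, "gene-counts") if rng is None else rng)
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    gene_ids = list(gene_ids)
    n = len(gene_ids)

    means = rng.lognormal(config.log_mean, config.log_sigma, size=n)
    silent = rng.random(n) < config.unexpressed_gene_fraction
    means[silent] = 0.0

    expressed_idx = np.nonzero(~silent)[0]
    n_de = int(round(config.de_fraction * expressed_idx.size))
    de_idx = rng.choice(expressed_idx, size=n_de, replace=False) if n_de else np.array([], int)
    direction = rng.choice([1.0, -1.0], size=de_idx.size)

    cond_means = {config.conditions[0]: means.copy(), config.conditions[1]: means.copy()}
    second = cond_means[config.conditions[1]]
    second[de_idx] = means[de_idx] * config.de_effect ** direction

    condition = config.condition_of()
    counts = np.zeros((n, len(config.sample_ids)), dtype=np.int64)
    for j, sample in enumerate(config.sample_ids):
        m = cond_means[condition[sample]]
        counts[:, j] = _noisy_counts(m, config.nb_dispersion, rng)
    frame = pd.DataFrame(counts, index=gene_ids, columns=config.sample_ids)
    return GeneExpression(
        counts=frame,
        condition=condition,
        de_genes=frozenset(gene_ids[i] for i in de_idx),
    )


def _noisy_counts(means: np.ndarray, dispersion: float, rng) -> np.ndarray:
    out = np.zeros_like(means, dtype=np.int64)
    pos = means > 0
    if not pos.any():
        return out
    m = means[pos]
    if dispersion <= 0:
        out[pos] = rng.poisson(m)
    else:
        size = 1.0 / dispersion
        p = size / (size + m)
        out[pos] = rng.negative_binomial(size, p)
    return out


def perturb_psi(psi, rng, jitter: float = 0.025) -> np.ndarray:
    """Apply per-sample inter-sample variability to one PSI vector.

    Each entry moves by an independent uniform(0, jitter) magnitude with a
    random sign, is clamped to [0, 1], and the vector is renormalized so it
    sums to 1 again. A single-isoform vector is returned unchanged ([1.0]).
    """
    rng = as_rng(rng)
    p = np.asarray(psi, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("input PSI vector must be non-negative and sum to 1")
    delta = rng.uniform(0.0, jitter, size=p.size) * rng.choice([-1.0, 1.0], size=p.size)
    q = np.clip(p + delta, 0.0, 1.0)
    total = q.sum()
    if total <= 0:  # all entries clamped to zero; keep the original proportions
        return p.copy()
    return q / total


def assign_psi(
    config: TruthConfig,
    isoform_map: Mapping[str, Sequence[str]],
    rng=None,
    ds_genes: Sequence[str] | None = None,
) -> PsiMatrix:
    """Base PSI vectors per gene (condition-specific for DS genes), then the
    per-sample perturbation applied to every sample independently."""
    rng = as_rng(stage_rng(config.seed, "psi") if rng is None else rng)
    samples = config.sample_ids
    condition = config.condition_of()

    if ds_genes is None:
        multi = [g for g in sorted(isoform_map) if len(isoform_map[g]) > 1]
        n_ds = int(round(config.ds_fraction * len(multi)))
        ds_genes = list(rng.choice(multi, size=n_ds, replace=False)) if n_ds else []
    ds_set = frozenset(ds_genes)

    values: dict[str, np.ndarray] = {}
    for gene in sorted(isoform_map):
        k = len(isoform_map[gene])
        if k == 1:
            values[gene] = np.ones((1, len(samples)))
            continue
        base = rng.dirichlet(np.full(k, config.psi_alpha))
        bases = {config.conditions[0]: base, config.conditions[1]: base}
        if gene in ds_set:
            for _ in range(100):
                alt = rng.dirichlet(np.full(k, config.psi_alpha))
                if np.max(np.abs(alt - base)) >= config.ds_min_shift:
                    break
            bases[config.conditions[1]] = alt
        mat = np.empty((k, len(samples)))
        for j, sample in enumerate(samples):
            mat[:, j] = perturb_psi(bases[condition[sample]], rng, config.psi_jitter)
        values[gene] = mat
    return PsiMatrix(
        samples=samples,
        isoforms={g: list(txs) for g, txs in isoform_map.items()},
        values=values,
        ds_genes=ds_set,
    )


def allocate_transcript_counts(
    gene_expression: GeneExpression, psi: PsiMatrix, rng=None
) -> TruthTable:
    """Split gene counts into isoform counts by a multinomial draw with PSI
    probabilities; isoform counts sum exactly to the gene count."""
    rng = as_rng(rng)
    counts = gene_expression.counts
    missing = set(counts.index) - set(psi.values)
    if missing:
        raise ValueError(f"PSI matrix missing genes: {sorted(missing)[:5]}")
    records = []
    for gene in counts.index:
        isoforms = psi.isoforms[gene]
        mat = psi.values[gene]
        for j, sample in enumerate(counts.columns):
            total = int(counts.loc[gene, sample])
            if total > 0:
                alloc = rng.multinomial(total, mat[:, j])
            else:
                alloc = np.zeros(len(isoforms), dtype=int)
            cond = gene_expression.condition[sample]
            for tx, c in zip(isoforms, alloc):
                records.append((sample, tx, gene, int(c), cond))
    df = pd.DataFrame(records, columns=TruthTable.COLUMNS)
    return TruthTable(df)


@dataclass
class TwoConditionTruth:
    """A complete synthetic dataset: truth table plus generating labels."""

    truth: TruthTable
    labels: pd.Series            # transcript_id -> {null, expressed, de}
    de_genes: frozenset
    ds_genes: frozenset
    psi: PsiMatrix
    gene_expression: GeneExpression


def build_two_condition_truth(
    config: TruthConfig, annotation: AnnotationSet | None = None
) -> TwoConditionTruth:
    """Generate a full two-condition truth set.

    With an annotation, the gene → isoform structure (and the minimum
    transcript length rule: genes whose isoforms are all shorter than
    ``min_transcript_length`` get zero expression) comes from it; otherwise a
    synthetic structure is drawn from ``isoform_count_probs``.
    """
    rng_struct = stage_rng(config.seed, "structure")
    if annotation is not None:
        isoform_map = {g: list(txs) for g, txs in annotation.genes.items()}
        gene_ids = sorted(isoform_map)
    else:
        gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
        ks = rng_struct.choice(
            np.arange(1, len(tuple(config.isoform_count_probs)) + 1),
            size=len(gene_ids),
            p=np.asarray(config.isoform_count_probs, dtype=float),
        )
        isoform_map = {
            g: [f"{g}.t{j + 1}" for j in range(int(k))] for g, k in zip(gene_ids, ks)
        }

    expression = sample_gene_counts(config, gene_ids, stage_rng(config.seed, "gene-counts"))

    if annotation is not None and config.min_transcript_length > 0:
        for gene, txs in isoform_map.items():
            lengths = [annotation.transcripts[t].spliced_length for t in txs]
            if max(lengths) < config.min_transcript_length:
                expression.counts.loc[gene, :] = 0

    psi = assign_psi(config, isoform_map, stage_rng(config.seed, "psi"))
    truth = allocate_transcript_counts(expression, psi, stage_rng(config.seed, "allocate"))

    totals = truth.total_counts()
    gene_of = truth.gene_of()
    labels = pd.Series("expressed", index=totals.index, name="label")
    labels[totals == 0] = "null"
    de_tx = gene_of.index[(gene_of.isin(expression.de_genes)) & (totals > 0)]
    labels[de_tx] = "de"
    return TwoConditionTruth(
        truth=truth,
        labels=labels,
        de_genes=expression.de_genes,
        ds_genes=psi.ds_genes,
        psi=psi,
        gene_expression=expression,
    )
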