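"""Accuracy, enrichment, clustering and DE-concordance statistics.

The central accuracy metric is the pseudocount-adjusted absolute log2 fold
change |logFC| = |log2((y + 1) / (x + 1))| of an estimated count y against
the true count x; 0 means a perfect estimate and ±10 is roughly a 1000-fold
error. Everything else in this module summarizes that metric (percentile
curves, per-bin means, discordant sets, property enrichment) or measures how
well a method's estimates inform a downstream differential-expression call
(Jaccard concordance of top-n lists, q-value count curves, and a lower bound
on the realized FDR from transcripts known to be null).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotation import AnnotationSet
from .errors import DialectError, ValidationError
from .truth import TruthTable


# ---------------------------------------------------------------------------
# accuracy


def abs_log_fc(true_count: float, est_count: float) -> float:
    """|log2((est + 1) / (true + 1))| for one transcript."""
    if true_count < 0 or est_count < 0:
        raise ValueError("counts must be non-negative")
    return float(abs(np.log2((est_count + 1.0) / (true_count + 1.0))))


def accuracy_table(true_counts: pd.Series, est_counts: pd.Series) -> pd.DataFrame:
    """Per-transcript truth/estimate pairs with signed and absolute logFC.

    Aligned on the union of indices; a transcript absent from one side
    counts as 0 there.
    """
    idx = true_counts.index.union(est_counts.index)
    x = true_counts.reindex(idx, fill_value=0).astype(float)
    y = est_counts.reindex(idx, fill_value=0).astype(float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    logfc = np.log2((y + 1.0) / (x + 1.0))
    return pd.DataFrame(
        {"true_count": x, "est_count": y, "logfc": logfc, "abs_logfc": logfc.abs()}
    ).sort_index()


def expressed_filter(truth: TruthTable, annotation: AnnotationSet) -> list[str]:
    """Transcripts of genes with at least one expressed isoform.

    Genes whose every isoform has zero truth are dropped entirely; a
    zero-truth isoform survives if a sibling is expressed.
    """
    totals = truth.total_counts()
    keep: list[str] = []
    for gene_id, tx_ids in annotation.genes.items():
        if any(totals.get(tx, 0) > 0 for tx in tx_ids):
            keep.extend(tx_ids)
    return sorted(keep)


def percentile_curve(
    values: Sequence[float], percentiles: Sequence[int] | None = None
) -> pd.DataFrame:
    """Nearest-rank percentiles of a value set, every 10% by default.

    A row (x, y) means x% of the values are <= y; the curve is monotone
    non-decreasing.
    """
    vals = np.sort(np.asarray(list(values), dtype=float))
    if vals.size == 0:
        raise ValueError("percentile_curve needs at least one value")
    if percentiles is None:
        percentiles = list(range(0, 101, 10))
    rows = []
    for x in percentiles:
        rank = max(1, int(np.ceil(x / 100.0 * vals.size)))
        rows.append((x, float(vals[rank - 1])))
    return pd.DataFrame(rows, columns=["percentile", "value"])


def spearman_per_sample(truth: TruthTable, quant: "QuantTable | pd.DataFrame") -> pd.Series:
    """Spearman rho between true and estimated counts, per shared sample.

    A constant vector in either input makes the correlation undefined; the
    sample gets NaN with a warning.
    """
    est = quant.counts if hasattr(quant, "counts") else quant
    true_mat = truth.counts_matrix()
    idx = true_mat.index.union(est.index)
    true_mat = true_mat.reindex(idx, fill_value=0)
    est = est.reindex(idx, fill_value=0)
    out = {}
    for sample in [s for s in true_mat.columns if s in est.columns]:
        x, y = true_mat[sample].to_numpy(float), est[sample].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"sample {sample}: constant vector, correlation undefined")
            out[sample] = np.nan
            continue
        out[sample] = float(stats.spearmanr(x, y).statistic)
    return pd.Series(out, name="spearman_rho")


# ---------------------------------------------------------------------------
# method similarity


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    distance: pd.DataFrame

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def build(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = build(node.left), build(node.right)
            dl = max(node.dist - node.left.dist, 0.0)
            dr = max(node.dist - node.right.dist, 0.0)
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return build(tree) + ";"


def cluster_methods(
    vectors: Mapping[str, pd.Series] | pd.DataFrame,
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of methods with correlation distance.

    Each method contributes one feature vector (typically per-transcript mean
    estimated counts, or cross-condition logFC values); the distance between
    two methods is 1 - Pearson correlation; linkage is average by default.
    """
    frame = pd.DataFrame(vectors) if not isinstance(vectors, pd.DataFrame) else vectors
    if frame.shape[1] < 2:
        raise ValueError("clustering needs at least two methods")
    data = frame.to_numpy(float).T  # methods x features
    if np.any(np.ptp(data, axis=1) == 0):
        raise ValueError("a method's feature vector is constant; correlation undefined")
    corr = np.corrcoef(data)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    labels = list(frame.columns)
    return ClusterResult(
        labels=labels,
        linkage=linkage,
        distance=pd.DataFrame(dist, index=labels, columns=labels),
    )


# ---------------------------------------------------------------------------
# structural-property enrichment


def mean_abslogfc_by_bin(
    abs_logfc: pd.DataFrame,
    truth: TruthTable,
    annotation: AnnotationSet,
    samples: Sequence[str] | None = None,
    min_transcripts: int = 100,
) -> pd.DataFrame:
    """Mean |logFC| grouped by the gene's number of expressed isoforms.

    ``abs_logfc`` is a transcripts x replicates frame; each gene's bin is the
    maximum, over the chosen replicates, of its per-sample count of expressed
    isoforms. Bins supported by fewer than ``min_transcripts`` transcripts
    are omitted.
    """
    counts = truth.counts_matrix()
    if samples is not None:
        counts = counts[list(samples)]
    gene_of = truth.gene_of()
    expressed = (counts > 0).astype(int)
    per_gene = expressed.groupby(gene_of.reindex(expressed.index)).sum()
    gene_bin = per_gene.max(axis=1)

    per_tx = abs_logfc.mean(axis=1).rename("abs_logfc").to_frame()
    per_tx["gene_id"] = gene_of.reindex(per_tx.index)
    per_tx["bin"] = per_tx["gene_id"].map(gene_bin)
    per_tx = per_tx[per_tx["bin"] >= 1]
    grouped = per_tx.groupby("bin")["abs_logfc"].agg(["mean", "size"])
    grouped = grouped[grouped["size"] >= min_transcripts]
    out = grouped.reset_index()
    out.columns = ["n_expressed_isoforms", "mean_abs_logfc", "n_transcripts"]
    return out


def discordant_set(
    abs_logfc: pd.DataFrame | pd.Series, n: int = 2000
) -> list[str]:
    """The n transcripts most discordant from the truth.

    Ranked by mean |logFC| across replicates, descending; boundary ties break
    by transcript_id. If n exceeds the population the whole set is returned
    with a warning.
    """
    mean = abs_logfc.mean(axis=1) if isinstance(abs_logfc, pd.DataFrame) else abs_logfc
    order = sorted(mean.index, key=lambda tx: (-mean[tx], tx))
    if n > len(order):
        warnings.warn(f"requested {n} transcripts but only {len(order)} available")
        return order
    return order[:n]


def ks_enrichment(
    foreground_ids: Iterable[str],
    property_table: pd.DataFrame,
    n_methods: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample KS test of foreground vs background per property.

    The background is the full property table. Raw p-values are Bonferroni
    corrected by (number of properties) x (number of methods in the run),
    capped at 1.
    """
    fg = sorted(set(foreground_ids))
    if len(fg) < 2:
        raise ValueError("foreground must contain at least two transcripts")
    missing = set(fg) - set(property_table.index)
    if missing:
        raise KeyError(f"foreground ids absent from property table: {sorted(missing)[:5]}")
    factor = property_table.shape[1] * n_methods
    rows = {}
    for prop in property_table.columns:
        fg_vals = property_table.loc[fg, prop].to_numpy(float)
        bg_vals = property_table[prop].to_numpy(float)
        res = stats.ks_2samp(fg_vals, bg_vals)
        corrected = min(1.0, float(res.pvalue) * factor)
        rows[prop] = {
            "statistic": float(res.statistic),
            "pvalue": float(res.pvalue),
            "pvalue_bonferroni": corrected,
            "significant": corrected < alpha,
        }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "property"
    return report


# ---------------------------------------------------------------------------
# differential-expression concordance


def simple_de(counts: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    """Rank-test differential expression between two conditions.

    A stand-in DE caller for exercising the concordance machinery: per
    transcript, an exact two-sided Mann-Whitney U test between the replicate
    counts of the two conditions, Benjamini-Hochberg q-values, and the
    cross-condition logFC (pseudocount 1) used for tie-breaking.
    """
    condition = condition.reindex(counts.columns)
    levels = sorted(condition.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, found {levels}")
    a_cols = condition.index[condition == levels[0]]
    b_cols = condition.index[condition == levels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each condition needs at least two replicates")
    a = counts[a_cols].to_numpy(float)
    b = counts[b_cols].to_numpy(float)
    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        row = np.concatenate([a[i], b[i]])
        if np.ptp(row) == 0:  # identical values in every replicate: no evidence
            continue
        pvals[i] = stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
    qvals = stats.false_discovery_control(pvals, method="bh")
    logfc = np.log2((b.mean(axis=1) + 1.0) / (a.mean(axis=1) + 1.0))
    out = pd.DataFrame(
        {"pvalue": pvals, "qvalue": qvals, "logfc": logfc}, index=counts.index
    )
    out.index.name = "transcript_id"
    return out


def de_ranking(de_table: pd.DataFrame) -> list[str]:
    """Deterministic DE ranking: ascending q-value, ties broken by larger
    |logFC|, remaining ties by transcript_id."""
    _validate_de(de_table)
    key = pd.DataFrame(
        {
            "q": de_table["qvalue"],
            "neg_abs_logfc": -de_table["logfc"].abs(),
            "tx": de_table.index.astype(str),
        }
    )
    return list(key.sort_values(["q", "neg_abs_logfc", "tx"]).index)


def _validate_de(de_table: pd.DataFrame) -> None:
    if "qvalue" not in de_table.columns:
        raise DialectError(
            f"DE table needs a qvalue column; found {list(de_table.columns)}"
        )
    q = de_table["qvalue"]
    if ((q < 0) | (q > 1)).any():
        raise ValidationError("q-values must lie in [0, 1]")


def read_de_table(path) -> pd.DataFrame:
    """Ingest a generic external DE table (transcript_id, qvalue[, logfc])."""
    table = pd.read_csv(path, sep="\t")
    needed = {"transcript_id", "qvalue"}
    if not needed <= set(table.columns):
        raise DialectError(
            f"DE table needs columns {sorted(needed)}; found {list(table.columns)}"
        )
    if "logfc" not in table.columns:
        table["logfc"] = 0.0
    table = table.set_index("transcript_id")
    _validate_de(table)
    return table


def jaccard_topn_curve(
    ranking_true: Sequence[str],
    ranking_est: Sequence[str],
    n_grid: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Jaccard index of the top-n sets of two rankings, over a grid of n.

    Defaults to a logarithmic grid from 1 to the ranking length; n beyond the
    list length is truncated with a warning.
    """
    ranking_true = list(ranking_true)
    ranking_est = list(ranking_est)
    limit = min(len(ranking_true), len(ranking_est))
    if n_grid is None:
        n_grid = np.unique(np.geomspace(1, max(limit, 1), num=25).astype(int)).tolist()
    rows = []
    for n in n_grid:
        if n > limit:
            warnings.warn(f"top-{n} exceeds ranking length {limit}; truncated")
            n = limit
        top_a, top_b = set(ranking_true[:n]), set(ranking_est[:n])
        union = top_a | top_b
        rows.append((n, len(top_a & top_b) / len(union) if union else 0.0))
    return pd.DataFrame(rows, columns=["n", "jaccard"])


def qvalue_count_curve(
    de_table: pd.DataFrame, cutoffs: Sequence[float]
) -> pd.DataFrame:
    """Number of transcripts with q-value below each cutoff."""
    _validate_de(de_table)
    q = de_table["qvalue"].to_numpy(float)
    rows = [(x, int((q < x).sum())) for x in cutoffs]
    return pd.DataFrame(rows, columns=["cutoff", "n_below"])


def null_fdr_bound(
    de_table: pd.DataFrame, null_ids: Iterable[str], cutoffs: Sequence[float]
) -> pd.DataFrame:
    """Lower bound on the realized FDR from known-null transcripts.

    Every rejected transcript with zero true expression in all replicates of
    both conditions is a certain false positive, so
    #{null and q < x} / #{q < x} bounds the FDR at cutoff x from below
    (0 when nothing is rejected).
    """
    _validate_de(de_table)
    null_set = set(null_ids)
    is_null = de_table.index.isin(null_set)
    q = de_table["qvalue"].to_numpy(float)
    rows = []
    for x in cutoffs:
        rejected = q < x
        denom = int(rejected.sum())
        bound = float((rejected & is_null).sum() / denom) if denom else 0.0
        rows.append((x, bound, denom))
    return pd.DataFrame(rows, columns=["cutoff", "fdr_lower_bound", "n_rejected"])


# ---------------------------------------------------------------------------
# report container


@dataclass
class EvalReport:
    """A directory-of-TSVs evaluation report."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    cluster_newick: str | None = None

    def write(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in self.tables.items():
            path = out_dir / f"{name}.tsv"
            table.to_csv(path, sep="\t", index=not isinstance(table.index, pd.RangeIndex))
            written.append(path)
        if self.cluster_newick is not None:
            path = out_dir / "cluster.newick"
            path.write_text(self.cluster_newick + "\n")
            written.append(path)
        return written
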