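"""End-to-end orchestration: fixture → truth → simulate → quantify → evaluate.

Each stage writes its outputs under the run directory and records them (with
SHA-256 hashes) in ``manifest.json``; a rerun skips any stage whose
parameters are unchanged and whose outputs all still hash to the recorded
values, and reruns everything downstream of a stage that was dirty.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluate as ev
from .annotation import GenomeSequence, read_gtf
from .fixtures import make_toy_fixture
from .properties import build_property_table, write_property_table
from .quantify import QuantTable, exact_match_align, nrp_quantify, unambiguous_quantify
from .simulate import SimulationConfig, read_fastq_pairs, simulate_sample
from .truth import TruthConfig, TruthTable, build_two_condition_truth
from .annotation import spliced_sequence

log = logging.getLogger("isoquantbench")

STAGES = ("fixture", "truth", "simulate", "quantify", "evaluate")
BUILTIN_QUANTIFIERS = ("nrp", "unambiguous")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, serializable to YAML."""

    out_dir: str = "isoquantbench_run"
    genome_fasta: str | None = None       # None -> generate the toy fixture
    gtf: str | None = None
    fixture_isoform_counts: tuple[int, ...] | None = None  # None -> default fixture
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig.idealized)
    truth: TruthConfig = field(default_factory=TruthConfig)
    quantifiers: tuple[str, ...] = BUILTIN_QUANTIFIERS
    discordant_n: int = 2000
    min_bin_transcripts: int = 100
    qvalue_cutoffs: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2)

    def __post_init__(self):
        unknown = set(self.quantifiers) - set(BUILTIN_QUANTIFIERS)
        if unknown:
            raise ValueError(f"unknown quantifiers: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        truth = TruthConfig(**raw.pop("truth", {}))
        if "quantifiers" in raw:
            raw["quantifiers"] = tuple(raw["quantifiers"])
        if "qvalue_cutoffs" in raw:
            raw["qvalue_cutoffs"] = tuple(raw["qvalue_cutoffs"])
        return cls(simulation=sim, truth=truth, **raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["quantifiers"] = list(self.quantifiers)
        data["qvalue_cutoffs"] = list(self.qvalue_cutoffs)
        data["truth"]["isoform_count_probs"] = list(self.truth.isoform_count_probs)
        data["truth"]["conditions"] = list(self.truth.conditions)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _params_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}, "seed": None}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_clean(self, stage: str, params_hash: str, root: Path) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None or entry["params"] != params_hash:
            return False
        for rel, digest in entry["outputs"].items():
            path = root / rel
            if not path.exists() or _sha256(path) != digest:
                return False
        return True

    def record(self, stage: str, params_hash: str, outputs: list[Path], root: Path,
               elapsed: float) -> None:
        self.data["stages"][stage] = {
            "params": params_hash,
            "outputs": {str(p.relative_to(root)): _sha256(p) for p in outputs},
            "seconds": round(elapsed, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a summary dict with key output paths.

    Stages whose recorded outputs are intact and whose parameters are
    unchanged are skipped; a dirty stage forces every later stage to rerun.
    A stage failure raises with the failing stage named.
    """
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(root / "manifest.json")
    manifest.data["seed"] = config.seed
    dirty = False
    summary: dict = {"out_dir": str(root)}

    def run_stage(stage, params, action):
        nonlocal dirty
        phash = _params_hash(params)
        if not dirty and manifest.stage_clean(stage, phash, root):
            log.info("stage %s: up to date, skipped", stage)
            return False
        started = time.monotonic()
        try:
            outputs = action()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, phash, outputs, root, time.monotonic() - started)
        log.info("stage %s: done in %.2fs", stage, time.monotonic() - started)
        dirty = True
        return True

    # ---- fixture -----------------------------------------------------------
    genome_path = Path(config.genome_fasta) if config.genome_fasta else root / "genome.fa"
    gtf_path = Path(config.gtf) if config.gtf else root / "annotation.gtf"

    if config.genome_fasta is None or config.gtf is None:
        def do_fixture():
            kwargs = {"seed": config.seed}
            if config.fixture_isoform_counts is not None:
                kwargs["isoform_counts"] = tuple(config.fixture_isoform_counts)
            fixture = make_toy_fixture(**kwargs)
            paths = fixture.write(root)
            return [paths["genome"], paths["gtf"]]

        run_stage(
            "fixture",
            {"seed": config.seed, "isoform_counts": config.fixture_isoform_counts},
            do_fixture,
        )

    genome = GenomeSequence.from_fasta(genome_path)
    annotation = read_gtf(gtf_path)
    summary["genome"], summary["gtf"] = str(genome_path), str(gtf_path)

    # ---- truth -------------------------------------------------------------
    truth_cfg = dataclasses.replace(config.truth, seed=config.seed)
    truth_path = root / "truth.tsv"
    labels_path = root / "labels.tsv"
    psi_path = root / "psi.tsv"

    def do_truth():
        result = build_two_condition_truth(truth_cfg, annotation)
        result.truth.to_tsv(truth_path)
        result.labels.rename("label").to_csv(labels_path, sep="\t")
        result.psi.to_tsv(psi_path)
        return [truth_path, labels_path, psi_path]

    run_stage("truth", dataclasses.asdict(truth_cfg), do_truth)
    truth = TruthTable.from_tsv(truth_path)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)["label"]
    summary["truth"] = str(truth_path)

    # ---- simulate ----------------------------------------------------------
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    reads_dir = root / "reads"
    samples = truth.samples

    def do_simulate():
        outputs = []
        for sample in samples:
            bundle = simulate_sample(
                annotation, genome, truth.sample_counts(sample), sim_cfg, sample
            )
            p1, p2 = bundle.write_fastq(reads_dir)
            origin = bundle.write_origin(reads_dir / f"{sample}.origin.tsv")
            outputs.extend([p1, p2, origin])
        return outputs

    run_stage(
        "simulate",
        {"sim": dataclasses.asdict(sim_cfg), "samples": samples},
        do_simulate,
    )
    summary["reads_dir"] = str(reads_dir)

    # ---- quantify ----------------------------------------------------------
    quant_dir = root / "quant"

    def do_quantify():
        quant_dir.mkdir(parents=True, exist_ok=True)
        seqs = {
            tx: spliced_sequence(annotation.transcripts[tx], genome)
            for tx in annotation.transcript_ids
        }
        lengths = {tx: len(s) for tx, s in seqs.items()}
        budget = 0 if sim_cfg.error_rate == 0 and sim_cfg.sub_freq == 0 else 2
        per_method: dict[str, dict[str, pd.Series]] = {m: {} for m in config.quantifiers}
        for sample in samples:
            pairs = read_fastq_pairs(
                reads_dir / f"{sample}_1.fastq", reads_dir / f"{sample}_2.fastq"
            )
            alignments, _ = exact_match_align(
                pairs, seqs, sim_cfg.frag_min, sim_cfg.frag_max, max_mismatches=budget
            )
            if "nrp" in per_method:
                per_method["nrp"][sample] = nrp_quantify(alignments, lengths)
            if "unambiguous" in per_method:
                per_method["unambiguous"][sample] = unambiguous_quantify(
                    alignments, lengths
                )
        outputs = []
        for method, series in per_method.items():
            table = QuantTable.from_series(method, series).reindex(annotation)
            outputs.append(table.to_tsv(quant_dir / f"{method}.tsv"))
        return outputs

    run_stage(
        "quantify",
        {"quantifiers": list(config.quantifiers), "sim": dataclasses.asdict(sim_cfg)},
        do_quantify,
    )
    quants = {
        m: QuantTable.from_tsv(quant_dir / f"{m}.tsv") for m in config.quantifiers
    }
    summary["quant_dir"] = str(quant_dir)

    # ---- evaluate ----------------------------------------------------------
    report_dir = root / "report"

    def do_evaluate():
        report = _evaluate_all(
            config, genome, annotation, truth, labels, quants
        )
        outputs = report.write(report_dir)
        prop_path = report_dir / "properties.tsv"
        write_property_table(build_property_table(annotation, genome), prop_path)
        outputs.append(prop_path)
        return outputs

    run_stage(
        "evaluate",
        {
            "quantifiers": list(config.quantifiers),
            "discordant_n": config.discordant_n,
            "cutoffs": list(config.qvalue_cutoffs),
        },
        do_evaluate,
    )
    summary["report_dir"] = str(report_dir)
    summary["manifest"] = str(root / "manifest.json")
    return summary


def _evaluate_all(config, genome, annotation, truth, labels, quants) -> ev.EvalReport:
    report = ev.EvalReport()
    truth_mat = truth.counts_matrix()
    condition = truth.condition_of()
    expressed = ev.expressed_filter(truth, annotation)
    prop_table = build_property_table(annotation, genome)

    percentiles, spearman, ks_rows, accuracy_rows = [], [], [], []
    mean_vectors = {"truth": truth_mat.mean(axis=1)}
    for method, quant in quants.items():
        quant = quant.reindex(annotation)
        mean_vectors[method] = quant.mean_expression()
        acc = ev.accuracy_table(truth_mat.mean(axis=1), quant.mean_expression())
        accuracy_rows.append(
            {"method": method, "mean_abs_logfc": float(acc["abs_logfc"].mean())}
        )
        curve = ev.percentile_curve(acc.loc[acc.index.isin(expressed), "abs_logfc"])
        curve.insert(0, "method", method)
        percentiles.append(curve)
        rho = ev.spearman_per_sample(truth, quant).rename("spearman_rho").to_frame()
        rho.insert(0, "method", method)
        spearman.append(rho.reset_index(names="sample_id"))

        per_rep = pd.DataFrame(
            {
                s: ev.accuracy_table(truth_mat[s], quant.counts[s])["abs_logfc"]
                for s in truth_mat.columns
                if s in quant.counts.columns
            }
        )
        fg = ev.discordant_set(per_rep, min(config.discordant_n, len(per_rep)))
        ks = ev.ks_enrichment(fg, prop_table, n_methods=len(quants))
        ks.insert(0, "method", method)
        ks_rows.append(ks.reset_index())

    report.tables["accuracy_summary"] = pd.DataFrame(accuracy_rows)
    report.tables["percentiles"] = pd.concat(percentiles, ignore_index=True)
    report.tables["spearman"] = pd.concat(spearman, ignore_index=True)
    report.tables["ks_report"] = pd.concat(ks_rows, ignore_index=True)

    if len(mean_vectors) >= 2:
        cluster = ev.cluster_methods(pd.DataFrame(mean_vectors).fillna(0.0))
        report.cluster_newick = cluster.to_newick()

    # DE concordance: truth-based DE vs each method's DE
    de_truth = ev.simple_de(truth_mat, condition)
    rank_truth = ev.de_ranking(de_truth)
    null_ids = labels.index[labels == "null"]
    jaccard_rows, count_rows, fdr_rows = [], [], []
    for method, quant in quants.items():
        counts = quant.reindex(annotation).counts
        de_est = ev.simple_de(counts, condition)
        jac = ev.jaccard_topn_curve(rank_truth, ev.de_ranking(de_est))
        jac.insert(0, "method", method)
        jaccard_rows.append(jac)
        qc = ev.qvalue_count_curve(de_est, config.qvalue_cutoffs)
        qc.insert(0, "method", method)
        count_rows.append(qc)
        fdr = ev.null_fdr_bound(de_est, null_ids, config.qvalue_cutoffs)
        fdr.insert(0, "method", method)
        fdr_rows.append(fdr)
    qc_truth = ev.qvalue_count_curve(de_truth, config.qvalue_cutoffs)
    qc_truth.insert(0, "method", "truth")
    count_rows.append(qc_truth)

    report.tables["jaccard"] = pd.concat(jaccard_rows, ignore_index=True)
    report.tables["qvalue_counts"] = pd.concat(count_rows, ignore_index=True)
    report.tables["fdr_bound"] = pd.concat(fdr_rows, ignore_index=True)
    return report
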