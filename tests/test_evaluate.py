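"""Accuracy metrics, enrichment, clustering and DE-concordance statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoquantbench import (
    AnnotationSet,
    TranscriptModel,
    abs_log_fc,
    accuracy_table,
    cluster_methods,
    de_ranking,
    discordant_set,
    expressed_filter,
    jaccard_topn_curve,
    ks_enrichment,
    mean_abslogfc_by_bin,
    null_fdr_bound,
    percentile_curve,
    qvalue_count_curve,
    read_de_table,
    simple_de,
    spearman_per_sample,
)
from isoquantbench.errors import DialectError, ValidationError
from isoquantbench.truth import TruthTable


def make_truth(counts_by_sample, condition="A"):
    rows = []
    for sample, counts in counts_by_sample.items():
        for tx, c in counts.items():
            rows.append((sample, tx, tx.split(".")[0], c, condition))
    return TruthTable(pd.DataFrame(rows, columns=TruthTable.COLUMNS))


class TestAbsLogFc:
    @pytest.mark.parametrize(
        "true,est,expected",
        [(0, 0, 0.0), (1, 3, 1.0), (0, 1023, 10.0), (7, 7, 0.0)],
    )
    def test_worked_examples(self, true, est, expected):
        assert abs_log_fc(true, est) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            abs_log_fc(-1, 2)

    def test_accuracy_table_alignment_and_sign(self):
        table = accuracy_table(
            pd.Series({"a": 3.0, "b": 0.0}), pd.Series({"a": 1.0, "c": 7.0})
        )
        assert table.loc["a", "logfc"] == pytest.approx(-1.0)
        assert table.loc["c", "true_count"] == 0.0
        assert (table["abs_logfc"] >= 0).all()


class TestExpressedFilter:
    def annotation(self):
        return AnnotationSet.from_transcripts(
            [
                TranscriptModel("g1.t1", "g1", "c", "+", ((0, 10),)),
                TranscriptModel("g1.t2", "g1", "c", "+", ((0, 5),)),
                TranscriptModel("g2.t1", "g2", "c", "+", ((0, 10),)),
                TranscriptModel("g2.t2", "g2", "c", "+", ((0, 5),)),
            ]
        )

    def test_caption_rule(self):
        truth = make_truth({"s1": {"g1.t1": 5, "g1.t2": 0, "g2.t1": 0, "g2.t2": 0}})
        kept = expressed_filter(truth, self.annotation())
        assert kept == ["g1.t1", "g1.t2"]  # sibling of expressed isoform kept

    def test_all_expressed_kept(self):
        truth = make_truth({"s1": {"g1.t1": 5, "g1.t2": 3, "g2.t1": 1, "g2.t2": 2}})
        assert len(expressed_filter(truth, self.annotation())) == 4


class TestPercentileCurve:
    def test_all_zero_values(self):
        curve = percentile_curve([0.0, 0.0, 0.0])
        assert (curve["value"] == 0).all()

    def test_nearest_rank_worked_example(self):
        curve = percentile_curve([0, 0, 1, 3]).set_index("percentile")["value"]
        assert curve[50] == 0
        assert curve[100] == 3

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            percentile_curve([])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=200))
    def test_matches_brute_force_nearest_rank_and_monotone(self, values):
        curve = percentile_curve(values)
        ordered = sorted(values)
        for x, y in zip(curve["percentile"], curve["value"]):
            rank = max(1, int(np.ceil(x / 100 * len(ordered))))
            assert y == ordered[rank - 1]
        assert (np.diff(curve["value"]) >= 0).all()


class TestSpearman:
    def test_identity_and_reversal(self):
        truth = make_truth({"s1": {"t1": 1, "t2": 2, "t3": 3, "t4": 4}})
        quant = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0]}, index=["t1", "t2", "t3", "t4"])
        assert spearman_per_sample(truth, quant)["s1"] == pytest.approx(1.0)
        quant_rev = pd.DataFrame({"s1": [4.0, 3.0, 2.0, 1.0]}, index=["t1", "t2", "t3", "t4"])
        assert spearman_per_sample(truth, quant_rev)["s1"] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # d^2 = (0,1,1,0) -> rho = 1 - 6*2/(4*15) = 0.8
        truth = make_truth({"s1": {"t1": 1, "t2": 2, "t3": 3, "t4": 4}})
        quant = pd.DataFrame({"s1": [1.0, 3.0, 2.0, 4.0]}, index=["t1", "t2", "t3", "t4"])
        assert spearman_per_sample(truth, quant)["s1"] == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        truth = make_truth({"s1": {"t1": 1, "t2": 2}})
        quant = pd.DataFrame({"s1": [5.0, 5.0]}, index=["t1", "t2"])
        with pytest.warns(UserWarning, match="undefined"):
            rho = spearman_per_sample(truth, quant)
        assert np.isnan(rho["s1"])


class TestClusterMethods:
    def test_identical_vectors_merge_first(self):
        idx = [f"t{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        a = pd.Series(rng.random(20), index=idx)
        c = pd.Series(rng.random(20), index=idx)
        result = cluster_methods({"A": a, "B": a.copy(), "C": c})
        assert result.distance.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
        first_merge = set(result.linkage[0, :2].astype(int))
        assert {result.labels[i] for i in first_merge} == {"A", "B"}

    def test_anticorrelated_distance_is_two(self):
        x = pd.Series([1.0, 2.0, 3.0])
        result = cluster_methods({"A": x, "B": -x})
        assert result.distance.loc["A", "B"] == pytest.approx(2.0)

    def test_fewer_than_two_methods_rejected(self):
        with pytest.raises(ValueError):
            cluster_methods({"A": pd.Series([1.0, 2.0])})

    def test_newick_contains_all_labels(self):
        rng = np.random.default_rng(1)
        vectors = {m: pd.Series(rng.random(30)) for m in ["truth", "nrp", "unamb"]}
        newick = cluster_methods(vectors).to_newick()
        assert newick.endswith(";")
        for label in vectors:
            assert label in newick


class TestMeanAbsLogfcByBin:
    def test_bins_below_support_threshold_omitted_and_means_correct(self):
        # g1: 2 expressed isoforms (bin 2, 3 transcripts); g2: bin 1 but only 2 tx
        truth = make_truth(
            {
                "s1": {"g1.t1": 5, "g1.t2": 3, "g1.t3": 0, "g2.t1": 4, "g2.t2": 0},
                "s2": {"g1.t1": 5, "g1.t2": 0, "g1.t3": 0, "g2.t1": 4, "g2.t2": 0},
            }
        )
        ann = AnnotationSet.from_transcripts(
            [
                TranscriptModel(tx, tx.split(".")[0], "c", "+", ((0, 10),))
                for tx in ["g1.t1", "g1.t2", "g1.t3", "g2.t1", "g2.t2"]
            ]
        )
        abs_logfc = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 10.0, 20.0], "s2": [1.0, 2.0, 3.0, 10.0, 20.0]},
            index=["g1.t1", "g1.t2", "g1.t3", "g2.t1", "g2.t2"],
        )
        out = mean_abslogfc_by_bin(abs_logfc, truth, ann, min_transcripts=3)
        assert list(out["n_expressed_isoforms"]) == [2]  # g2's bin-1 has only 2 tx
        assert out["mean_abs_logfc"].iloc[0] == pytest.approx(2.0)

    def test_exact_estimates_give_zero_means(self, toy, toy_truth):
        mat = toy_truth.truth.counts_matrix()
        zero = pd.DataFrame(0.0, index=mat.index, columns=mat.columns)
        out = mean_abslogfc_by_bin(
            accuracy_frame(mat, mat), toy_truth.truth, toy.annotation, min_transcripts=1
        )
        assert (out["mean_abs_logfc"] == 0).all()
        del zero


def accuracy_frame(true_mat, est_mat):
    return pd.DataFrame(
        {s: accuracy_table(true_mat[s], est_mat[s])["abs_logfc"] for s in true_mat.columns}
    )


class TestDiscordantSet:
    def test_whole_population_when_n_equals_size(self):
        values = pd.Series({"a": 1.0, "b": 2.0})
        assert set(discordant_set(values, 2)) == {"a", "b"}

    def test_oversized_n_returns_all_with_warning(self):
        values = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.warns(UserWarning):
            assert len(discordant_set(values, 2000)) == 2

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(2)
        values = pd.Series(rng.random(50), index=[f"t{i:02d}" for i in range(50)])
        top = discordant_set(values.to_frame("s1"), 10)
        oracle = sorted(values.index, key=lambda t: (-values[t], t))[:10]
        assert top == oracle

    def test_default_n_is_2000(self):
        import inspect

        assert inspect.signature(discordant_set).parameters["n"].default == 2000


class TestKsEnrichment:
    def synthetic_table(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "length": rng.lognormal(7, 1, n),
                "exon_count": rng.poisson(8, n) + 1,
                "sibling_count": rng.poisson(2, n),
                "hexamer_entropy": rng.normal(9, 0.5, n),
                "compression_complexity": rng.uniform(0.2, 0.4, n),
            },
            index=[f"t{i:05d}" for i in range(n)],
        )

    def test_foreground_equals_background_gives_zero_statistic(self):
        table = self.synthetic_table(200)
        report = ks_enrichment(table.index, table)
        assert (report["statistic"] == 0).all()
        assert (report["pvalue_bonferroni"] >= report["pvalue"]).all()

    def test_planted_length_bias_flagged_only_for_length(self):
        table = self.synthetic_table()
        foreground = table["length"].nlargest(100).index
        report = ks_enrichment(foreground, table)
        assert report.loc["length", "significant"]
        assert not report.loc["hexamer_entropy", "significant"]

    def test_tiny_foreground_rejected(self):
        table = self.synthetic_table(50)
        with pytest.raises(ValueError):
            ks_enrichment([table.index[0]], table)

    def test_bonferroni_factor_scales_with_methods(self):
        table = self.synthetic_table(300, seed=1)
        fg = table.index[:30]
        one = ks_enrichment(fg, table, n_methods=1)
        many = ks_enrichment(fg, table, n_methods=7)
        ratio = many["pvalue_bonferroni"] / one["pvalue_bonferroni"]
        unsat = one["pvalue_bonferroni"] < 1 / 7
        assert np.allclose(ratio[unsat], 7.0)


class TestDeConcordance:
    def test_jaccard_identity_is_one(self):
        ranking = [f"t{i}" for i in range(100)]
        curve = jaccard_topn_curve(ranking, list(ranking))
        assert (curve["jaccard"] == 1.0).all()

    def test_jaccard_disjoint_is_zero(self):
        curve = jaccard_topn_curve(["a", "b"], ["c", "d"], n_grid=[1, 2])
        assert (curve["jaccard"] == 0.0).all()

    def test_jaccard_worked_example(self):
        curve = jaccard_topn_curve(
            ["a", "b", "c", "x"], ["b", "c", "d", "x"], n_grid=[3]
        )
        assert curve["jaccard"].iloc[0] == pytest.approx(0.5)

    def test_jaccard_truncates_oversized_n(self):
        with pytest.warns(UserWarning, match="truncated"):
            curve = jaccard_topn_curve(["a"], ["a"], n_grid=[5])
        assert curve["jaccard"].iloc[0] == 1.0

    def test_qvalue_count_curve(self):
        de = pd.DataFrame({"qvalue": [0.01, 0.04, 0.2], "logfc": [1, 2, 3]},
                          index=["a", "b", "c"])
        curve = qvalue_count_curve(de, [0.005, 0.05, 0.5]).set_index("cutoff")["n_below"]
        assert curve[0.005] == 0
        assert curve[0.05] == 2
        assert curve[0.5] == 3
        assert (np.diff(curve.values) >= 0).all()

    def test_null_fdr_bound_cases(self):
        de = pd.DataFrame(
            {"qvalue": [0.01] * 10 + [0.9] * 5, "logfc": 0.0},
            index=[f"t{i}" for i in range(15)],
        )
        null_ids = [f"t{i}" for i in range(5)]  # 5 of the 10 rejected are null
        curve = null_fdr_bound(de, null_ids, [0.05]).iloc[0]
        assert curve["fdr_lower_bound"] == pytest.approx(0.5)
        empty = null_fdr_bound(de, [], [0.05]).iloc[0]
        assert empty["fdr_lower_bound"] == 0.0
        none_rejected = null_fdr_bound(de, null_ids, [0.001]).iloc[0]
        assert none_rejected["fdr_lower_bound"] == 0.0

    def test_null_fdr_bound_all_null(self):
        de = pd.DataFrame({"qvalue": [0.01, 0.01], "logfc": 0.0}, index=["a", "b"])
        curve = null_fdr_bound(de, ["a", "b"], [0.05]).iloc[0]
        assert curve["fdr_lower_bound"] == 1.0


class TestSimpleDe:
    def counts(self, shift):
        rng = np.random.default_rng(3)
        base = rng.poisson(100, size=(50, 12)).astype(float)
        base[0, 6:] *= shift
        cols = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        frame = pd.DataFrame(base, index=[f"t{i:02d}" for i in range(50)], columns=cols)
        condition = pd.Series({c: c[0] for c in cols})
        return frame, condition

    def test_identical_conditions_give_large_q(self):
        frame, condition = self.counts(shift=1)
        frame.loc["t01"] = 10.0  # constant across all replicates
        de = simple_de(frame, condition)
        assert de.loc["t01", "pvalue"] == 1.0
        assert de["qvalue"].between(0, 1).all()

    def test_large_shift_ranks_first(self):
        frame, condition = self.counts(shift=100)
        de = simple_de(frame, condition)
        assert de_ranking(de)[0] == "t00"

    def test_requires_two_replicates_per_condition(self):
        frame, _ = self.counts(shift=1)
        condition = pd.Series(
            {c: ("A" if c != "B5" else "B") for c in frame.columns}
        )
        with pytest.raises(ValueError, match="two replicates"):
            simple_de(frame, condition)

    def test_ties_broken_by_abs_logfc_then_id(self):
        de = pd.DataFrame(
            {"qvalue": [0.0, 0.0, 0.0], "logfc": [2.0, -5.0, 2.0]},
            index=["tb", "ta", "tc"],
        )
        assert de_ranking(de) == ["ta", "tb", "tc"]


class TestReadDeTable:
    def test_round_trip_and_ranking(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text(
            "transcript_id\tqvalue\tlogfc\nt1\t0.0\t5.0\nt2\t0.0\t2.0\nt3\t0.5\t9.0\n"
        )
        de = read_de_table(path)
        assert len(de) == 3
        assert de_ranking(de) == ["t1", "t2", "t3"]

    def test_q_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("transcript_id\tqvalue\nt1\t1.5\n")
        with pytest.raises(ValidationError):
            read_de_table(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("id\tq\nt1\t0.5\n")
        with pytest.raises(DialectError):
            read_de_table(path)
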