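import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import markerseg as m
from markerseg.errors import UndefinedStatisticError, ValidationError

from conftest import make_transcripts


def cell_with_n_transcripts(n, cell="c1", qv=20.0, gene="KRT5"):
    return [(float(i), 0.0, gene, qv, cell) for i in range(n)]


class TestQcFilter:
    def test_cell_with_exactly_ten_qualifying_transcripts_kept(self):
        tr = make_transcripts(cell_with_n_transcripts(10))
        out, kept = m.qc_filter(tr)
        assert kept == ["c1"]
        assert (out["cell_id"] == "c1").sum() == 10

    def test_cell_with_nine_transcripts_dropped(self):
        tr = make_transcripts(cell_with_n_transcripts(9))
        out, kept = m.qc_filter(tr)
        assert kept == []
        assert (out["cell_id"] == m.UNASSIGNED).all()

    def test_quality_filter_applied_before_count_filter(self):
        # 12 transcripts, 3 below QV 20 -> 9 qualify -> cell excluded
        rows = cell_with_n_transcripts(9, qv=25.0) + cell_with_n_transcripts(3, qv=19.0)
        tr = make_transcripts(rows)
        out, kept = m.qc_filter(tr)
        assert kept == []
        assert len(out) == 9  # low-QV rows dropped entirely

    def test_idempotent(self, gland):
        transcripts, _, _ = gland
        once, kept1 = m.qc_filter(transcripts)
        twice, kept2 = m.qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert kept1 == kept2


class TestBuildCounts:
    def test_empty_table(self):
        cm = m.build_counts(make_transcripts([]))
        assert cm.total == 0

    def test_single_entry(self):
        cm = m.build_counts(make_transcripts(cell_with_n_transcripts(5)))
        assert cm.total == 5
        assert cm.counts[0, cm.genes.index("KRT5")] == 5

    def test_total_equals_kept_transcripts(self, gland):
        transcripts, _, _ = gland
        kept, _ = m.qc_filter(transcripts)
        cm = m.build_counts(kept)
        assert cm.total == (kept["cell_id"] != m.UNASSIGNED).sum()


class TestNormalize:
    def test_single_cell_direct_arithmetic(self):
        cm = m.CountMatrix(sp.csr_matrix(np.array([[4, 0]])), ["c1"], ["g1", "g2"])
        norm = m.normalize(cm)
        assert norm.values[0, 0] == pytest.approx(np.log1p(4.0))
        assert norm.values[0, 1] == 0.0
        assert norm.target_sum == 4.0

    def test_identical_cells_identical_vectors(self):
        cm = m.CountMatrix(
            sp.csr_matrix(np.array([[3, 7], [3, 7]])), ["c1", "c2"], ["g1", "g2"]
        )
        norm = m.normalize(cm)
        np.testing.assert_allclose(norm.values[0], norm.values[1])

    def test_zero_gene_column_stays_zero(self):
        cm = m.CountMatrix(
            sp.csr_matrix(np.array([[5, 0], [9, 0]])), ["c1", "c2"], ["g1", "g2"]
        )
        norm = m.normalize(cm)
        assert (norm.values[:, 1] == 0).all()

    def test_all_zero_matrix_rejected(self):
        cm = m.CountMatrix(sp.csr_matrix((2, 2), dtype=np.int64), ["a", "b"], ["g", "h"])
        with pytest.raises(ValidationError):
            m.normalize(cm)

    def test_scaled_totals_equal_median(self, gland):
        transcripts, _, _ = gland
        kept, _ = m.qc_filter(transcripts)
        cm = m.build_counts(kept)
        norm = m.normalize(cm)
        pre_log_totals = np.expm1(norm.values).sum(axis=1)
        np.testing.assert_allclose(pre_log_totals, norm.target_sum, rtol=1e-9)


class TestGeneSetScore:
    def norm_fixture(self, values, genes):
        return m.NormalizedMatrix(
            np.asarray(values, dtype=float), [f"c{i}" for i in range(len(values))],
            list(genes), target_sum=10.0)

    def test_all_zero_cell_scores_zero(self):
        norm = self.norm_fixture([[0, 0, 0, 0, 0]], m.SEBOGENESIS_GENES)
        assert m.gene_set_score(norm)["c0"] == 0.0

    def test_unit_values_score_one(self):
        norm = self.norm_fixture([[1, 1, 1, 1, 1]], m.SEBOGENESIS_GENES)
        assert m.gene_set_score(norm)["c0"] == pytest.approx(1.0)

    def test_invariant_to_gene_order_and_absent_genes(self):
        norm = self.norm_fixture([[0.5, 1.5, 2.5, 0.0, 3.0]], m.SEBOGENESIS_GENES)
        base = m.gene_set_score(norm, m.GeneSetScoreSpec("s", m.SEBOGENESIS_GENES))
        shuffled = m.gene_set_score(norm, m.GeneSetScoreSpec("s", m.SEBOGENESIS_GENES[::-1]))
        with pytest.warns(UserWarning, match="absent"):
            padded = m.gene_set_score(
                norm, m.GeneSetScoreSpec("s", m.SEBOGENESIS_GENES + ("NOT_A_GENE",)))
        assert base["c0"] == shuffled["c0"] == padded["c0"]

    def test_no_genes_present_is_an_error(self):
        norm = self.norm_fixture([[1.0]], ["KRT5"])
        with pytest.raises(ValidationError):
            m.gene_set_score(norm, m.GeneSetScoreSpec("s", ("FASN",)))

    def test_sebocytes_outscore_basal_cells(self, gland):
        transcripts, _, truth = gland
        kept, _ = m.qc_filter(transcripts)
        norm = m.normalize(m.build_counts(kept))
        scores = m.gene_set_score(norm)
        types = pd.Series({c: truth.cell_types[c] for c in scores.index})
        assert scores[types == "sebocyte"].mean() > scores[types == "basal"].mean()


class TestExpressionRatio:
    def norm_fixture(self):
        values = np.array(
            [[2.0, 1.0], [1.0, 2.0], [2.0, 1.0], [1.0, 2.0]], dtype=float)
        return m.NormalizedMatrix(values, ["a1", "a2", "b1", "b2"],
                                  ["FABP5", "CRABP2"], target_sum=10.0)

    def test_equal_means_give_ratio_one(self):
        norm = self.norm_fixture()
        groups = pd.Series({"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"})
        ratios = m.expression_ratio(norm, groups)
        assert ratios["g1"] == pytest.approx(1.0)

    def test_zero_denominator_uses_pseudocount(self):
        values = np.array([[3.0, 0.0]])
        norm = m.NormalizedMatrix(values, ["c0"], ["FABP5", "CRABP2"], 10.0)
        ratios = m.expression_ratio(norm, pd.Series({"c0": "g"}), delta=0.01)
        assert ratios["g"] == pytest.approx((3.0 + 0.01) / 0.01)

    def test_identical_groups_identical_ratios(self):
        norm = self.norm_fixture()
        groups = pd.Series({"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"})
        ratios = m.expression_ratio(norm, groups)
        assert ratios["g1"] == pytest.approx(ratios["g2"])


class TestCompareMethods:
    def rows(self, groups):
        frames = []
        for name, values in groups.items():
            frames.append(pd.DataFrame({
                "method": name,
                "cell_id": [f"{name}_{i}" for i in range(len(values))],
                "metric": values}))
        return pd.concat(frames, ignore_index=True)

    def test_identical_groups_no_difference(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        comp = m.compare_methods(self.rows({"a": vals, "b": vals}), metrics=["metric"])
        pair = comp.pairwise.iloc[0]
        assert pair["mean_diff"] == pytest.approx(0.0)
        assert pair["p_adj"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        groups = {
            "a": rng.normal(10.0, 2.0, 5),
            "b": rng.normal(12.0, 2.0, 5),
            "c": rng.normal(15.0, 2.0, 5),
        }
        rows = self.rows(groups)
        comp = m.compare_methods(rows, metrics=["metric"])
        ref = pingouin.pairwise_tukey(data=rows, dv="metric", between="method")
        for _, r in ref.iterrows():
            ours = comp.pairwise[
                (comp.pairwise["group1"] == r["A"]) & (comp.pairwise["group2"] == r["B"])
            ].iloc[0]
            assert abs(ours["mean_diff"]) == pytest.approx(abs(r["diff"]), abs=1e-6)
            assert ours["p_adj"] == pytest.approx(r["p_tukey"], abs=1e-6)
        import scipy.stats

        f_ref, p_ref = scipy.stats.f_oneway(*groups.values())
        anova = comp.anova.iloc[0]
        assert anova["F"] == pytest.approx(f_ref, rel=1e-9)
        assert anova["p"] == pytest.approx(p_ref, rel=1e-9)

    def test_huge_separation_has_tiny_p(self):
        rng = np.random.default_rng(1)
        comp = m.compare_methods(
            self.rows({"a": rng.normal(0, 1, 50), "b": rng.normal(100, 1, 50)}),
            metrics=["metric"])
        assert comp.pairwise.iloc[0]["p_adj"] < 1e-10

    def test_all_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            m.compare_methods(
                self.rows({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}),
                metrics=["metric"])

    def test_duplicate_method_cell_pair_rejected(self):
        rows = self.rows({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        rows.loc[1, "cell_id"] = rows.loc[0, "cell_id"]
        with pytest.raises(ValidationError):
            m.compare_methods(rows, metrics=["metric"])


class TestMisassignment:
    def truth(self, types, true_cells):
        seg = m.Segmentation([])
        return m.GlandTruth(
            segmentation=seg, cell_types=types,
            true_cell=pd.Series(true_cells,
                                index=pd.Index([f"t{i}" for i in range(len(true_cells))],
                                               name="transcript_id")))

    def test_perfect_assignment_scores_zero(self):
        tr = make_transcripts([(0, 0, "KRT79", 30, "b1"), (1, 1, "KRT79", 30, "s1")])
        truth = self.truth({"b1": "basal", "s1": "sebocyte"}, ["b1", "s1"])
        assert m.misassignment_rate(tr, truth, "KRT79", "basal") == 0.0

    def test_all_wrong_scores_one(self):
        tr = make_transcripts([(0, 0, "KRT79", 30, "b1"), (1, 1, "KRT79", 30, "b1")])
        truth = self.truth({"b1": "basal", "s1": "sebocyte"}, ["s1", "s1"])
        assert m.misassignment_rate(tr, truth, "KRT79", "basal") == 1.0

    def test_enumerated_fixture(self):
        # 10 assigned transcripts, 3 of them wrongly credited to basal cells
        rows, true_cells = [], []
        for i in range(7):
            rows.append((i, 0, "KRT79", 30, "s1"))
            true_cells.append("s1")
        for i in range(3):
            rows.append((i, 1, "KRT79", 30, "b1"))
            true_cells.append("s1")
        tr = make_transcripts(rows)
        truth = self.truth({"b1": "basal", "s1": "sebocyte"}, true_cells)
        assert m.misassignment_rate(tr, truth, "KRT79", "basal") == pytest.approx(0.3)

    def test_absent_gene_rejected(self):
        tr = make_transcripts([(0, 0, "KRT79", 30, "b1")])
        truth = self.truth({"b1": "basal"}, ["b1"])
        with pytest.raises(ValidationError):
            m.misassignment_rate(tr, truth, "NOT_A_GENE", "basal")
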