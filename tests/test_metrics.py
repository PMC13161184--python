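import numpy as np
import pandas as pd
import pytest

from helpers import ed2_enumeration, ols_closed_form
from conftest import random_tree

from orchidedge.errors import (
    DegeneratePredictorError,
    InsufficientDataError,
    ValidationError,
)
from orchidedge.io import AssessmentTable, read_newick
from orchidedge.metrics import (
    ed2_scores,
    ed_threat_regression,
    edge2_pipeline,
    equal_splits_ed,
    fair_proportion_ed,
    rank_top_n,
    total_pd,
)
from orchidedge.risk import build_risk_model


def make_table(categories: dict[str, str]) -> AssessmentTable:
    frame = pd.DataFrame(
        {
            "category_hk": list(categories.values()),
            "category_cn": ["LC"] * len(categories),
            "habit": 1.0,
            "habitats": [frozenset({"lowland_forest"})] * len(categories),
            "mating": 1.0,
            "trade": 0,
        },
        index=pd.Index(list(categories), name="taxon"),
    )
    return AssessmentTable(frame)


class TestTotalPd:
    def test_three_tip_example(self, three_tip_tree):
        assert total_pd(three_tip_tree) == pytest.approx(5.0)

    def test_star_tree(self):
        assert total_pd(read_newick("(A:3,B:3,C:3,D:3);")) == pytest.approx(12.0)


class TestFairProportionEd:
    def test_cherry_symmetry(self):
        ed = fair_proportion_ed(read_newick("(A:1,B:1);"))
        assert ed["A"] == ed["B"] == pytest.approx(1.0)

    def test_hand_worked_shares(self, three_tip_tree):
        ed = fair_proportion_ed(three_tip_tree)
        assert ed["A"] == pytest.approx(1.5)
        assert ed["B"] == pytest.approx(1.5)
        assert ed["C"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n_tips", [5, 20, 50])
    def test_conservation_sum_equals_pd(self, seed, n_tips):
        tree = random_tree(np.random.default_rng(seed), n_tips)
        assert fair_proportion_ed(tree).sum() == pytest.approx(
            total_pd(tree), rel=1e-9
        )

    def test_equal_splits_variant_on_known_tree(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        es = equal_splits_ed(tree)
        # D: 3 + 0; C: 2 + 1/2; A,B: 1 + 1/2 + 1/4
        assert es["D"] == pytest.approx(3.0)
        assert es["C"] == pytest.approx(2.5)
        assert es["A"] == es["B"] == pytest.approx(1.75)


class TestEd2Scores:
    def test_all_survive_gives_tbl(self, three_tip_tree):
        ed2 = ed2_scores(
            three_tip_tree, {"A": 1e-12, "B": 1e-12, "C": 1e-12}
        )
        assert ed2["A"] == pytest.approx(1.0, abs=1e-9)
        assert ed2["C"] == pytest.approx(2.0, abs=1e-9)

    def test_all_extinct_gives_depth(self, three_tip_tree):
        ed2 = ed2_scores(three_tip_tree, {"A": 1.0, "B": 1.0, "C": 1.0})
        depth = three_tip_tree.edge_arrays()["depth"]
        np.testing.assert_allclose(ed2.values, depth)

    def test_hand_worked_value(self, three_tip_tree):
        ed2 = ed2_scores(three_tip_tree, {"A": 0.3, "B": 0.5, "C": 0.7})
        assert ed2["A"] == pytest.approx(1 + 1 * 0.5)
        assert ed2["B"] == pytest.approx(1 + 1 * 0.3)
        assert ed2["C"] == pytest.approx(2.0)

    def test_missing_tip_rejected(self, three_tip_tree):
        with pytest.raises(ValidationError, match="C"):
            ed2_scores(three_tip_tree, {"A": 0.5, "B": 0.5})

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(2, 7)))
        pext = {t: float(rng.uniform(0.01, 0.99)) for t in tree.tip_labels}
        expected = ed2_enumeration(tree, pext)
        ed2 = ed2_scores(tree, pext)
        for tip, value in expected.items():
            assert ed2[tip] == pytest.approx(value, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_tbl_and_depth(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_tree(rng, 15)
        pext = {t: float(rng.uniform(0.001, 1.0)) for t in tree.tip_labels}
        arrays = tree.edge_arrays()
        ed2 = ed2_scores(tree, pext).values
        assert np.all(ed2 >= arrays["tbl"] - 1e-12)
        assert np.all(ed2 <= arrays["depth"] + 1e-12)


class TestEdge2Pipeline:
    def test_two_tip_direct_product(self):
        tree = read_newick("(A:1,B:1);")
        table = make_table({"A": "CR", "B": "LC"})
        model = build_risk_model(1001, seed=0)
        result = edge2_pipeline(tree, table, "hk", model, n_draws=200, seed=1)
        # no internal edges: ED2 is exactly the terminal branch, so
        # EDGE2 reduces to the raw GE2 draw and stays in its interval
        np.testing.assert_allclose(result.ed2_draws, 1.0)
        a = result.taxa.index("A")
        b = result.taxa.index("B")
        assert np.all((result.edge2_draws[:, a] >= 0.69436) & (result.edge2_draws[:, a] <= 0.99999))
        assert np.all((result.edge2_draws[:, b] >= 0.00174) & (result.edge2_draws[:, b] <= 0.09337))

    def test_determinism(self, small_bundle):
        model = build_risk_model(501, seed=5)
        a = edge2_pipeline(small_bundle.tree, small_bundle.assessments, "hk", model, 100, seed=9)
        b = edge2_pipeline(small_bundle.tree, small_bundle.assessments, "hk", model, 100, seed=9)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_edge2_below_ed2(self, small_bundle):
        model = build_risk_model(501, seed=5)
        result = edge2_pipeline(small_bundle.tree, small_bundle.assessments, "hk", model, 100, seed=9)
        assert np.all(result.edge2_draws < result.ed2_draws)
        assert np.all(result.edge2_draws > 0)

    def test_category_monotonicity(self):
        tree = read_newick("((A:1,B:2):1,(C:1.5,D:0.5):2);")
        model = build_risk_model(1001, seed=0)
        medians = {}
        for cat in ("LC", "NT", "VU", "EN", "CR"):
            table = make_table({"A": cat, "B": "LC", "C": "VU", "D": "EN"})
            res = edge2_pipeline(tree, table, "hk", model, n_draws=500, seed=42)
            medians[cat] = res.summary.set_index("taxon").at["A", "edge2_median"]
        values = [medians[c] for c in ("LC", "NT", "VU", "EN", "CR")]
        assert values == sorted(values)

    def test_missing_tip_named(self, three_tip_tree):
        table = make_table({"A": "LC", "B": "LC"})
        with pytest.raises(ValidationError, match="C"):
            edge2_pipeline(three_tip_tree, table, "hk", build_risk_model(101, seed=0), 10, seed=0)


class TestRankTopN:
    def _result(self, medians, ed2_medians):
        from orchidedge.metrics import Edge2Result

        taxa = sorted(medians)
        summary = pd.DataFrame(
            {
                "taxon": taxa,
                "category": "LC",
                "ed2_median": [ed2_medians[t] for t in taxa],
                "ed2_iqr": 0.0,
                "edge2_median": [medians[t] for t in taxa],
                "edge2_iqr": 0.0,
                "rank": 0,
            }
        )
        return Edge2Result(taxa, ["LC"] * len(taxa), np.zeros((1, len(taxa))), np.zeros((1, len(taxa))), summary)

    def test_n_larger_than_taxa(self):
        result = self._result({"A": 1.0, "B": 2.0}, {"A": 1.0, "B": 2.0})
        assert len(rank_top_n(result, 10)) == 2

    def test_tie_broken_by_ed2(self):
        result = self._result({"A": 1.0, "B": 1.0}, {"A": 0.5, "B": 0.9})
        top = rank_top_n(result, 2)
        assert list(top["taxon"]) == ["B", "A"]

    def test_dominant_taxon_ranks_first(self, small_bundle):
        # make one taxon CR with the longest pendant branch: it must win
        table = small_bundle.assessments.df.copy()
        arrays = small_bundle.tree.edge_arrays()
        best = arrays["tips"][int(np.argmax(arrays["tbl"]))]
        table["category_hk"] = "LC"
        table.loc[best, "category_hk"] = "CR"
        result = edge2_pipeline(
            small_bundle.tree, AssessmentTable(table), "hk",
            build_risk_model(1001, seed=0), 500, seed=1,
        )
        assert rank_top_n(result, 1)["taxon"].iloc[0] == best


class TestEdThreatRegression:
    def test_perfect_line(self):
        table = make_table({t: c for t, c in zip("ABCDE", ["LC", "NT", "VU", "EN", "CR"])})
        ed = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("ABCDE"))
        result = ed_threat_regression(ed, table, "hk")
        assert result.r2 == pytest.approx(1.0)
        assert result.pvalue < 1e-6

    def test_constant_ed(self):
        table = make_table({t: c for t, c in zip("ABCDE", ["LC", "NT", "VU", "EN", "CR"])})
        ed = pd.Series([2.0] * 5, index=list("ABCDE"))
        result = ed_threat_regression(ed, table, "hk")
        assert result.slope == 0.0
        assert result.r2 == 0.0

    def test_hand_ols(self):
        table = make_table({t: c for t, c in zip("ABCDE", ["LC", "NT", "VU", "EN", "CR"])})
        y = [2.0, 1.0, 4.0, 3.0, 6.0]
        ed = pd.Series(y, index=list("ABCDE"))
        result = ed_threat_regression(ed, table, "hk")
        slope, intercept, r2 = ols_closed_form([0, 1, 2, 3, 4], y)
        assert result.slope == pytest.approx(slope)
        assert result.intercept == pytest.approx(intercept)
        assert result.r2 == pytest.approx(r2)
        assert result.adj_r2 == pytest.approx(1 - (1 - r2) * 4 / 3)

    def test_unweighted_categories_excluded(self):
        cats = {"A": "LC", "B": "NT", "C": "VU", "D": "RE", "E": "DD"}
        table = make_table(cats)
        ed = pd.Series([1.0, 2.0, 3.0, 100.0, 200.0], index=list("ABCDE"))
        result = ed_threat_regression(ed, table, "hk")
        assert result.n == 3

    def test_insufficient_data(self):
        table = make_table({"A": "LC", "B": "RE", "C": "DD"})
        ed = pd.Series([1.0, 2.0, 3.0], index=list("ABC"))
        with pytest.raises(InsufficientDataError):
            ed_threat_regression(ed, table, "hk")

    def test_degenerate_predictor(self):
        table = make_table({"A": "LC", "B": "LC", "C": "LC"})
        ed = pd.Series([1.0, 2.0, 3.0], index=list("ABC"))
        with pytest.raises(DegeneratePredictorError):
            ed_threat_regression(ed, table, "hk")
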