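import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dysbiome.core_tables import TaxonomyMap
from dysbiome.design import Comparison
from dysbiome.differential_abundance import DaResult
from dysbiome.summary import (cluster_with_support, fit_au, fold_difference,
                              genus_presence, linkage_to_newick)
from dysbiome.summary import test_fold_bias as fold_bias_ttest


class TestFoldDifference:
    @pytest.mark.parametrize("n1,n2,fd,plot", [
        (10, 5, 2.0, 2.0),
        (5, 10, 0.5, -2.0),
        (7, 7, 1.0, 1.0),
    ])
    def test_worked_examples(self, n1, n2, fd, plot):
        rec = fold_difference(n1, n2)
        assert rec.fold_difference == pytest.approx(fd)
        assert rec.plot_value == pytest.approx(plot)

    def test_zero_denominator_substituted_and_flagged(self):
        rec = fold_difference(8, 0)
        assert rec.fold_difference == pytest.approx(8.0)
        assert rec.zero_denominator and not rec.undefined

    def test_zero_denominator_exclude_policy(self):
        rec = fold_difference(8, 0, zero_policy="exclude")
        assert rec.undefined

    def test_both_zero_undefined(self):
        rec = fold_difference(0, 0)
        assert rec.undefined and np.isnan(rec.fold_difference)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(1, 500), st.integers(1, 500))
    def test_reciprocal_product_is_one(self, n1, n2):
        a = fold_difference(n1, n2).fold_difference
        b = fold_difference(n2, n1).fold_difference
        assert a * b == pytest.approx(1.0)


class TestFoldBias:
    def test_closed_form_t(self):
        recs = [fold_difference(int(v * 10), 10) for v in (1.5, 2.5, 2.0)]
        out = fold_bias_ttest({"d": recs})
        assert out.loc["d", "t_stat"] == pytest.approx(3.4641, abs=1e-3)
        assert out.loc["d", "p_value"] == pytest.approx(0.0742, abs=1e-3)

    def test_exact_null_gives_p_one(self):
        recs = [fold_difference(5, 5), fold_difference(9, 9),
                fold_difference(3, 3)]
        out = fold_bias_ttest({"d": recs})
        assert out.loc["d", "p_value"] == 1.0
        assert out.loc["d", "t_stat"] == 0.0

    def test_zero_variance_off_null_degenerate(self):
        recs = [fold_difference(10, 5), fold_difference(20, 10)]
        out = fold_bias_ttest({"d": recs})
        assert out.loc["d", "degenerate"]
        assert out.loc["d", "p_value"] == 0.0

    def test_holm_applied_across_diseases(self):
        strong = [fold_difference(n, 5) for n in (30, 32, 28, 31)]
        weak = [fold_difference(n, 10) for n in (11, 9, 12, 10)]
        out = fold_bias_ttest({"a": strong, "b": weak})
        assert np.all(out["p_holm"] >= out["p_value"] - 1e-15)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            fold_bias_ttest({"d": [fold_difference(2, 1)]})


def _result(otu_ids, sig_neg=(), sig_pos=()):
    n = len(otu_ids)
    lfc = np.zeros(n)
    padj = np.ones(n)
    for i, o in enumerate(otu_ids):
        if o in sig_neg:
            lfc[i], padj[i] = -1.0, 0.001
        elif o in sig_pos:
            lfc[i], padj[i] = 1.0, 0.001
    se = np.ones(n)
    return DaResult(list(otu_ids), np.ones(n), lfc, se, lfc / se,
                    padj, padj)


@pytest.fixture()
def taxonomy3():
    return TaxonomyMap.from_lineage_strings({
        "o1": "k__B; p__; c__; o__; f__; g__Prevotella; s__",
        "o2": "k__B; p__; c__; o__; f__; g__Prevotella; s__",
        "o3": "k__B; p__; c__; o__; f__; g__Bacteroides; s__",
        "o4": "k__B; p__; c__; o__; f__; g__; s__",
    })


class TestGenusPresence:
    def make_inputs(self, taxonomy3):
        otus = ["o1", "o2", "o3", "o4"]
        comps = [Comparison(f"d_c{i}", [f"h{i}"], [f"x{i}"], "d", "p")
                 for i in range(9)]
        results = {}
        for i, c in enumerate(comps):
            # Prevotella depleted (healthy side) in comparisons 0, 2, 4
            neg = {"o1"} if i in (0, 2, 4) else set()
            # Bacteroides enriched in disease in every comparison
            results[c.comparison_id] = _result(otus, sig_neg=neg,
                                               sig_pos={"o3"})
        return results, comps

    def test_proportions(self, taxonomy3):
        results, comps = self.make_inputs(taxonomy3)
        mat_h, mat_d = genus_presence(results, comps, taxonomy3)
        assert mat_h.loc["d", "Prevotella"] == pytest.approx(3 / 9)
        assert mat_d.loc["d", "Bacteroides"] == pytest.approx(1.0)

    def test_never_significant_genus_pruned(self, taxonomy3):
        results, comps = self.make_inputs(taxonomy3)
        mat_h, mat_d = genus_presence(results, comps, taxonomy3)
        # o4 is unclassified; no other genus beyond the two hit ones appears
        assert set(mat_h.columns) == {"Prevotella", "Bacteroides"}


class TestClusterSupport:
    def test_flat_half_bp_maps_to_half_au(self):
        scales = np.arange(0.5, 1.45, 0.1)
        assert fit_au(scales, np.full(10, 0.5), 1000) == pytest.approx(0.5)

    def test_unanimous_support_is_one(self):
        scales = np.arange(0.5, 1.45, 0.1)
        assert fit_au(scales, np.ones(10), 1000) == 1.0
        assert fit_au(scales, np.zeros(10), 1000) == 0.0

    def test_duplicated_rows_always_co_cluster(self, rng):
        mat = pd.DataFrame(rng.random((5, 24)), index=list("ABCDE"))
        mat.loc["E"] = mat.loc["D"]
        cs = cluster_with_support(mat, n_boot=150, seed=3)
        pair = cs.nodes[cs.nodes["members"] == frozenset({"D", "E"})]
        assert len(pair) == 1
        assert pair["bp"].iloc[0] >= 0.99
        assert pair["au"].iloc[0] >= 0.95

    def test_row_order_invariance(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 20)), index=list("ABCDE"))
        cs1 = cluster_with_support(mat, n_boot=80, seed=5)
        cs2 = cluster_with_support(mat.iloc[::-1], n_boot=80, seed=5)
        assert set(cs1.nodes["members"]) == set(cs2.nodes["members"])

    def test_identical_rows_forced_topology(self):
        mat = pd.DataFrame(np.ones((4, 6)), index=list("ABCD"))
        cs = cluster_with_support(mat, n_boot=10, seed=1)
        assert np.all(cs.nodes["bp"] == 1.0)
        assert np.all(cs.nodes["au"] == 1.0)

    def test_support_in_unit_interval(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 15)), index=list("ABCDE"))
        cs = cluster_with_support(mat, n_boot=50, seed=2)
        assert cs.nodes["bp"].between(0, 1).all()
        assert cs.nodes["au"].between(0, 1).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_with_support(pd.DataFrame(np.ones((2, 3))))


def test_linkage_to_newick_preserves_leaves(rng):
    import skbio
    from io import StringIO
    from scipy.cluster import hierarchy
    x = rng.normal(size=(5, 8))
    z = hierarchy.linkage(x, "complete")
    nwk = linkage_to_newick(z, list("ABCDE"))
    tree = skbio.TreeNode.read(StringIO(nwk))
    assert {t.name for t in tree.tips()} == set("ABCDE")
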