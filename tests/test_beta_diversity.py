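from io import StringIO

import numpy as np
import pytest
import skbio

from dysbiome.beta_diversity import pcoa, permanova, weighted_unifrac
from dysbiome.core_tables import OtuTable


def table_of(counts, otu_ids):
    counts = np.asarray(counts)
    return OtuTable(counts, [f"s{i}" for i in range(counts.shape[0])],
                    otu_ids)


def tree_of(newick):
    return skbio.TreeNode.read(StringIO(newick))


def brute_unifrac(counts, otu_ids, tree, normalized):
    """Per-branch enumeration oracle for weighted UniFrac."""
    props = counts / counts.sum(axis=1, keepdims=True)
    col = {o: i for i, o in enumerate(otu_ids)}
    branches = []
    for node in tree.traverse(include_self=False):
        tips = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        idx = [col[t] for t in tips if t in col]
        branches.append((node.length or 0.0, idx))
    n = counts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for b, idx in branches:
                pa, pb = props[i, idx].sum(), props[j, idx].sum()
                num += b * abs(pa - pb)
                den += b * (pa + pb)
            out[i, j] = num / den if normalized else num
    return out


class TestWeightedUnifrac:
    def test_identical_samples_distance_zero(self):
        t = table_of([[3, 7], [3, 7]], ["A", "B"])
        dm = weighted_unifrac(t, tree_of("(A:1,B:1);"))
        assert dm[0, 1] == pytest.approx(0.0)

    def test_disjoint_tips_on_star_tree_normalized_one(self):
        t = table_of([[10, 0], [0, 25]], ["A", "B"])
        dm = weighted_unifrac(t, tree_of("(A:1,B:1);"), "normalized")
        assert dm[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["raw", "normalized"])
    def test_matches_per_branch_oracle(self, variant, rng):
        nwk = "((A:0.3,B:0.7):0.2,(C:0.5,(D:0.1,E:0.4):0.6):0.9);"
        counts = rng.integers(0, 40, size=(4, 5))
        counts[:, 0] += 1
        t = table_of(counts, list("ABCDE"))
        dm = weighted_unifrac(t, tree_of(nwk), variant)
        oracle = brute_unifrac(counts.astype(float), list("ABCDE"),
                               tree_of(nwk), variant == "normalized")
        assert np.allclose(dm.data, oracle, atol=1e-10)

    def test_caterpillar_tree_oracle(self):
        nwk = "((A:0.5,B:0.25):0.75,C:1.25);"
        counts = np.array([[6, 2, 2], [1, 1, 8]])
        t = table_of(counts, list("ABC"))
        dm = weighted_unifrac(t, tree_of(nwk), "raw")
        oracle = brute_unifrac(counts.astype(float), list("ABC"),
                               tree_of(nwk), False)
        assert dm[0, 1] == pytest.approx(oracle[0, 1])

    def test_zero_length_graft_leaves_distances_unchanged(self, rng):
        counts = rng.integers(1, 30, size=(3, 3))
        t = table_of(counts, list("ABC"))
        base = weighted_unifrac(t, tree_of("((A:0.2,B:0.3):0.4,C:0.6);"))
        grafted = weighted_unifrac(
            t, tree_of("(((A:0.2,B:0.3):0.0):0.4,C:0.6);"))
        assert np.allclose(base.data, grafted.data, atol=1e-12)

    def test_normalized_bounded_and_symmetric(self, tiny_cohort):
        table, _, tree, *_ = tiny_cohort
        sub = table.select_samples(table.sample_ids[:10])
        dm = weighted_unifrac(sub, tree)
        assert np.all(dm.data >= 0) and np.all(dm.data <= 1 + 1e-12)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)

    def test_missing_otu_listed_in_error(self):
        t = table_of([[1, 2], [3, 4]], ["A", "ZZZ"])
        with pytest.raises(ValueError, match="ZZZ"):
            weighted_unifrac(t, tree_of("(A:1,B:1);"))

    def test_zero_total_sample_rejected(self):
        t = table_of([[1, 2], [0, 0]], ["A", "B"])
        with pytest.raises(ValueError, match="s1"):
            weighted_unifrac(t, tree_of("(A:1,B:1);"))


class TestPcoa:
    def test_two_samples_closed_form(self):
        dm = skbio.DistanceMatrix([[0, 3.0], [3.0, 0]], ids=["a", "b"])
        coords, eig = pcoa(dm)
        assert sorted(np.abs(coords.iloc[:, 0])) == pytest.approx([1.5, 1.5])

    def test_equilateral_triangle_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, eig = pcoa(skbio.DistanceMatrix(d, ids=list("abc")))
        assert len(eig) == 2
        assert eig[0] == pytest.approx(eig[1])

    def test_zero_matrix_gives_no_positive_axes(self):
        dm = skbio.DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        coords, eig = pcoa(dm)
        assert coords.shape[1] == 0

    def test_euclidean_input_reproduced(self, rng):
        x = rng.normal(size=(6, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        coords, _ = pcoa(skbio.DistanceMatrix(d, ids=[str(i) for i in range(6)]))
        d2 = np.linalg.norm(coords.to_numpy()[:, None]
                            - coords.to_numpy()[None, :], axis=2)
        assert np.allclose(d, d2, atol=1e-8)


class TestPermanova:
    def make_dm(self, rng, n=6, shift=0.0):
        x = rng.normal(size=(n, 4))
        x[n // 2:] += shift
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        return skbio.DistanceMatrix(d, ids=[str(i) for i in range(n)])

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            permanova(self.make_dm(rng), ["g"] * 6)

    def test_exact_enumeration_at_n6(self, rng):
        dm = self.make_dm(rng, 6, shift=2.0)
        labels = np.repeat([0, 1], 3)
        res = permanova(dm, labels, n_perm=999, seed=1)
        assert res.n_permutations == 20  # C(6,3) arrangements enumerated
        # oracle: recompute over all 20 splits directly
        from itertools import combinations
        sq = dm.data ** 2
        n = 6
        ss_t = sq.sum() / (2 * n)

        def f_of(split):
            ss_w = 0.0
            for grp in (split, tuple(set(range(n)) - set(split))):
                idx = np.array(grp)
                ss_w += sq[np.ix_(idx, idx)].sum() / (2 * len(idx))
            return ((ss_t - ss_w) / 1) / (ss_w / 4)

        f_obs = f_of((0, 1, 2))
        fs = [f_of(s) for s in combinations(range(6), 3)]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res.p_value == pytest.approx(p_exact)
        assert res.pseudo_f == pytest.approx(f_obs)

    def test_pseudo_f_matches_skbio(self, rng):
        dm = self.make_dm(rng, 20, shift=1.0)
        labels = np.repeat(["a", "b"], 10)
        ours = permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(dm, list(labels),
                                                permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"])

    def test_deterministic_under_seed(self, rng):
        dm = self.make_dm(rng, 20, shift=0.5)
        labels = np.repeat([0, 1], 10)
        a = permanova(dm, labels, 199, seed=9)
        b = permanova(dm, labels, 199, seed=9)
        assert a.p_value == b.p_value

    def test_invariant_to_label_names(self, rng):
        dm = self.make_dm(rng, 16, shift=1.0)
        a = permanova(dm, np.repeat([0, 1], 8), 199, seed=4)
        b = permanova(dm, np.repeat(["x", "y"], 8), 199, seed=4)
        assert a.p_value == b.p_value
        assert a.pseudo_f == pytest.approx(b.pseudo_f)

    def test_p_lower_bound(self, rng):
        dm = self.make_dm(rng, 30, shift=5.0)
        res = permanova(dm, np.repeat([0, 1], 15), n_perm=199, seed=2)
        assert res.p_value >= 1 / 200
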