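import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dysbiome.core_tables import OtuTable
from dysbiome.differential_abundance import (benjamini_hochberg,
                                             count_enriched,
                                             estimate_dispersion,
                                             estimate_size_factors,
                                             wald_test)
from dysbiome.synthetic import SimulationConfig, simulate_cohort


def make_table(counts):
    counts = np.asarray(counts)
    return OtuTable(counts, [f"s{i}" for i in range(counts.shape[0])],
                    [f"o{j}" for j in range(counts.shape[1])])


class TestSizeFactors:
    def test_exact_doubling(self):
        t = make_table([[10, 20, 30], [20, 40, 60]])
        sf = estimate_size_factors(t)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_identical_samples_all_one(self):
        t = make_table([[5, 7, 9]] * 4)
        assert estimate_size_factors(t) == pytest.approx(np.ones(4))

    def test_hand_computed_medians(self):
        # per-OTU geometric means (4,8); ratios give factors (1, 2, 0.5)
        t = make_table([[4, 8], [8, 16], [2, 4]])
        assert estimate_size_factors(t) == pytest.approx([1.0, 2.0, 0.5])

    def test_geometric_mean_is_one(self, tiny_cohort):
        sf = estimate_size_factors(tiny_cohort[0])
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_all_zero_sample_named(self):
        t = make_table([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="s1"):
            estimate_size_factors(t)

    def test_poscounts_fallback(self):
        # no OTU is positive in every sample, factors still finite
        t = make_table([[4, 0, 6], [0, 5, 3], [8, 10, 0]])
        sf = estimate_size_factors(t)
        assert np.all(np.isfinite(sf)) and np.all(sf > 0)


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        t = make_table([[5, 9]] * 6)
        disp = estimate_dispersion(t, np.ones(6))
        assert np.all(disp == pytest.approx(1e-8))

    def test_poisson_counts_near_floor(self, rng):
        counts = rng.poisson(200, size=(400, 50))
        disp = estimate_dispersion(make_table(counts), np.ones(400))
        assert np.median(disp) < 0.01

    def test_nb_dispersion_recovered(self, rng):
        alpha, mu = 0.5, 100.0
        counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu),
                                       size=(200, 100))
        disp = estimate_dispersion(make_table(counts), np.ones(200))
        assert 0.35 <= np.median(disp) <= 0.65


class TestWaldTest:
    def test_symmetric_input_is_null(self):
        block = np.array([[10, 40], [20, 30], [15, 35]])
        t = make_table(np.vstack([block, block]))
        res = wald_test(t, np.array([0, 0, 0, 1, 1, 1]))
        assert res.log2fc == pytest.approx(np.zeros(2), abs=1e-6)
        assert res.p_value == pytest.approx(np.ones(2), abs=1e-6)

    def test_planted_fourfold_depletion_recovered(self, rng):
        # 10 of 200 OTUs depleted: a small DE fraction keeps the
        # median-of-ratios normalization unbiased
        mu_h = np.full(200, 400.0)
        mu_d = mu_h.copy()
        mu_d[:10] /= 4.0  # 4-fold depletion in group 2
        alpha = 0.1
        draw = lambda mu: rng.negative_binomial(
            1 / alpha, 1 / (1 + alpha * mu), size=(50, 200))
        t = make_table(np.vstack([draw(mu_h), draw(mu_d)]))
        res = wald_test(t, np.repeat([0, 1], 50))
        # estimates centred on the truth; each within a joint-coverage band
        assert np.mean(res.log2fc[:10]) == pytest.approx(-2.0, abs=0.25)
        for j in range(10):
            ci = 3.3 * res.lfcse[j]  # ~99.9% per OTU, ~99% jointly over 10
            assert res.log2fc[j] - ci <= -2.0 <= res.log2fc[j] + ci

    def test_wald_stat_is_lfc_over_se(self, tiny_cohort):
        res = wald_test(tiny_cohort[0], np.repeat([0, 1], 30))
        ok = np.isfinite(res.wald_stat)
        assert res.wald_stat[ok] == pytest.approx(
            (res.log2fc / res.lfcse)[ok])

    def test_sign_antisymmetry(self, tiny_cohort):
        table = tiny_cohort[0]
        g = np.repeat([0, 1], 30)
        a = wald_test(table, g)
        b = wald_test(table, 1 - g)
        ok = np.isfinite(a.log2fc)
        assert a.log2fc[ok] == pytest.approx(-b.log2fc[ok], abs=1e-6)
        assert a.p_value[ok] == pytest.approx(b.p_value[ok], abs=1e-6)

    def test_scale_invariance(self):
        # rescaling one library is absorbed by its size factor; in the
        # overdispersed regime the NB working weights saturate at 1/alpha,
        # so the Wald statistics are insensitive to the rescaling
        rng = np.random.default_rng(3)
        alpha, mu = 0.5, 200.0
        counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu),
                                       size=(40, 30)) + 1
        t1 = make_table(counts)
        scaled = counts.copy()
        scaled[0] *= 5
        t2 = make_table(scaled)
        g = np.repeat([0, 1], 20)
        r1, r2 = wald_test(t1, g), wald_test(t2, g)
        sf1, sf2 = estimate_size_factors(t1), estimate_size_factors(t2)
        assert (sf2[0] / sf2[1]) / (sf1[0] / sf1[1]) == pytest.approx(5.0)
        ok = np.isfinite(r1.wald_stat)
        assert np.max(np.abs(r1.wald_stat[ok] - r2.wald_stat[ok])) < 0.15

    def test_null_type_one_error_calibrated(self):
        cfg = SimulationConfig(n_samples_per_group=50, n_otus=500,
                               n_genera=20, effect_log2fc=0.0,
                               antibiotic_effect_log2fc=0.0, seed=99)
        table, *_ = simulate_cohort(cfg)
        res = wald_test(table, np.repeat([0, 1], 50))
        frac = np.mean(res.p_value[np.isfinite(res.p_value)] < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_all_zero_otu_has_absent_stats(self):
        counts = np.array([[5, 0], [7, 0], [6, 0], [8, 0]])
        res = wald_test(make_table(counts), np.array([0, 0, 1, 1]))
        assert np.isnan(res.p_value[1])
        assert np.isnan(res.log2fc[1])

    def test_empty_group_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            wald_test(tiny_cohort[0], np.zeros(60, dtype=int))


def bh_oracle(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for i in range(m):
        rank_i = np.flatnonzero(order == i)[0] + 1
        candidates = [min(1.0, m * p[order[j - 1]] / j)
                      for j in range(rank_i, m + 1)]
        out[i] = min(candidates)
    return out


class TestBenjaminiHochberg:
    def test_worked_example(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_step_up_definition(self, p):
        assert benjamini_hochberg(p) == pytest.approx(bh_oracle(p))


class TestCountEnriched:
    def test_no_significance_gives_zero(self, null_cohort):
        res = wald_test(null_cohort[0], np.repeat([0, 1], 30))
        # adjusted p-values on a null cohort should clear almost everything
        n1, n2 = count_enriched(res, alpha=1e-6)
        assert (n1, n2) == (0, 0)

    def test_label_flip_swaps_counts(self, tiny_cohort):
        table = tiny_cohort[0]
        g = np.repeat([0, 1], 30)
        a = count_enriched(wald_test(table, g))
        b = count_enriched(wald_test(table, 1 - g))
        assert a == (b[1], b[0])

    def test_planted_depletion_power(self, tiny_cohort):
        table, *_ , truth = tiny_cohort
        res = wald_test(table, np.repeat([0, 1], 30))
        n_healthy, n_disease = count_enriched(res)
        n_planted = int(np.sum(truth.dysbiotic_flag == "depleted"))
        assert n_healthy >= 0.8 * n_planted
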