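"""Statistical tests against closed-form and enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from bafkit.intervals import GenomicInterval, SignalTrack
from bafkit.stats import (
    MorphometryRecord,
    binned_pearson,
    dunn_posthoc,
    kruskal_wallis,
    nuclear_density,
    nuclear_shape_index,
    tumor_volume,
    welch_t,
    wilcoxon_rank_sum,
)


class TestWelch:
    def test_identical_samples(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0) and r.pvalue == pytest.approx(1.0)

    def test_closed_form_example(self):
        r = welch_t([10, 11, 12], [1, 2, 3])
        assert r.statistic == pytest.approx(9 / np.sqrt(2 / 3))
        assert r.df == pytest.approx(4.0)

    def test_sign_flips_on_swap_p_unchanged(self):
        a, b = [10, 11, 12], [1, 2, 5]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        r1, r2 = welch_t(a, b), welch_t(a + 5, b + 5)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestKruskal:
    def test_hand_ranked_three_by_three(self):
        # ranks are 1..9 with no ties: H = 12/(9*10) * (6+90+234) - 30 = 7.2
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.statistic == pytest.approx(7.2)
        assert r.pvalue == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_identical_values_h_zero(self):
        r = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_agreement_with_exact_permutation_null(self):
        # enumerate all label permutations of 6 values in two groups of 3
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        obs = kruskal_wallis([values[:3], values[3:]])
        hs = []
        for comb in itertools.combinations(range(6), 3):
            g1 = [values[i] for i in comb]
            g2 = [values[i] for i in range(6) if i not in comb]
            hs.append(sps.kruskal(g1, g2).statistic)
        exact_p = np.mean(np.array(hs) >= obs.statistic - 1e-12)
        # chi-square approximation is crude at n=6; enumeration bounds it
        assert abs(obs.pvalue - exact_p) < 0.08

    def test_reordering_invariance(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        r1 = kruskal_wallis(groups)
        r2 = kruskal_wallis([rng.permutation(g) for g in groups])
        assert r1.statistic == pytest.approx(r2.statistic)


class TestDunn:
    def test_identical_groups_z_zero(self):
        res = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        r = res[(0, 1)]
        assert r.statistic == pytest.approx(0.0)
        assert r.adjusted_pvalue == pytest.approx(1.0)

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(i * 0.5, 1, 12) for i in range(4)]
        for r in dunn_posthoc(groups).values():
            assert r.adjusted_pvalue >= r.pvalue - 1e-15

    def test_well_separated_groups_all_significant(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(5 * i, 1.0, 20) for i in range(3)]
        res = dunn_posthoc(groups)
        assert all(r.adjusted_pvalue < 0.01 for r in res.values())

    def test_ties_correction_matches_hand_formula(self):
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0, 4.0]]
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie = float((counts**3 - counts).sum())
        var = n * (n + 1) / 12 - tie / (12 * (n - 1))
        z_hand = (ranks[:3].mean() - ranks[3:].mean()) / np.sqrt(var * (2 / 3))
        r = dunn_posthoc(groups)[(0, 1)]
        assert r.statistic == pytest.approx(z_hand)


class TestWilcoxon:
    def test_exact_enumeration_small_example(self):
        # C(4,2)=6 arrangements; only the two extremes are as extreme: p = 1/3
        r = wilcoxon_rank_sum([1, 2], [3, 4])
        assert r.pvalue == pytest.approx(1 / 3)

    def test_identical_singletons(self):
        assert wilcoxon_rank_sum([5.0], [5.0]).pvalue == pytest.approx(1.0)

    def test_exact_and_approximate_branches_agree_at_cutover(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
            exact = wilcoxon_rank_sum(x, y).pvalue
            _, approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                         method="asymptotic")
            assert abs(exact - approx) < 0.02

    def test_shift_invariance(self):
        x, y = [1.0, 2.0, 5.0], [3.0, 4.0, 6.0]
        assert wilcoxon_rank_sum(x, y).pvalue == pytest.approx(
            wilcoxon_rank_sum([v + 9 for v in x], [v + 9 for v in y]).pvalue
        )


class TestTypeIError:
    """Under the null, rejection at alpha=0.05 stays near 5%."""

    N_REPS = 2000

    def test_welch_null_calibration(self):
        rng = np.random.default_rng(100)
        x = rng.normal(0, 1, (self.N_REPS, 10))
        y = rng.normal(0, 1, (self.N_REPS, 10))
        _, p = sps.ttest_ind(x, y, axis=1, equal_var=False)
        # spot-check the vectorized null against the library entry point
        r = welch_t(x[0], y[0])
        assert r.pvalue == pytest.approx(float(p[0]))
        rate = float((p < 0.05).mean())
        assert 0.035 <= rate <= 0.065

    def test_kruskal_null_calibration(self):
        rng = np.random.default_rng(101)
        hits = 0
        for _ in range(self.N_REPS):
            groups = [rng.normal(0, 1, 8) for _ in range(3)]
            if kruskal_wallis(groups).pvalue < 0.05:
                hits += 1
        assert 0.035 <= hits / self.N_REPS <= 0.065

    def test_wilcoxon_null_calibration(self):
        rng = np.random.default_rng(102)
        hits = 0
        for _ in range(self.N_REPS):
            x, y = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
            if wilcoxon_rank_sum(x, y).pvalue < 0.05:
                hits += 1
        assert 0.035 <= hits / self.N_REPS <= 0.065


class TestBinnedPearson:
    def test_track_against_itself(self):
        rng = np.random.default_rng(5)
        runs = [(GenomicInterval("chr1", i * 1000, (i + 1) * 1000),
                 float(rng.random())) for i in range(50)]
        t = SignalTrack(runs)
        assert binned_pearson(t, t, 5000, {"chr1": 50_000}) == pytest.approx(1.0)

    def test_track_against_negation(self):
        rng = np.random.default_rng(6)
        runs = [(GenomicInterval("chr1", i * 1000, (i + 1) * 1000),
                 float(rng.random())) for i in range(50)]
        t = SignalTrack(runs)
        assert binned_pearson(t, t.scale(-1.0), 5000,
                              {"chr1": 50_000}) == pytest.approx(-1.0)

    def test_hand_computed_on_five_bins(self):
        a_vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        b_vals = [2.0, 1.0, 4.0, 3.0, 6.0]
        a = SignalTrack([(GenomicInterval("chr1", i * 100, (i + 1) * 100), v)
                         for i, v in enumerate(a_vals)])
        b = SignalTrack([(GenomicInterval("chr1", i * 100, (i + 1) * 100), v)
                         for i, v in enumerate(b_vals)])
        r = binned_pearson(a, b, 100, {"chr1": 500})
        # textbook formula on the bin sums
        x = np.array(a_vals) * 100
        y = np.array(b_vals) * 100
        expect = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_restricted_to_sites(self):
        a = SignalTrack([(GenomicInterval("chr1", 0, 100), 1.0),
                         (GenomicInterval("chr1", 200, 300), 5.0)])
        b = SignalTrack([(GenomicInterval("chr1", 0, 100), 2.0),
                         (GenomicInterval("chr1", 200, 300), 10.0)])
        sites = [GenomicInterval("chr1", 0, 100),
                 GenomicInterval("chr1", 200, 300)]
        assert binned_pearson(a, b, 100, restrict=sites) == pytest.approx(1.0)

    def test_single_bin_rejected(self):
        t = SignalTrack([(GenomicInterval("chr1", 0, 100), 1.0)])
        with pytest.raises(ValueError):
            binned_pearson(t, t, 100, {"chr1": 100})


class TestPhenotypeFormulas:
    def test_tumor_volume_printed_formula(self):
        assert tumor_volume(10, 5) == pytest.approx(125.0)
        assert tumor_volume(10, 10) == pytest.approx(500.0)

    def test_doubling_short_axis_quadruples_volume(self):
        assert tumor_volume(20, 10) == pytest.approx(4 * tumor_volume(20, 5))

    def test_axis_order_enforced(self):
        with pytest.raises(ValueError):
            tumor_volume(5, 10)

    def test_single_region_shape_index_is_mean_ratio(self):
        rec = MorphometryRecord("t", [(1.0, [(2.0, 1.0), (2.2, 1.0), (1.8, 1.0)])])
        assert nuclear_shape_index(rec) == pytest.approx(2.0)

    def test_two_region_weighted_mean(self):
        rec = MorphometryRecord("t", [
            (0.5, [(2.0, 1.0)] * 3),
            (0.5, [(1.0, 1.0)] * 3),
        ])
        assert nuclear_shape_index(rec) == pytest.approx(1.5)

    def test_round_nuclei_index_is_minimum_one(self):
        rec = MorphometryRecord("t", [(1.0, [(3.0, 3.0)] * 3)])
        assert nuclear_shape_index(rec) == pytest.approx(1.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MorphometryRecord("t", [(0.7, [(2.0, 1.0)] * 3)])

    def test_long_axis_must_dominate(self):
        with pytest.raises(ValueError):
            MorphometryRecord("t", [(1.0, [(1.0, 2.0)] * 3)])

    def test_density_units(self):
        assert nuclear_density(0) == 0.0
        assert nuclear_density(25) == 25.0
        assert nuclear_density(25, to_mm2=True) == pytest.approx(50_000.0)
        assert nuclear_density(50) == 2 * nuclear_density(25)
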