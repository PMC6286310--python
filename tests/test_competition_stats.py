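import math

import numpy as np
import pytest
from scipy import stats

from caretaker.competition_stats import (
    CloneMeasurement,
    call_suppressor,
    dagostino_pearson,
    paired_ratio_test,
    per_disc_ratio,
    rank_group_test,
    summarize_genotype,
)
from caretaker.errors import InputError, SampleSizeError
from caretaker.synthetic_data import CloneDatasetSpec, gen_clone_dataset


def _m(loser, winner, disc="d0", geno="g"):
    return CloneMeasurement(disc_id=disc, genotype=geno,
                            loser_area=loser, winner_area=winner)


class TestPerDiscRatio:
    @pytest.mark.parametrize("loser,winner,expected",
                             [(0, 100, 0.0), (100, 100, 1.0), (30, 120, 0.25)])
    def test_ratio(self, loser, winner, expected):
        assert per_disc_ratio(_m(loser, winner)) == expected

    def test_nonpositive_winner_rejected(self):
        with pytest.raises(InputError):
            _m(10, 0)


class TestSummarizeGenotype:
    def test_constant_ratios(self):
        ms = [_m(50, 100, disc=f"d{i}") for i in range(5)]
        s = summarize_genotype(ms)
        assert (s.mean_ratio, s.sem, s.n) == (0.5, 0.0, 5)

    def test_hand_arithmetic(self):
        ms = [_m(50, 100), _m(100, 100), _m(150, 100)]
        s = summarize_genotype(ms)
        assert s.mean_ratio == pytest.approx(1.0)
        assert s.sem == pytest.approx(0.5 / math.sqrt(3))

    def test_n_conserved(self, rescue_spec):
        data = gen_clone_dataset(rescue_spec)
        assert summarize_genotype(data).n == len(data)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            summarize_genotype([])

    def test_mixed_genotypes_rejected(self):
        with pytest.raises(InputError):
            summarize_genotype([_m(1, 2, geno="a"), _m(1, 2, geno="b")])


class TestDagostinoPearson:
    def test_matches_reference_implementation(self, rng):
        # contract: within 1e-6 of scipy's omnibus test on shared inputs
        for n in (8, 9, 20, 45, 100, 500):
            x = rng.normal(size=n) + rng.exponential(size=n)
            ours = dagostino_pearson(x)
            ref_stat, ref_p = stats.normaltest(x)
            assert ours.statistic == pytest.approx(float(ref_stat), abs=1e-6)
            assert ours.p_value == pytest.approx(float(ref_p), abs=1e-6)

    def test_type_i_error_rate(self):
        rejections = 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(size=5000)
            rejections += dagostino_pearson(x).p_value < 0.05
        assert 0.03 <= rejections / 200 <= 0.08

    def test_power_on_exponential(self):
        x = np.random.default_rng(0).exponential(size=1000)
        assert dagostino_pearson(x).p_value < 0.001

    def test_constant_sample_rejected(self):
        with pytest.raises(InputError):
            dagostino_pearson([1.0] * 20)

    def test_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            dagostino_pearson([0.1, 0.2, 0.3])


class TestRankGroupTest:
    def test_identical_groups(self):
        assert rank_group_test([[1.0, 1.0], [1.0, 1.0]]) == 1.0

    def test_complete_separation(self):
        # one-sided exact rank p for n=3,3 separation is 1/20; our two-sided
        # asymptotic Kruskal-Wallis gives chi2.sf(3.857, 1) ~= 0.0495
        p = rank_group_test([[1, 2, 3], [101, 102, 103]])
        assert p == pytest.approx(0.0495, abs=5e-4)
        exact_one_sided = stats.mannwhitneyu(
            [101, 102, 103], [1, 2, 3], alternative="greater", method="exact"
        ).pvalue
        assert exact_one_sided == pytest.approx(1 / 20)

    def test_two_group_reduces_to_mann_whitney(self, rng):
        a, b = rng.normal(size=30), rng.normal(0.5, size=30)
        kw = rank_group_test([a, b])
        mw = stats.mannwhitneyu(a, b, alternative="two-sided",
                                use_continuity=False,
                                method="asymptotic").pvalue
        assert kw == pytest.approx(float(mw), rel=1e-9)

    def test_three_groups(self, rng):
        groups = [rng.normal(loc, size=25) for loc in (0.0, 0.0, 2.0)]
        assert rank_group_test(groups) < 1e-4

    def test_pipeline_level_separation(self):
        loser = gen_clone_dataset(CloneDatasetSpec("l", 45, 0.95, seed=1))
        rescue = gen_clone_dataset(CloneDatasetSpec("r", 45, 0.05, seed=2))
        p = rank_group_test([[per_disc_ratio(m) for m in loser],
                             [per_disc_ratio(m) for m in rescue]])
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            rank_group_test([[1, 2, 3]])

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            rank_group_test([[1, 2], []])


class TestCallSuppressor:
    def test_candidate_equals_control(self, loser_spec):
        s = summarize_genotype(gen_clone_dataset(loser_spec))
        call = call_suppressor(s, s)
        assert not call.is_suppressor
        assert call.ratio_test_p > 0.05

    def test_rescue_called(self, loser_spec, rescue_spec):
        loser = summarize_genotype(gen_clone_dataset(loser_spec))
        rescue = summarize_genotype(gen_clone_dataset(rescue_spec))
        call = call_suppressor(rescue, loser)
        assert call.is_suppressor
        assert call.ratio_test_p < 1e-10

    def test_bimodal_candidate_rejected_by_normality(self, loser_spec):
        # mixture of fully-rescued and barely-above-control discs: large
        # ratio increase, but strongly bimodal -> criterion (ii) fails
        full = gen_clone_dataset(CloneDatasetSpec("bimodal", 24, 0.0,
                                                  noise_sd=0.05, seed=21))
        gone = gen_clone_dataset(CloneDatasetSpec("bimodal", 24, 0.9,
                                                  noise_sd=0.05, seed=22))
        candidate = summarize_genotype(full + gone)
        loser = summarize_genotype(gen_clone_dataset(loser_spec))
        call = call_suppressor(candidate, loser)
        assert call.ratio_test_p < 0.05          # mean size did increase
        assert call.normality_p < 0.05           # but distribution is bimodal
        assert not call.is_suppressor

    def test_one_sided_asymmetry(self, loser_spec, rescue_spec):
        # swapping candidate and control can only destroy a call
        loser = summarize_genotype(gen_clone_dataset(loser_spec))
        rescue = summarize_genotype(gen_clone_dataset(rescue_spec))
        assert call_suppressor(rescue, loser).is_suppressor
        assert not call_suppressor(loser, rescue).is_suppressor

    def test_small_candidate_refused(self, loser_spec):
        tiny = summarize_genotype(
            gen_clone_dataset(CloneDatasetSpec("tiny", 5, 0.1, seed=4)))
        loser = summarize_genotype(gen_clone_dataset(loser_spec))
        with pytest.raises(SampleSizeError):
            call_suppressor(tiny, loser)

    def test_type_i_control_quick(self, loser_spec):
        # fuller 500-pair version lives in the acceptance suite
        calls = 0
        n_pairs = 60
        for seed in range(n_pairs):
            a = summarize_genotype(gen_clone_dataset(
                CloneDatasetSpec("a", 47, 0.95, seed=1000 + seed)))
            b = summarize_genotype(gen_clone_dataset(
                CloneDatasetSpec("b", 47, 0.95, seed=2000 + seed)))
            calls += call_suppressor(a, b).is_suppressor
        assert calls / n_pairs <= 0.05 + 0.05  # generous at this n


class TestPairedRatioTest:
    def test_all_pairs_equal(self):
        res = paired_ratio_test([(2.0, 2.0)] * 10)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_constant_doubling_degenerate(self):
        res = paired_ratio_test([(2.0, 1.0)] * 10)
        assert res.p_value == 0.0
        assert res.degenerate
        assert math.isinf(res.statistic)

    def test_matches_log_t_test(self, rng):
        pairs = [(float(t), float(c))
                 for t, c in zip(rng.lognormal(1, 0.3, 15),
                                 rng.lognormal(1, 0.3, 15))]
        res = paired_ratio_test(pairs)
        logr = np.log([t / c for t, c in pairs])
        ref = stats.ttest_1samp(logr, 0.0)
        assert res.p_value == pytest.approx(float(ref.pvalue))
        assert not res.degenerate

    def test_power_simulation(self):
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            control = rng.lognormal(3, 0.5, 20)
            treated = control * 1.5 * rng.lognormal(0, 0.2, 20)
            res = paired_ratio_test(list(zip(treated, control)))
            rejections += res.p_value < 0.05
        assert rejections / 200 > 0.9

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            paired_ratio_test([(1.0, 0.0), (2.0, 1.0)])

    def test_too_few_pairs(self):
        with pytest.raises(InputError):
            paired_ratio_test([(1.0, 2.0)])
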