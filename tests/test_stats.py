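"""Descriptives, one-way ANOVA (raw and from summaries), exact Wilcoxon."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mammober.stats import (anova_from_summaries, comparison_report, describe,
                            format_p, one_way_anova, wilcoxon_one_sample)


class TestDescribe:
    def test_one_to_ten(self):
        s = describe(range(1, 11))
        assert s.mean == 5.5 and s.median == 5.5
        assert s.range == 9 and s.sum == 55
        assert s.minimum == 1 and s.maximum == 10

    def test_constant_list(self):
        s = describe([2.0] * 6)
        assert s.sd == 0 and s.sem == 0 and s.range == 0

    def test_sem_identity(self, rng):
        v = rng.uniform(size=17)
        s = describe(v)
        assert s.sem * math.sqrt(s.n) == pytest.approx(s.sd)
        assert s.sum == pytest.approx(s.n * s.mean)
        assert s.minimum <= s.p25 <= s.median <= s.p75 <= s.maximum

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            describe([])


class TestAnovaRaw:
    def test_identical_constant_groups(self):
        r = one_way_anova([[3.0, 3.0], [3.0, 3.0, 3.0]])
        assert r.ss_treatment == 0 and r.f_ratio == 0 and r.p_value == 1.0

    def test_two_groups_hand_computation(self):
        # SS_treat = 2*(0-1/2)^2 + 2*(1-1/2)^2 = 1
        r = one_way_anova([[0.0, 0.0], [1.0, 1.0]])
        assert r.ss_treatment == pytest.approx(1.0)
        assert r.ss_residual == 0
        assert math.isinf(r.f_ratio)
        assert r.p_value == 0.0

    def test_matches_two_pass_oracle_and_scipy(self, rng):
        for _ in range(10):
            groups = [rng.normal(size=int(rng.integers(3, 9))).tolist()
                      for _ in range(int(rng.integers(2, 5)))]
            r = one_way_anova(groups)
            # independent two-pass SS computation
            all_v = np.concatenate(groups)
            grand = all_v.mean()
            ss_tot = ((all_v - grand) ** 2).sum()
            ss_res = sum(((np.array(g) - np.mean(g)) ** 2).sum() for g in groups)
            assert r.ss_total == pytest.approx(ss_tot, rel=1e-10)
            assert r.ss_residual == pytest.approx(ss_res, rel=1e-10)
            f, p = sps.f_oneway(*groups)
            assert r.f_ratio == pytest.approx(f, rel=1e-10)
            assert r.p_value == pytest.approx(p, rel=1e-8)

    def test_conservation(self, rng):
        groups = [rng.normal(size=6).tolist() for _ in range(4)]
        r = one_way_anova(groups)
        assert r.ss_total == pytest.approx(r.ss_treatment + r.ss_residual,
                                           abs=1e-10)
        assert r.df_total == r.df_treatment + r.df_residual

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="two groups"):
            one_way_anova([[1.0, 2.0]])


class TestAnovaFromSummaries:
    def test_identical_means_zero_treatment(self):
        r = anova_from_summaries([1.0, 1.0, 1.0], [0.2, 0.3, 0.1], 5)
        assert r.ss_treatment == pytest.approx(0.0, abs=1e-15)

    def test_agrees_with_raw_to_1e12(self, rng):
        groups = [rng.normal(loc=i, size=8) for i in range(5)]
        means = [g.mean() for g in groups]
        sds = [g.std(ddof=1) for g in groups]
        r_raw = one_way_anova([g.tolist() for g in groups])
        r_sum = anova_from_summaries(means, sds, 8)
        assert r_sum.ss_treatment == pytest.approx(r_raw.ss_treatment, abs=1e-12)
        assert r_sum.ss_residual == pytest.approx(r_raw.ss_residual, abs=1e-12)
        assert r_sum.f_ratio == pytest.approx(r_raw.f_ratio, rel=1e-10)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            anova_from_summaries([1.0, 2.0], [0.1], 5)


def _bruteforce_wilcoxon_p(diffs):
    """Literal enumeration of all 2^n sign assignments (independent oracle)."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    w_minus = ranks[diffs < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs + 1e-9:
            count += 1
    return min(2.0 * count / 2 ** n, 1.0)


class TestWilcoxon:
    def test_ten_positive_values(self):
        r = wilcoxon_one_sample([0.9, 0.91, 0.92, 0.93, 0.89, 0.9, 0.94,
                                 0.95, 0.88, 0.96])
        assert r.w_plus == 55 and r.w_minus == 0 and r.w_signed == 55
        assert r.p_value == pytest.approx(2 / 1024)
        assert r.exact

    def test_single_value_p_is_one(self):
        r = wilcoxon_one_sample([0.5])
        assert r.p_value == 1.0

    def test_all_one_sign_p_is_two_to_the_minus_n_plus_one(self):
        for n in (3, 6, 12, 20):
            r = wilcoxon_one_sample(list(np.arange(1, n + 1, dtype=float)))
            assert r.p_value == pytest.approx(2.0 * 2.0 ** (-n))

    def test_matches_enumeration_oracle_small_n(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            vals = np.round(rng.normal(scale=2.0, size=n), 1)
            vals = vals[vals != 0]
            if vals.size == 0:
                continue
            r = wilcoxon_one_sample(vals)
            assert r.p_value == pytest.approx(_bruteforce_wilcoxon_p(vals),
                                              abs=1e-12)

    def test_matches_scipy_exact_when_no_ties(self, rng):
        for _ in range(20):
            vals = rng.normal(size=12)  # continuous: no ties, no zeros
            r = wilcoxon_one_sample(vals)
            p_scipy = sps.wilcoxon(vals, method="exact").pvalue
            assert r.p_value == pytest.approx(p_scipy, abs=1e-12)

    def test_zero_differences_dropped(self):
        r = wilcoxon_one_sample([0.0, 0.0, 1.0, 2.0, 3.0])
        assert r.n == 3
        assert r.p_value == pytest.approx(2 / 8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_one_sample([0.0, 0.0])

    def test_large_n_normal_approximation_close_to_exact_tail(self, rng):
        vals = rng.normal(loc=0.8, size=40)
        r = wilcoxon_one_sample(vals)
        assert not r.exact
        p_scipy = sps.wilcoxon(vals, method="approx", correction=True).pvalue
        assert r.p_value == pytest.approx(p_scipy, rel=0.05)

    def test_p_values_in_unit_interval(self, rng):
        for _ in range(30):
            vals = rng.normal(size=int(rng.integers(1, 30)))
            r = wilcoxon_one_sample(vals)
            assert 0.0 <= r.p_value_one_sided <= r.p_value <= 1.0


class TestComparisonReport:
    def _results(self, rng, k=7, n=10):
        return {f"model{i}": (0.9 + 0.01 * i + 0.005 *
                              rng.standard_normal(n)).tolist()
                for i in range(k)}

    def test_seven_models_ten_replicates_df(self, rng, tmp_path):
        bundle = comparison_report(self._results(rng), tmp_path, make_plots=False)
        assert bundle["anova"]["df_treatment"] == 6
        assert bundle["anova"]["df_residual"] == 63
        assert (tmp_path / "descriptives.csv").exists()
        assert (tmp_path / "anova.csv").exists()
        assert (tmp_path / "wilcoxon.csv").exists()

    def test_two_identical_models_f_zero(self, tmp_path):
        vals = [0.9, 0.91, 0.92, 0.9, 0.93]
        bundle = comparison_report({"a": vals, "b": list(vals)}, tmp_path,
                                   make_plots=False)
        assert bundle["anova"]["f_ratio"] == pytest.approx(0.0, abs=1e-20)

    def test_model_order_invariance(self, rng, tmp_path):
        res = self._results(rng, k=4, n=6)
        b1 = comparison_report(res, tmp_path / "a", make_plots=False)
        shuffled = dict(reversed(list(res.items())))
        b2 = comparison_report(shuffled, tmp_path / "b", make_plots=False)
        assert b1["anova"]["f_ratio"] == pytest.approx(b2["anova"]["f_ratio"])
        assert b1["anova"]["p_value"] == pytest.approx(b2["anova"]["p_value"])

    def test_unequal_replicates_named(self, tmp_path):
        with pytest.raises(ValueError, match="modelB"):
            comparison_report({"modelA": [1.0, 2.0], "modelB": [1.0]}, tmp_path)

    def test_plots_written(self, rng, tmp_path):
        comparison_report(self._results(rng, k=3, n=5), tmp_path, make_plots=True)
        assert (tmp_path / "qq_residuals.png").exists()
        assert (tmp_path / "residuals_vs_fit.png").exists()


def test_format_p_threshold():
    assert format_p(5e-5) == "< 0.0001"
    assert format_p(0.0234).startswith("0.023")
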