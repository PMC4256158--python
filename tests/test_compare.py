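"""Log-rank, Holm adjustment, t-tests, and demographic classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

import wormdemog as w
from conftest import make_events


def two_cohorts(m0_a, g_a, m0_b, g_b, n=150, seed=0):
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    a = w.discretize_and_censor(
        w.sample_gm_lifetimes(w.GMParams(m0_a, g_a), n, s1), 0.01, 80, seed=101, group="a"
    )
    b = w.discretize_and_censor(
        w.sample_gm_lifetimes(w.GMParams(m0_b, g_b), n, s2), 0.01, 80, seed=102, group="b"
    )
    return a, b


class TestLogrank:
    def test_identical_tables(self, toy_events):
        res = w.logrank_test(toy_events, toy_events)
        assert res.statistic == 0.0
        assert res.p_raw == 1.0
        assert res.percent_change == 0.0

    def test_symmetry_under_label_swap(self):
        a, b = two_cohorts(0.004, 0.25, 0.001, 0.25, seed=5)
        r1 = w.logrank_test(a, b)
        r2 = w.logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_zero_deaths_undefined(self):
        ev = make_events([("a", "g", "r1", 3, "censored"), ("b", "g", "r1", 5, "censored")])
        with pytest.raises(ValueError):
            w.logrank_test(ev, ev)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_lifelines(self, seed):
        a, b = two_cohorts(0.004, 0.25, 0.002, 0.3, seed=seed)
        ours = w.logrank_test(a, b)
        theirs = ll_logrank(
            a["event_day"], b["event_day"],
            event_observed_A=a["status"] == "death",
            event_observed_B=b["status"] == "death",
        )
        assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.p_raw == pytest.approx(theirs.p_value, rel=1e-9)

    def test_observed_minus_expected_sums_to_zero(self):
        a, b = two_cohorts(0.004, 0.25, 0.002, 0.3, seed=9)
        oe = w.logrank_oe_contributions(a, b)
        np.testing.assert_allclose(oe["oe_a"] + oe["oe_b"], 0.0, atol=1e-12)
        assert abs(oe["oe_a"].sum() + oe["oe_b"].sum()) < 1e-10


class TestHolmAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(w.holm_adjust([0.03]), [0.03])

    def test_two_p_hand_example(self):
        np.testing.assert_allclose(w.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_three_large_ps_cap_at_one(self):
        np.testing.assert_allclose(w.holm_adjust([0.9, 0.9, 0.9]), [1.0, 1.0, 1.0])

    def test_empty_input(self):
        assert len(w.holm_adjust([])) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            w.holm_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_statsmodels_holm(self, ps):
        ours = w.holm_adjust(ps)
        theirs = multipletests(ps, method="holm")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        # adjusted never below raw, order preserved under permutation
        assert np.all(ours >= np.asarray(ps) - 1e-15)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = w.two_sample_t([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.p_raw == 1.0
        assert res.percent_change == 0.0

    def test_clear_separation(self):
        a = np.full(5, 10.0) + np.arange(5) * 1e-9
        res = w.two_sample_t(a + 5.0, a)
        assert res.p_raw < 1e-6
        assert res.percent_change == pytest.approx(50.0, rel=1e-6)

    def test_matches_permutation_oracle(self):
        # with 3 vs 3 there are only C(6,3)=20 splits, so the exhaustive
        # permutation p has resolution 0.05; demand agreement at that scale
        a = [7.0, 9.0, 8.0]
        b = [6.0, 5.0, 8.5]
        res = w.two_sample_t(a, b)
        perm = stats.permutation_test(
            (a, b),
            lambda x, y, axis: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent",
            n_resamples=np.inf,
        )
        assert res.p_raw == pytest.approx(perm.pvalue, abs=0.05)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            w.two_sample_t([1.0], [2.0, 3.0])


def _fits(m0s, gs):
    return w.summarize_replicates(
        [
            w.GMFit(params=w.GMParams(m, g), rss=0.0, n_points=20, converged=True)
            for m, g in zip(m0s, gs)
        ]
    )


def _life(pct, p):
    return w.ComparisonResult(0.0, p, p, pct, "t_test")


class TestClassifyDemographicGroup:
    CTRL = ([0.0040, 0.0042, 0.0038], [0.25, 0.26, 0.24])

    def test_group1_roa_down_lifespan_up(self):
        trt = _fits([0.0041, 0.0039, 0.0040], [0.13, 0.125, 0.135])
        call = w.classify_demographic_group(trt, _fits(*self.CTRL), _life(50.0, 1e-6))
        assert call.group == 1
        assert (call.imr_effect, call.roa_effect, call.lifespan_effect) == ("none", "down", "up")

    def test_group2_imr_down_lifespan_up(self):
        trt = _fits([0.0008, 0.0009, 0.0007], [0.25, 0.255, 0.245])
        call = w.classify_demographic_group(trt, _fits(*self.CTRL), _life(25.0, 1e-4))
        assert call.group == 2

    def test_group3_imr_down_roa_up_lifespan_none(self):
        trt = _fits([0.0004, 0.0005, 0.0003], [0.45, 0.46, 0.44])
        call = w.classify_demographic_group(trt, _fits(*self.CTRL), _life(0.5, 0.8))
        assert call.group == 3

    def test_group4_all_none(self):
        trt = _fits(*self.CTRL)
        call = w.classify_demographic_group(trt, _fits(*self.CTRL), _life(0.0, 1.0))
        assert call.group == 4

    def test_unobserved_pattern_is_unclassified(self):
        # IMR up is a pattern the four groups never show
        trt = _fits([0.02, 0.021, 0.019], [0.25, 0.26, 0.24])
        call = w.classify_demographic_group(trt, _fits(*self.CTRL), _life(-20.0, 1e-4))
        assert call.group == "unclassified"

    def test_invariant_to_replicate_order(self):
        trt = _fits([0.0008, 0.0009, 0.0007], [0.25, 0.255, 0.245])
        trt_rev = _fits([0.0007, 0.0009, 0.0008], [0.245, 0.255, 0.25])
        life = _life(25.0, 1e-4)
        c1 = w.classify_demographic_group(trt, _fits(*self.CTRL), life)
        c2 = w.classify_demographic_group(trt_rev, _fits(*self.CTRL), life)
        assert c1 == c2

    def test_requires_two_replicates(self):
        single = _fits([0.004], [0.25])
        with pytest.raises(ValueError):
            w.classify_demographic_group(single, single, _life(0.0, 1.0))


class TestPercentChangeParams:
    def test_equal_means_zero(self):
        f = _fits([0.004, 0.004], [0.25, 0.25])
        assert w.percent_change_params(f, f) == pytest.approx((0.0, 0.0))

    def test_ninety_percent_reduction(self):
        trt = _fits([0.001, 0.001], [0.25, 0.25])
        ctl = _fits([0.010, 0.010], [0.25, 0.25])
        imr_pct, _ = w.percent_change_params(trt, ctl)
        assert imr_pct == pytest.approx(90.0)

    def test_increase_is_negative_reduction(self):
        trt = _fits([0.004, 0.004], [0.30, 0.30])
        ctl = _fits([0.004, 0.004], [0.25, 0.25])
        _, roa_pct = w.percent_change_params(trt, ctl)
        assert roa_pct == pytest.approx(-20.0)


class TestMeanLifespanComparison:
    def test_detects_longer_lived_group(self):
        import pandas as pd

        parts_a, parts_b = [], []
        for i, r in enumerate(("r1", "r2", "r3")):
            aa, bb = two_cohorts(0.004, 0.25, 0.004, 0.13, n=200, seed=40 + i)
            aa = aa.assign(replicate=r)
            bb = bb.assign(replicate=r, group="slow")
            parts_a.append(aa)
            parts_b.append(bb)
        events = pd.concat(parts_a + parts_b, ignore_index=True)
        res = w.mean_lifespan_comparison(events, "slow", "a")
        assert res.percent_change > 20
        assert res.p_raw < 0.05
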