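"""Mann-Whitney U correctness, classification, trend, and proportion contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from poeclab import (
    InsufficientDataError,
    RateSet,
    classify_cohort,
    classify_neuron,
    mann_whitney_u,
    proportion_summary,
    trend_analysis,
)
from poeclab.compare import NeuronClassification


def oracle_exact_p(ra, rb):
    """Independent full-enumeration oracle: U by direct pair counting over all
    label assignments of the pooled sample."""
    pooled = list(ra) + list(rb)
    n_a = len(ra)

    def u_of(subset):
        a_vals = [pooled[i] for i in subset]
        b_vals = [pooled[i] for i in range(len(pooled)) if i not in subset]
        u = 0.0
        for x in a_vals:
            for y in b_vals:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(range(n_a))
    dist = [u_of(s) for s in itertools.combinations(range(len(pooled)), n_a)]
    total = len(dist)
    p_low = sum(u <= u_obs + 1e-9 for u in dist) / total
    p_high = sum(u >= u_obs - 1e-9 for u in dist) / total
    return min(1.0, 2.0 * min(p_low, p_high))


def permutation_p(ra, rb, n_resamples, seed):
    """Vectorised Monte-Carlo permutation oracle for the two-sided test."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([ra, rb])
    n_a = ra.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mu = n_a * rb.size / 2.0
    perms = rng.permuted(np.tile(ranks, (n_resamples, 1)), axis=1)[:, :n_a]
    u_null = perms.sum(axis=1) - n_a * (n_a + 1) / 2
    return np.mean(np.abs(u_null - mu) >= abs(u_obs - mu) - 1e-9)


class TestMannWhitney:
    def test_separated_sets_exact_p(self):
        res = mann_whitney_u(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.u_a == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 arrangements
        assert res.method == "exact"

    def test_identical_multisets_p_one(self):
        res = mann_whitney_u(np.array([1.0, 1, 2]), np.array([1.0, 1, 2]))
        assert res.p_value == 1.0

    def test_u_sum_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            ra = rng.integers(0, 5, rng.integers(2, 12)).astype(float)
            rb = rng.integers(0, 5, rng.integers(2, 12)).astype(float)
            res = mann_whitney_u(ra, rb)
            assert res.u_a + res.u_b == pytest.approx(ra.size * rb.size)

    def test_exact_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(1)
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                for _ in range(8):
                    # small integer support forces ties
                    ra = rng.integers(0, 4, n_a).astype(float)
                    rb = rng.integers(0, 4, n_b).astype(float)
                    res = mann_whitney_u(ra, rb, mode="exact")
                    assert res.p_value == pytest.approx(oracle_exact_p(ra, rb)), (ra, rb)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            ra = rng.normal(size=6)
            rb = rng.normal(size=5)
            res = mann_whitney_u(ra, rb, mode="exact")
            ref = stats.mannwhitneyu(ra, rb, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_normal_approx_close_to_permutation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ra = rng.normal(0.0, 1.0, 30)
            rb = rng.normal(0.4, 1.0, 30)
            res = mann_whitney_u(ra, rb, mode="normal_approx")
            p_perm = permutation_p(ra, rb, n_resamples=20_000, seed=4)
            assert abs(res.p_value - p_perm) < 0.015

    def test_normal_approx_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        ra = rng.normal(0, 1, 40)
        rb = np.round(rng.normal(0.3, 1, 35), 1)  # some ties after rounding
        res = mann_whitney_u(np.round(ra, 1), rb, mode="normal_approx")
        ref = stats.mannwhitneyu(np.round(ra, 1), rb, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney_u(np.array([]), np.array([1.0]))

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=7),
        st.lists(st.integers(0, 6), min_size=1, max_size=7),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_p_in_unit_interval_and_symmetric(self, a, b):
        ra, rb = np.asarray(a, float), np.asarray(b, float)
        res_ab = mann_whitney_u(ra, rb)
        res_ba = mann_whitney_u(rb, ra)
        assert 0.0 <= res_ab.p_value <= 1.0
        assert res_ab.p_value == pytest.approx(res_ba.p_value)
        assert res_ab.u_a == pytest.approx(res_ba.u_b)


def _rs(neuron_id, condition, rates):
    return RateSet(neuron_id=neuron_id, condition=condition, rates=np.asarray(rates, float))


class TestClassification:
    def test_dominating_set_labelled_increased(self):
        rng = np.random.default_rng(6)
        r_on = _rs(0, "on", rng.lognormal(0, 0.2, 30))
        r_off = _rs(0, "off", 2.0 * rng.lognormal(0, 0.2, 30))
        cls = classify_neuron(r_off, r_on)
        assert cls.label == "increased" and cls.p_value < 0.05

    def test_non_significant_is_other(self):
        rng = np.random.default_rng(7)
        r_on = _rs(0, "on", rng.lognormal(0, 0.3, 10))
        r_off = _rs(0, "off", rng.lognormal(0, 0.3, 10))
        cls = classify_neuron(r_off, r_on)
        if cls.p_value >= 0.05:
            assert cls.label == "other"

    def test_insufficient_events_flagged(self):
        cls = classify_neuron(_rs(0, "off", [0.5, 0.6]), _rs(0, "on", [0.4] * 10))
        assert cls.label == "other" and cls.reason == "insufficient"
        assert np.isnan(cls.p_value)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.lognormal(0, 0.3, 15)
            b = rng.lognormal(0.5, 0.3, 15)
            fwd = classify_neuron(_rs(0, "off", a), _rs(0, "on", b))
            rev = classify_neuron(_rs(0, "off", b), _rs(0, "on", a))
            flip = {"increased": "decreased", "decreased": "increased", "other": "other"}
            assert rev.label == flip[fwd.label]

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(9)
        flagged = 0
        n = 500
        for _ in range(n):
            a = rng.lognormal(0, 0.25, 30)
            b = rng.lognormal(0, 0.25, 30)
            if classify_neuron(_rs(0, "off", a), _rs(0, "on", b)).label != "other":
                flagged += 1
        band = 2 * np.sqrt(0.05 * 0.95 / n)
        assert abs(flagged / n - 0.05) < band

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(10)
        correct = []
        for mult in (1.2, 1.5, 2.0):
            hits = 0
            for _ in range(150):
                a = mult * rng.lognormal(0, 0.25, 30)
                b = rng.lognormal(0, 0.25, 30)
                hits += classify_neuron(_rs(0, "off", a), _rs(0, "on", b)).label == "increased"
            correct.append(hits / 150)
        assert correct[0] <= correct[1] <= correct[2]


class TestTrendAndProportions:
    def _cls(self, comparison, label):
        return NeuronClassification(
            neuron_id=1, comparison=comparison, label=label, p_value=0.01,
            median_a=1.0, median_b=0.5, n_a=10, n_b=10,
        )

    @pytest.mark.parametrize(
        "off_label,fixed_label,expected",
        [
            ("increased", "increased", "consistent_up"),
            ("decreased", "decreased", "consistent_down"),
            ("increased", "decreased", "none"),
            ("increased", "other", "none"),
            ("other", "other", "none"),
        ],
    )
    def test_trend_requires_agreement(self, off_label, fixed_label, expected):
        tr = trend_analysis(
            self._cls("off_vs_on", off_label),
            self._cls("fixed_vs_on", fixed_label),
            medians={"on": 0.5, "off": 1.0, "fixed": 1.2},
        )
        assert tr.trend == expected

    def test_trend_median_ordering_mode(self):
        tr = trend_analysis(
            self._cls("off_vs_on", "other"),
            self._cls("fixed_vs_on", "other"),
            medians={"on": 0.5, "off": 1.0, "fixed": 1.2},
            require_significance=False,
        )
        assert tr.trend == "consistent_up"

    def test_proportions_match_counts(self):
        rows = (
            [{"comparison": "off_vs_on", "label": "increased"}] * 4
            + [{"comparison": "off_vs_on", "label": "decreased"}] * 9
            + [{"comparison": "off_vs_on", "label": "other"}] * 87
        )
        props = proportion_summary(pd.DataFrame(rows))
        row = props.iloc[0]
        assert (row["pct_increased"], row["pct_decreased"], row["pct_other"]) == (4.0, 9.0, 87.0)

    def test_proportions_sum_to_100(self):
        rng = np.random.default_rng(11)
        rows = [
            {"comparison": "off_vs_on", "label": rng.choice(["increased", "decreased", "other"])}
            for _ in range(37)
        ]
        props = proportion_summary(pd.DataFrame(rows))
        total = props[["pct_increased", "pct_decreased", "pct_other"]].sum(axis=1)
        assert np.allclose(total, 100.0)

    def test_classify_cohort_both_comparisons(self):
        rng = np.random.default_rng(12)
        rate_sets = []
        for nid in range(5):
            for cond in ("on", "off", "fixed"):
                rate_sets.append(_rs(nid, cond, rng.lognormal(0, 0.3, 12)))
        df = classify_cohort(rate_sets)
        assert set(df["comparison"]) == {"off_vs_on", "fixed_vs_on"}
        assert len(df) == 10

    def test_classify_cohort_bh_is_more_conservative(self):
        rng = np.random.default_rng(13)
        rate_sets = []
        for nid in range(40):
            shift = 1.6 if nid < 5 else 1.0
            rate_sets.append(_rs(nid, "on", rng.lognormal(0, 0.3, 15)))
            rate_sets.append(_rs(nid, "off", shift * rng.lognormal(0, 0.3, 15)))
            rate_sets.append(_rs(nid, "fixed", rng.lognormal(0, 0.3, 15)))
        plain = classify_cohort(rate_sets, adjust="none")
        bh = classify_cohort(rate_sets, adjust="bh")
        n_sig = (plain["label"] != "other").sum()
        n_sig_bh = (bh["label"] != "other").sum()
        assert n_sig_bh <= n_sig
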