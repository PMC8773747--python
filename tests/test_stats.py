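import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from nirstress import classify_by_saa, compare_three_groups, compare_two_groups, correlate
from nirstress.stats import DegenerateDataError, dunnett_t3, smm_cdf
from nirstress.validation import two_group_power


class TestClassification:
    @pytest.mark.parametrize(
        "saa,two,three",
        [
            (12.73, "control", "control"),
            (37.82, "stress", "eustress"),
            (61.82, "stress", "distress"),
            (30.0, "unclassified", "unclassified"),  # 28-33 gap
            (0.0, "control", "control"),
            (28.0, "unclassified", "unclassified"),  # boundaries exclusive
            (33.0, "unclassified", "unclassified"),
            (44.0, "unclassified", "unclassified"),
        ],
    )
    def test_threshold_assignment(self, saa, two, three):
        a = classify_by_saa(saa)
        assert (a.two_group, a.three_group) == (two, three)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_by_saa(-1.0)

    @settings(max_examples=300, derandomize=True)
    @given(saa=st.floats(min_value=0.0, max_value=200.0, allow_nan=False))
    def test_three_group_refines_two_group(self, saa):
        a = classify_by_saa(saa)
        if a.three_group in ("eustress", "distress"):
            assert a.two_group == "stress"
        elif a.three_group == "control":
            assert a.two_group == "control"
        else:
            assert a.two_group == "unclassified"


class TestTwoGroups:
    def test_identical_groups(self):
        rep = compare_two_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_separated_groups(self, rng):
        a = np.zeros(4) + rng.normal(0, 1e-3, 4)
        b = np.full(4, 10.0) + rng.normal(0, 1e-3, 4)
        rep = compare_two_groups({"a": a, "b": b})
        assert rep.p_value < 1e-6
        assert rep.levene_p is not None

    def test_agrees_with_closed_form_toy(self):
        a, b = [0.0, 2.0], [3.0, 5.0]
        rep = compare_two_groups({"a": a, "b": b})
        t_ref, p_ref = sst.ttest_ind(a, b)
        assert rep.statistic == pytest.approx(t_ref)
        assert rep.p_value == pytest.approx(p_ref)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_two_groups({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_welch_chosen_for_unequal_variances(self, rng):
        a = rng.normal(0, 0.1, 50)
        b = rng.normal(0, 10.0, 50)
        rep = compare_two_groups({"a": a, "b": b})
        assert rep.variant == "welch"

    def test_reported_questionnaire_effect_detectable(self):
        """Trait-anxiety scores at the reported group means/SDs (41.3+-9.3 vs
        50.1+-10.2, n=22/22) yield median p below 0.05 across replicates."""
        median_p, power = two_group_power(41.32, 9.27, 50.14, 10.24, 22, 1000, seed=99)
        assert median_p < 0.05
        assert power > 0.5


class TestThreeGroups:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        rep = compare_three_groups({"a": g, "b": g, "c": g})
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_agrees_with_closed_form_toy(self):
        groups = {"a": [0.0, 2.0], "b": [3.0, 5.0], "c": [10.0, 14.0]}
        rep = compare_three_groups(groups, run_posthoc=False)
        f_ref, p_ref = sst.f_oneway(*groups.values())
        assert rep.statistic == pytest.approx(f_ref)
        assert rep.p_value == pytest.approx(p_ref)

    def test_outlier_group_detected_by_posthoc(self, rng):
        groups = {
            "a": rng.normal(0, 1, 11),
            "b": rng.normal(0, 1, 11),
            "c": rng.normal(10, 1, 11),
        }
        rep = compare_three_groups(groups)
        assert rep.p_value < 1e-6
        by_pair = {frozenset((c.group_a, c.group_b)): c.p_value for c in rep.posthoc}
        assert by_pair[frozenset(("a", "c"))] < 0.001
        assert by_pair[frozenset(("b", "c"))] < 0.001
        assert by_pair[frozenset(("a", "b"))] > 0.05

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_three_groups({"a": [1, 2], "b": [3, 4]})


class TestDunnettT3:
    def test_smm_reduces_to_t_for_single_comparison(self):
        for df in (5.0, 20.0):
            q = 2.0
            assert smm_cdf(q, 1, df) == pytest.approx(1 - 2 * sst.t.sf(q, df), abs=1e-9)

    def test_p_monotone_in_mean_difference(self):
        """Holding variances fixed, larger mean separation gives smaller T3 p."""
        rng = np.random.default_rng(0)
        base = rng.standard_normal(11)
        base -= base.mean()
        ps = []
        for delta in (0.5, 1.0, 2.0, 4.0):
            groups = {"a": base, "b": base + delta, "c": base - 0.1}
            comp = [c for c in dunnett_t3(groups) if {c.group_a, c.group_b} == {"a", "b"}][0]
            ps.append(comp.p_value)
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_p_more_conservative_than_welch(self):
        """The SMM reference with k=3 gives larger p than an uncorrected
        pairwise Welch test."""
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(m, 1, 11) for g, m in zip("abc", (0.0, 0.8, 0.4))}
        for c in dunnett_t3(groups):
            a, b = groups[c.group_a], groups[c.group_b]
            _, p_welch = sst.ttest_ind(a, b, equal_var=False)
            assert c.p_value >= p_welch - 1e-12


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_p_from_t_distribution(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        r, p = correlate(x, y)
        t = r * np.sqrt(28 / (1 - r**2))
        assert p == pytest.approx(2 * sst.t.sf(abs(t), 28), rel=1e-9)

    def test_degenerate_and_short_rejected(self):
        with pytest.raises(DegenerateDataError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])
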