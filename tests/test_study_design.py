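import math

import numpy as np
import pytest
from scipy import stats

from nntplan import (
    BinomialOutcome,
    DiscomfortRange,
    DomainError,
    InfeasibleError,
    IntervalEstimate,
    McSettings,
    NNTPair,
    Prevalence,
    ProspectiveDesign,
    RetrospectiveDesign,
    anticipated_prospective_counts,
    bayes_forward,
    bayes_predictive_nnt_intervals,
    exact_binomial_ci,
    minimum_n_search,
    nnt_interval_from_pv_interval,
    nnt_pair_from_predictive_values,
    prospective_summary,
    retrospective_summary,
    round_half_up,
    TestCharacteristics,
)
from nntplan.study_design import EXACT_BINOMIAL, _smallest_clearing_n, _round_half_away


class TestExactBinomialCI:
    @pytest.mark.parametrize("x, n, lo_pct, hi_pct", [
        (5, 10, 19, 81),     # anticipated PPV arm of the CTCL prospective design
        (29, 30, 83, 100),   # anticipated NPV arm
        (18, 22, 60, 95),    # anticipated sensitivity, retrospective design
        (34, 40, 70, 94),    # anticipated specificity
    ])
    def test_whole_percent_endpoints(self, x, n, lo_pct, hi_pct):
        ci = exact_binomial_ci(BinomialOutcome(x, n), 0.95)
        assert round_half_up(100 * ci.lower) == lo_pct
        assert round_half_up(100 * ci.upper) == hi_pct
        assert ci.method == EXACT_BINOMIAL

    def test_degenerate_endpoints_exact(self):
        assert exact_binomial_ci(BinomialOutcome(0, 7)).lower == 0.0
        assert exact_binomial_ci(BinomialOutcome(7, 7)).upper == 1.0

    @pytest.mark.parametrize("bad_level", [0.0, 1.0, -0.1, 1.7])
    def test_level_validation(self, bad_level):
        with pytest.raises(DomainError):
            exact_binomial_ci(BinomialOutcome(3, 9), bad_level)

    @pytest.mark.parametrize("x, n", [(5, 10), (18, 22), (0, 4), (4, 4), (1, 17)])
    def test_matches_independent_implementation(self, x, n):
        """Cross-check against statsmodels' beta-quantile interval."""
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
        ci = exact_binomial_ci(BinomialOutcome(x, n), 0.95)
        assert ci.lower == pytest.approx(float(lo), abs=1e-10, rel=1e-10)
        assert ci.upper == pytest.approx(float(hi), abs=1e-10, rel=1e-10)

    def test_coverage_is_conservative_small_n(self):
        """Exhaustive enumeration: coverage >= nominal for n <= 25."""
        level = 0.95
        for n in range(1, 26):
            ks = np.arange(n + 1)
            bounds = np.array([
                [exact_binomial_ci(BinomialOutcome(int(k), n), level).lower,
                 exact_binomial_ci(BinomialOutcome(int(k), n), level).upper]
                for k in ks
            ])
            for p in np.linspace(0.02, 0.98, 25):
                pmf = stats.binom.pmf(ks, n, p)
                covered = (bounds[:, 0] <= p) & (p <= bounds[:, 1])
                assert pmf[covered].sum() >= level - 1e-12


class TestNntIntervalTransform:
    def test_ppv_interval_to_nnt_pos(self):
        ci = exact_binomial_ci(BinomialOutcome(5, 10), 0.95)
        nnt = nnt_interval_from_pv_interval(ci, "pos")
        assert round_half_up(nnt.lower, 2) == 1.23
        assert round_half_up(nnt.upper, 2) == 5.35

    def test_npv_interval_to_nnt_neg(self):
        ci = exact_binomial_ci(BinomialOutcome(29, 30), 0.95)
        nnt = nnt_interval_from_pv_interval(ci, "neg")
        assert round_half_up(nnt.lower, 2) == 5.81
        assert nnt.upper > 1000  # NPV upper endpoint very close to 1

    def test_point_interval(self):
        iv = IntervalEstimate(1.0, 1.0, 0.95, EXACT_BINOMIAL)
        nnt = nnt_interval_from_pv_interval(iv, "pos")
        assert (nnt.lower, nnt.upper) == (1.0, 1.0)

    def test_npv_one_gives_infinite_upper(self):
        iv = IntervalEstimate(0.9, 1.0, 0.95, EXACT_BINOMIAL)
        nnt = nnt_interval_from_pv_interval(iv, "neg")
        assert math.isinf(nnt.upper)

    def test_zero_lower_rejected_on_positive_side(self):
        iv = IntervalEstimate(0.0, 0.4, 0.95, EXACT_BINOMIAL)
        with pytest.raises(DomainError):
            nnt_interval_from_pv_interval(iv, "pos")

    def test_transform_preserves_containment(self):
        """The point-estimate NNT lies inside the transformed interval."""
        for x, n in [(5, 10), (18, 22), (3, 11)]:
            ci = exact_binomial_ci(BinomialOutcome(x, n))
            nnt = nnt_interval_from_pv_interval(ci, "pos")
            assert nnt.lower <= n / x <= nnt.upper


class TestAnticipatedCounts:
    def test_ctcl_arms(self, ctcl_prospective):
        pos, neg = anticipated_prospective_counts(ctcl_prospective)
        assert (pos.successes, pos.trials) == (5, 10)
        assert (neg.successes, neg.trials) == (29, 30)

    def test_perfect_test(self):
        d = ProspectiveDesign(40, 0.25, NNTPair(1, math.inf))
        pos, neg = anticipated_prospective_counts(d)
        assert (pos.successes, pos.trials) == (10, 10)
        assert (neg.successes, neg.trials) == (30, 30)

    def test_rounding_path(self):
        d = ProspectiveDesign(100, 0.2, NNTPair(4, 50))
        pos, neg = anticipated_prospective_counts(d)
        assert (pos.successes, pos.trials) == (5, 20)
        assert (neg.successes, neg.trials) == (78, 80)


class TestProspectiveSummary:
    def test_ctcl_composition(self, ctcl_prospective, ctcl_range):
        rep = prospective_summary(ctcl_prospective, 0.95, ctcl_range)
        assert round_half_up(rep.nnt_pos_ci.lower, 2) == 1.23
        assert round_half_up(rep.nnt_pos_ci.upper, 2) == 5.35
        assert round_half_up(rep.nnt_neg_ci.lower, 2) == 5.81
        # 40 patients are far too few for the intervals to clear the range
        assert rep.clears_positive is False
        assert rep.clears_negative is False

    def test_matches_manual_composition(self):
        d = ProspectiveDesign(100, 0.2, NNTPair(4, 50))
        rep = prospective_summary(d)
        pos, neg = anticipated_prospective_counts(d)
        assert rep.ppv_ci == exact_binomial_ci(pos)
        assert rep.nnt_neg_ci == nnt_interval_from_pv_interval(exact_binomial_ci(neg), "neg")

    def test_perfect_test_degenerate_bounds(self):
        d = ProspectiveDesign(40, 0.25, NNTPair(1, math.inf))
        rep = prospective_summary(d)
        assert rep.ppv_ci.upper == 1.0
        assert rep.nnt_pos_ci.lower == 1.0
        assert math.isinf(rep.nnt_neg_ci.upper)


class TestBayesPredictiveIntervals:
    def test_reproducible_for_fixed_seed(self, ctcl_retrospective):
        mc = McSettings(n_draws=20_000, seed=77)
        a = bayes_predictive_nnt_intervals(ctcl_retrospective, 0.95, mc)
        b = bayes_predictive_nnt_intervals(ctcl_retrospective, 0.95, mc)
        assert a == b

    def test_independent_seeds_agree(self, ctcl_retrospective):
        a_pos, a_neg = bayes_predictive_nnt_intervals(
            ctcl_retrospective, 0.95, McSettings(100_000, seed=1))
        b_pos, b_neg = bayes_predictive_nnt_intervals(
            ctcl_retrospective, 0.95, McSettings(100_000, seed=2))
        for a, b in [(a_pos, b_pos), (a_neg, b_neg)]:
            assert a.lower == pytest.approx(b.lower, rel=0.02)
            assert a.upper == pytest.approx(b.upper, rel=0.02)

    def test_concentrates_at_scaled_counts(self, ctcl_prevalence):
        """With counts x1000 the intervals pin down the plug-in NNTs."""
        big = RetrospectiveDesign(
            n_cases=22_000, n_controls=40_000,
            anticipated_sn=BinomialOutcome(18_000, 22_000),
            anticipated_sp=BinomialOutcome(34_000, 40_000),
            prevalence=ctcl_prevalence,
        )
        pv = bayes_forward(TestCharacteristics(18 / 22, 34 / 40), ctcl_prevalence)
        point = nnt_pair_from_predictive_values(pv)
        pi_pos, pi_neg = bayes_predictive_nnt_intervals(big, 0.95, McSettings(50_000, 3))
        assert pi_pos.lower < point.nnt_pos < pi_pos.upper
        assert pi_neg.lower < point.nnt_neg < pi_neg.upper
        assert pi_pos.width < 0.05 * point.nnt_pos
        assert pi_neg.width < 0.15 * point.nnt_neg

    def test_width_shrinks_with_sample_size(self, ctcl_prevalence):
        widths = []
        for scale in (1, 4, 16):
            d = RetrospectiveDesign(
                n_cases=22 * scale, n_controls=40 * scale,
                anticipated_sn=BinomialOutcome(18 * scale, 22 * scale),
                anticipated_sp=BinomialOutcome(34 * scale, 40 * scale),
                prevalence=ctcl_prevalence,
            )
            pos, neg = bayes_predictive_nnt_intervals(d, 0.95, McSettings(40_000, 5))
            widths.append((pos.width, neg.width))
        assert widths[0][0] > widths[1][0] > widths[2][0]
        assert widths[0][1] > widths[1][1] > widths[2][1]

    def test_small_draw_count_warns(self, ctcl_retrospective):
        with pytest.warns(UserWarning, match="small"):
            bayes_predictive_nnt_intervals(ctcl_retrospective, 0.95, McSettings(500, 1))


class TestRetrospectiveSummary:
    def test_ctcl_requirements_and_intervals(self, ctcl_retrospective, ctcl_range):
        rep = retrospective_summary(
            ctcl_retrospective, 0.95, McSettings(50_000, 9), ctcl_range)
        assert round_half_up(100 * rep.sn_ci.lower) == 60
        assert round_half_up(100 * rep.sn_ci.upper) == 95
        assert round_half_up(100 * rep.sp_ci.lower) == 70
        assert round_half_up(100 * rep.sp_ci.upper) == 94
        assert round_half_up(100 * rep.required.sensitivity, 1) == 83.3
        assert round_half_up(100 * rep.required.specificity, 1) == 85.3
        # anticipated SN = 81.8% falls short of the required 83.3%
        assert rep.meets_required_sn is False
        assert rep.meets_required_sp is False

    def test_all_correct_counts(self, ctcl_prevalence):
        d = RetrospectiveDesign(
            n_cases=22, n_controls=40,
            anticipated_sn=BinomialOutcome(22, 22),
            anticipated_sp=BinomialOutcome(40, 40),
            prevalence=ctcl_prevalence,
        )
        rep = retrospective_summary(d, 0.95, McSettings(10_000, 4))
        assert rep.sn_ci.upper == 1.0
        assert rep.sp_ci.upper == 1.0

    def test_composition_consistency(self, ctcl_retrospective):
        mc = McSettings(20_000, 11)
        rep = retrospective_summary(ctcl_retrospective, 0.95, mc)
        assert rep.sn_ci == exact_binomial_ci(ctcl_retrospective.anticipated_sn)
        assert (rep.nnt_pos_pi, rep.nnt_neg_pi) == bayes_predictive_nnt_intervals(
            ctcl_retrospective, 0.95, mc)
        assert rep.required is None


class TestMinimumNSearch:
    def test_matches_brute_force_scan(self):
        target, dr = NNTPair(1.2, 200), DiscomfortRange(3, 20)
        res = minimum_n_search(target, dr, "prospective")

        def brute(p_hat, threshold):
            n = 2
            while True:
                x = min(max(_round_half_away(n * p_hat), 0), n)
                if exact_binomial_ci(BinomialOutcome(x, n), 0.95).lower > threshold:
                    return n
                n += 1

        assert res.n_first == brute(1 / 1.2, 1 / 3)
        assert res.n_second == brute(1 - 1 / 200, 1 - 1 / 20)

    def test_boundary_target_infeasible(self):
        with pytest.raises(InfeasibleError):
            minimum_n_search(NNTPair(3, 25), DiscomfortRange(3, 20), "prospective")

    def test_easy_target_needs_small_n(self):
        res = minimum_n_search(NNTPair(1.1, 1000), DiscomfortRange(8, 16), "prospective")
        assert res.n_first <= 5
        assert res.n_second <= 100

    def test_moderate_margin_has_finite_n(self):
        res = minimum_n_search(NNTPair(2, 30), DiscomfortRange(2.5, 25), "prospective")
        assert res.n_first > 10 and res.n_second > 10
        assert res.shape == "prospective"

    def test_retrospective_shape_requires_prevalence(self):
        with pytest.raises(DomainError):
            minimum_n_search(NNTPair(1.5, 50), DiscomfortRange(2, 30), "retrospective")

    def test_retrospective_shape(self):
        res = minimum_n_search(
            NNTPair(1.5, 50), DiscomfortRange(2, 30), "retrospective",
            prevalence=Prevalence(0.15),
        )
        assert res.shape == "retrospective"
        assert res.n_first >= 2 and res.n_second >= 2
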