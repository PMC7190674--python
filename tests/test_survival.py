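"""Kaplan-Meier, log-rank and best-cutoff tests against hand tables and
lifelines as an independent implementation."""

import numpy as np
import pandas as pd
import pytest

from spliceomix.survival import (best_cutoff, km_curve, logrank,
                                 permutation_logrank,
                                 signature_survival_report)


def ph_cohort(rng, n, beta=1.0, censor_time=2.0):
    """Exponential PH data with a standard-normal score."""
    score = rng.normal(0, 1, n)
    t = rng.exponential(1.0 / np.exp(beta * score))
    c = rng.uniform(0, censor_time, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    time = np.maximum(time, 1e-9)
    return score, time, event


class TestKM:
    def test_hand_table_no_censoring(self):
        # deaths at 1, 2, 3 out of 3 -> S = 2/3, 1/3, 0
        curve = km_curve([1, 2, 3], [1, 1, 1])
        assert curve.event_times.tolist() == [1, 2, 3]
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_hand_table_with_censoring(self):
        # classic example: events at 1 and 4; censored at 2 and 5
        # S(1) = 3/4 (4 at risk), S(4) = 3/4 * 1/2 (2 at risk at t=4)
        curve = km_curve([1, 2, 4, 5], [1, 0, 1, 0])
        assert curve.event_times.tolist() == [1, 4]
        assert curve.survival == pytest.approx([0.75, 0.375])

    def test_censored_at_event_time_still_at_risk(self):
        # at t=2: one event, one censored exactly at 2 -> both at risk
        curve = km_curve([2, 2, 3], [1, 0, 1])
        assert curve.at_risk[0] == 3
        assert curve.survival_at(2) == pytest.approx(2 / 3)

    def test_survival_at_is_right_continuous_step(self):
        curve = km_curve([1, 2, 3], [1, 1, 1])
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(1.5) == pytest.approx(2 / 3)
        assert curve.survival_at(100) == 0.0

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(1.0, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        curve = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(curve.survival, index=curve.event_times)
        theirs = kmf.survival_function_["KM_estimate"]
        for u, s in ours.items():
            assert s == pytest.approx(theirs.loc[u], abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_curve([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError, match="0 or 1"):
            km_curve([1.0, 2.0], [1, 2])
        with pytest.raises(ValueError, match="no survival records"):
            km_curve([], [])


class TestLogRank:
    def test_four_subject_worked_example_statistic_three(self):
        # group A: events at t=1,1; group B: events at t=2,2
        # t=1: O_A=2, E_A=1, V=4*(1/2)(1/2)*2/3 = 2/3... summed V=1/3? no:
        # computed by hand: (O-E)=1, V=1/3 only after t=2 contributes 0 and
        # t=1 contributes d(nA/n)(1-nA/n)(n-d)/(n-1) = 2*(1/2)(1/2)(2/3)=1/3
        res = logrank([1, 1], [1, 1], [2, 2], [1, 1])
        assert res.statistic == pytest.approx(3.0)
        assert res.observed == pytest.approx((2.0, 2.0))
        assert res.expected == pytest.approx((1.0, 3.0))

    def test_identical_groups_give_zero_statistic(self):
        res = logrank([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test

        for _ in range(10):
            ta = rng.exponential(1.0, 40)
            tb = rng.exponential(1.6, 35)
            ea = rng.integers(0, 2, 40)
            eb = rng.integers(0, 2, 35)
            if ea.sum() + eb.sum() == 0:
                continue
            ours = logrank(ta, ea, tb, eb)
            theirs = logrank_test(ta, tb, event_observed_A=ea,
                                  event_observed_B=eb)
            assert ours.statistic == pytest.approx(theirs.test_statistic,
                                                   abs=1e-8)
            assert ours.p_value == pytest.approx(theirs.p_value, abs=1e-8)

    def test_no_events_anywhere_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank([1, 2], [0, 0], [3, 4], [0, 0])

    def test_permutation_p_close_to_asymptotic_at_moderate_n(self, rng):
        ta = rng.exponential(1.0, 15)
        tb = rng.exponential(2.5, 15)
        res = permutation_logrank(ta, np.ones(15, int), tb,
                                  np.ones(15, int),
                                  n_permutations=10_000, seed=3)
        assert res.permutation_p == pytest.approx(res.p_value, abs=0.02)

    def test_permutation_p_never_zero(self):
        res = permutation_logrank([1, 1, 1], [1, 1, 1], [9, 9, 9],
                                  [1, 1, 1], n_permutations=500, seed=0)
        assert res.permutation_p >= 1 / 501


class TestBestCutoff:
    def test_candidates_respect_quantile_bounds(self, rng):
        score, t, e = ph_cohort(rng, 120)
        scan = best_cutoff(score, t, e, quantile_bounds=(0.10, 0.90))
        lo, hi = np.quantile(score, [0.10, 0.90])
        assert scan.candidates.min() >= lo
        assert scan.candidates.max() <= hi

    def test_chosen_p_is_scan_minimum(self, rng):
        score, t, e = ph_cohort(rng, 80)
        scan = best_cutoff(score, t, e)
        assert scan.chosen_p == scan.p_values.min()
        # exhaustively re-run the log-rank at the chosen threshold
        high = score > scan.chosen_cutoff
        res = logrank(t[high], e[high], t[~high], e[~high])
        assert res.p_value == pytest.approx(scan.chosen_p)

    def test_tie_resolves_to_smallest_cutoff(self):
        # two thresholds that produce identical group splits
        score = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        t = np.array([1.0, 1.5, 2.0, 5.0, 6.0, 7.0])
        e = np.ones(6, int)
        scan = best_cutoff(score, t, e, quantile_bounds=(0.0, 1.0))
        dup = pd.Series(scan.p_values).round(15)
        if dup.duplicated().any():
            first_dup_p = dup[dup.duplicated(keep=False)].iloc[0]
            chosen_among = scan.candidates[scan.p_values == scan.chosen_p]
            if scan.chosen_p == first_dup_p:
                assert scan.chosen_cutoff == chosen_among.min()

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="all scores equal"):
            best_cutoff([1.0, 1.0, 1.0], [1, 2, 3], [1, 1, 1])

    def test_strong_signal_beats_median_split_p(self, rng):
        score, t, e = ph_cohort(rng, 150, beta=1.2)
        scan = best_cutoff(score, t, e)
        med = np.median(score)
        high = score > med
        p_med = logrank(t[high], e[high], t[~high], e[~high]).p_value
        assert scan.chosen_p <= p_med + 1e-12


class TestSurvivalReport:
    def cohort_frame(self, rng, n=120, beta=1.0):
        score, t, e = ph_cohort(rng, n, beta=beta)
        idx = [f"P{i}" for i in range(n)]
        return (pd.Series(score, index=idx),
                pd.DataFrame({"time": t, "event": e}, index=idx))

    def test_high_risk_score_labelled_unfavorable(self, rng):
        scores, clin = self.cohort_frame(rng, beta=1.5)
        rep = signature_survival_report(scores, clin, split="median")
        assert rep.direction == "unfavorable"
        assert rep.logrank.p_value < 0.01

    def test_protective_score_labelled_favorable(self, rng):
        scores, clin = self.cohort_frame(rng, beta=-1.5)
        rep = signature_survival_report(scores, clin, split="median")
        assert rep.direction == "favorable"

    def test_best_cutoff_split_attaches_scan(self, rng):
        scores, clin = self.cohort_frame(rng)
        rep = signature_survival_report(scores, clin, split="best-cutoff")
        assert rep.cutoff_scan is not None
        assert rep.logrank.p_value == pytest.approx(rep.cutoff_scan.chosen_p)

    def test_permutation_adjusted_p_exceeds_minimal_p_under_null(self, rng):
        # under a null score the minimal-p scan is anti-conservative; the
        # permutation-adjusted p must be materially larger
        scores, clin = self.cohort_frame(rng, beta=0.0)
        rep = signature_survival_report(scores, clin, split="best-cutoff",
                                        permutation_adjust=True,
                                        n_permutations=200, seed=5)
        assert rep.permutation_adjusted_p is not None
        assert rep.permutation_adjusted_p > rep.cutoff_scan.chosen_p

    def test_unknown_split_rejected(self, rng):
        scores, clin = self.cohort_frame(rng)
        with pytest.raises(ValueError, match="unknown split"):
            signature_survival_report(scores, clin, split="tertile")
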