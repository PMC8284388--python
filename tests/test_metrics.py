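"""Evaluation metrics: concordance, Cox HR, reclassification/NRI, KM curves."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from irtpipe.metrics import (
    ReclassificationSummary,
    categorical_nri,
    cox_hr_per_sd,
    cumulative_incidence,
    expected_concordance_exponential,
    harrell_c,
    harrell_c_difference,
    pearson_correlation,
    percentile_rank,
    prs_age_interaction,
    prs_percentile_band,
    reclassification_table,
    threshold_metrics,
)


def brute_force_concordance(score, time, event):
    """O(n^2) pair enumeration: usable iff times differ and the earlier
    observed time is an event; score ties get half credit."""
    num = den = 0.0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if time[i] == time[j] or not event[i] or time[i] > time[j]:
                continue
            den += 1
            if score[i] > score[j]:
                num += 1
            elif score[i] == score[j]:
                num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_ranking_gives_one(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        score = np.array([4.0, 3.0, 2.0, 1.0])
        assert harrell_c(score, time, np.ones(4, bool)).value == 1.0

    def test_constant_score_gives_half(self):
        est = harrell_c(np.ones(6), np.arange(1.0, 7.0), np.ones(6, bool))
        assert est.value == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        score = rng.normal(size=n).round(1)  # rounding provokes score ties
        time = rng.exponential(size=n).round(1)  # and time ties
        event = rng.random(n) < 0.7
        if not event.any():
            event[0] = True
        est = harrell_c(score, time, event)
        assert est.value == pytest.approx(
            brute_force_concordance(score, time, event), rel=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        score = rng.normal(size=15)
        time = rng.exponential(size=15)
        event = rng.random(15) < 0.6
        if not event.any():
            event[0] = True
        c1 = harrell_c(score, time, event).value
        c2 = harrell_c(np.exp(score), time, event).value
        c3 = harrell_c(score**3, time, event).value
        assert c1 == pytest.approx(c2, rel=1e-12)
        assert c1 == pytest.approx(c3, rel=1e-12)

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError):
            harrell_c(np.arange(5.0), np.arange(5.0), np.zeros(5, bool))


class TestHarrellCDifference:
    def test_identical_scores_give_zero_and_p_one(self, rng):
        score = rng.normal(size=30)
        time = rng.exponential(size=30)
        event = rng.random(30) < 0.5
        event[0] = True
        dc, z, p = harrell_c_difference(score, score.copy(), time, event)
        assert dc == 0.0
        assert p == 1.0

    def test_antisymmetry_on_tie_free_toy(self, rng):
        score = rng.normal(size=25)
        time = rng.exponential(size=25)
        event = np.ones(25, bool)
        c = harrell_c(score, time, event).value
        dc, _, _ = harrell_c_difference(score, -score, time, event)
        assert dc == pytest.approx(2.0 * c - 1.0, rel=1e-12)

    def test_refuses_fewer_than_twenty_individuals(self, rng):
        with pytest.raises(ValueError, match="20"):
            harrell_c_difference(
                rng.normal(size=10), rng.normal(size=10),
                rng.exponential(size=10), np.ones(10, bool),
            )

    def test_null_type_one_error_rate(self):
        """Two independent noninformative scores: the jackknife z test
        rejects at ~5%; with 200 replicates the rate stays inside a wide
        binomial band."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 60
            time = rng.exponential(size=n)
            event = rng.random(n) < 0.7
            if not event.any():
                event[0] = True
            _, _, p = harrell_c_difference(
                rng.normal(size=n), rng.normal(size=n), time, event
            )
            rejections += p < 0.05
        # 3-sigma band around 0.05 for 200 draws: ~[0, 0.096]
        assert rejections / reps < 0.10


class TestCoxHrPerSd:
    def test_null_ci_contains_one(self, rng):
        n = 2000
        prs = rng.standard_normal(n)
        time = rng.exponential(1 / 0.02, size=n)
        est = cox_hr_per_sd(prs, np.minimum(time, 10.0), time <= 10.0)
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_matches_partial_likelihood_grid_search_on_toy(self):
        """4 subjects, distinct times, no ties: the fitted log HR equals the
        1-D grid maximizer of the explicitly written partial likelihood."""
        z = np.array([0.5, -0.3, 0.8, -1.0])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, bool)

        def log_pl(beta):
            order = np.argsort(time)
            total = 0.0
            for k, i in enumerate(order):
                risk_set = order[k:]
                total += beta * z[i] - math.log(np.sum(np.exp(beta * z[risk_set])))
            return total

        grid = np.linspace(-4, 4, 80_001)
        beta_grid = grid[np.argmax([log_pl(b) for b in grid])]
        est = cox_hr_per_sd(z, time, event)
        # the predictor is re-standardized internally; undo for comparison
        sd = np.std(z, ddof=1)
        assert math.log(est.value) / sd == pytest.approx(beta_grid, abs=2e-3)

    def test_no_events_is_an_error(self, rng):
        with pytest.raises(ValueError):
            cox_hr_per_sd(rng.normal(size=10), np.arange(1.0, 11.0), np.zeros(10, bool))


class TestReclassification:
    def test_identical_classifications_give_zero_rates(self, rng):
        high = rng.random(100) < 0.3
        event = rng.random(100) < 0.1
        summ = reclassification_table(high, high, event)
        assert summ.fraction_reclassified == 0.0
        assert summ.n == 100

    def test_additivity_of_up_and_down_fractions(self):
        """70 up + 67 down of 1000 reclassified: 7.0% + 6.7% = 13.7%."""
        n = 1000
        old = np.zeros(n, bool)
        new = np.zeros(n, bool)
        new[:70] = True  # up-classified
        old[70:137] = True  # down-classified (new stays low)
        event = np.zeros(n, bool)
        summ = reclassification_table(old, new, event)
        assert summ.fraction_up == pytest.approx(0.070)
        assert summ.fraction_down == pytest.approx(0.067)
        assert summ.fraction_reclassified == pytest.approx(0.137)

    def test_matches_hand_count_on_ten_rows(self):
        old = np.array([0, 0, 1, 1, 0, 1, 0, 0, 1, 0], bool)
        new = np.array([1, 0, 1, 0, 0, 1, 1, 0, 0, 1], bool)
        ev = np.array([1, 0, 1, 1, 0, 0, 0, 0, 1, 1], bool)
        summ = reclassification_table(old, new, ev)
        # hand tally: (old,new,event) counts
        assert summ.counts[0, 1, 1] == 2  # rows 0, 9
        assert summ.counts[0, 1, 0] == 1  # row 6
        assert summ.counts[1, 0, 1] == 2  # rows 3, 8
        assert summ.counts[1, 0, 0] == 0
        assert summ.counts.sum() == 10

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            reclassification_table([True], [True, False], [False, False])


class TestCategoricalNri:
    def test_identical_classifications_give_zero(self, rng):
        high = rng.random(200) < 0.3
        event = rng.random(200) < 0.2
        event[0] = True
        nri = categorical_nri(reclassification_table(high, high, event))
        assert nri["nri"].value == 0.0
        assert nri["nri_events"].value == 0.0
        assert nri["nri_nonevents"].value == 0.0

    def test_event_component_arithmetic(self):
        """104 of 1000 events up, 44 down: event NRI = 10.4% - 4.4% = 6.0%."""
        counts = np.zeros((2, 2, 2), dtype=int)
        counts[0, 1, 1] = 104
        counts[1, 0, 1] = 44
        counts[0, 0, 1] = 1000 - 104 - 44
        counts[0, 0, 0] = 5000  # nonevents, unmoved
        nri = categorical_nri(ReclassificationSummary(counts))
        assert nri["nri_events"].value == pytest.approx(0.060)
        assert nri["nri_nonevents"].value == 0.0
        assert nri["nri"].value == pytest.approx(0.060)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        old = rng.random(50) < 0.4
        new = rng.random(50) < 0.4
        ev = rng.random(50) < 0.5
        ev[0], ev[1] = True, False
        nri = categorical_nri(reclassification_table(old, new, ev), n_resamples=10)
        assert nri["nri"].value == pytest.approx(
            nri["nri_events"].value + nri["nri_nonevents"].value, abs=1e-12
        )

    def test_bootstrap_ci_is_seed_deterministic(self, rng):
        old = rng.random(300) < 0.3
        new = rng.random(300) < 0.3
        ev = rng.random(300) < 0.3
        ev[0], ev[1] = True, False
        summ = reclassification_table(old, new, ev)
        a = categorical_nri(summ, n_resamples=200, seed=7)
        b = categorical_nri(summ, n_resamples=200, seed=7)
        c = categorical_nri(summ, n_resamples=200, seed=8)
        assert (a["nri"].ci_low, a["nri"].ci_high) == (b["nri"].ci_low, b["nri"].ci_high)
        assert (a["nri"].ci_low, a["nri"].ci_high) != (c["nri"].ci_low, c["nri"].ci_high)
        assert a["nri"].ci_low <= a["nri"].value <= a["nri"].ci_high

    def test_empty_class_is_an_error(self):
        counts = np.zeros((2, 2, 2), dtype=int)
        counts[0, 0, 0] = 10
        with pytest.raises(ValueError):
            categorical_nri(ReclassificationSummary(counts))


class TestThresholdMetrics:
    def test_perfect_separation(self):
        risk = np.array([0.9, 0.8, 0.1, 0.2])
        ev = np.array([True, True, False, False])
        tm = threshold_metrics(risk, ev, 0.5)
        assert (tm.sensitivity, tm.specificity, tm.ppv) == (1.0, 1.0, 1.0)

    def test_threshold_zero_classifies_everyone_high(self, rng):
        risk = rng.uniform(0, 1, 50)
        ev = rng.random(50) < 0.3
        ev[0], ev[1] = True, False
        tm = threshold_metrics(risk, ev, 0.0)
        assert tm.sensitivity == 1.0
        assert tm.specificity == 0.0

    def test_hand_two_by_two_on_eight_rows(self):
        risk = np.array([0.09, 0.08, 0.02, 0.10, 0.04, 0.06, 0.11, 0.01])
        ev = np.array([1, 0, 0, 1, 1, 0, 0, 0], bool)
        tm = threshold_metrics(risk, ev, 0.075)
        # predicted high: rows 0,1,3,6 -> TP=2 FP=2 FN=1 TN=3
        assert tm.sensitivity == pytest.approx(2 / 3)
        assert tm.specificity == pytest.approx(3 / 5)
        assert tm.ppv == pytest.approx(2 / 4)

    def test_ppv_undefined_when_no_positives(self):
        tm = threshold_metrics([0.01, 0.02], [True, False], 0.5)
        assert math.isnan(tm.ppv)


class TestCumulativeIncidence:
    def test_all_censored_gives_flat_zero(self):
        curves = cumulative_incidence(
            np.array([1.0, 2.0, 3.0]), np.zeros(3, bool), np.array(["g"] * 3)
        )
        assert (curves["cum_incidence"] == 0.0).all()

    def test_no_censoring_reduces_to_ecdf(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        curves = cumulative_incidence(time, np.ones(4, bool), np.array(["g"] * 4))
        for t, frac in [(1.0, 0.25), (2.0, 0.5), (3.0, 0.75), (4.0, 1.0)]:
            row = curves[(curves.time == t)]
            assert row["cum_incidence"].iloc[0] == pytest.approx(frac)

    def test_matches_hand_product_limit_with_censoring(self):
        """8 subjects, events at 1,3,5,7 with censorings interleaved at
        2,4,6,8: KM survival is the hand-computed product."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([1, 0, 1, 0, 1, 0, 1, 0], bool)
        curves = cumulative_incidence(time, event, np.array(["g"] * 8))
        # S(1)=7/8; S(3)=7/8*5/6; S(5)=7/8*5/6*3/4; S(7)=...*1/2
        hand = {
            1.0: 1 - 7 / 8,
            3.0: 1 - (7 / 8) * (5 / 6),
            5.0: 1 - (7 / 8) * (5 / 6) * (3 / 4),
            7.0: 1 - (7 / 8) * (5 / 6) * (3 / 4) * (1 / 2),
        }
        for t, ci in hand.items():
            got = curves[curves.time == t]["cum_incidence"].iloc[0]
            assert got == pytest.approx(ci, rel=1e-12)
        assert curves["time"].max() <= 8.0  # never extrapolates

    def test_percentile_bands(self):
        pct = np.array([1.0, 50.0, 99.0, 30.0])
        bands = prs_percentile_band(pct)
        assert list(bands) == ["bottom5", "mid40-60", "top5", ""]
        ranks = percentile_rank(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(ranks, [25.0, 50.0, 75.0, 100.0])


class TestPrsAgeInteraction:
    @staticmethod
    def _simulate(n, slope, seed):
        rng = np.random.default_rng(seed)
        prs = rng.standard_normal(n)
        age = rng.uniform(40, 70, n)
        beta_age = 0.48 + slope * (age - 55.0)
        lp = beta_age * prs
        t_event = rng.exponential(1.0 / (0.004 * np.exp(lp)))
        censor = rng.uniform(8, 12, n)
        return prs, age, np.minimum(t_event, censor), t_event <= censor

    def test_constant_effect_interaction_ci_contains_zero(self):
        prs, age, time, event = self._simulate(20_000, 0.0, seed=31)
        est = prs_age_interaction(prs, age, time, event)["pooled"]
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_declining_effect_detected_as_negative(self):
        detected = 0
        for seed in (41, 42, 43):
            prs, age, time, event = self._simulate(30_000, -0.015, seed=seed)
            est = prs_age_interaction(prs, age, time, event)["pooled"]
            detected += est.value < 0 and est.p_value < 0.05
        assert detected >= 2

    def test_refit_determinism_and_per_sex_output(self):
        prs, age, time, event = self._simulate(3_000, 0.0, seed=32)
        sex = np.where(np.arange(3_000) % 2 == 0, "male", "female")
        a = prs_age_interaction(prs, age, time, event, sex=sex)
        b = prs_age_interaction(prs, age, time, event, sex=sex)
        assert set(a) == {"pooled", "male", "female"}
        assert a["pooled"].value == b["pooled"].value

    def test_constant_age_is_an_error(self, rng):
        with pytest.raises(ValueError, match="constant"):
            prs_age_interaction(
                rng.normal(size=50), np.full(50, 55.0),
                rng.exponential(size=50), np.ones(50, bool),
            )


class TestPearsonAndOracle:
    def test_identity_and_sign_flip(self, rng):
        x = rng.normal(size=20)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_five_pair_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        sx, sy = x - x.mean(), y - y.mean()
        expected = np.sum(sx * sy) / math.sqrt(np.sum(sx**2) * np.sum(sy**2))
        assert pearson_correlation(x, y) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), rng.normal(size=5))

    def test_closed_form_concordance_oracle(self):
        assert expected_concordance_exponential(1.0) == 0.5
        # per-SD log-hazard 0.48 (~HR 1.62) corresponds to C ~ 0.63
        assert expected_concordance_exponential(1.62) == pytest.approx(0.63, abs=0.005)
        # monotone in the hazard ratio
        cs = [expected_concordance_exponential(h) for h in (1.0, 1.3, 1.62, 2.0, 3.0)]
        assert all(b > a for a, b in zip(cs, cs[1:]))
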