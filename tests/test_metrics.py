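"""Censoring-aware metrics against brute-force and library oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index
from sklearn.metrics import average_precision_score

from censorbench import (
    ap_t,
    auc_t,
    bootstrap_ci,
    calibration_curve,
    censoring_concordance,
    harrell_c,
    km_estimate,
    regular_ap,
    regular_auc,
)
from conftest import brute_ap_t, brute_auc_t, brute_harrell_c


def _random_instance(rng, n_max=200):
    n = int(rng.integers(10, n_max + 1))
    scores = rng.standard_normal(n)  # continuous: no ties by construction
    times = rng.uniform(0.1, 10.0, n)
    events = rng.integers(0, 2, n)
    return scores, times, events


class TestTimeVaryingAUC:
    def test_perfect_separation(self):
        assert auc_t([0.9, 0.8, 0.2, 0.1], [1, 2, 5, 5], [1, 1, 0, 0], 3) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc_t([0.3] * 4, [1, 2, 5, 5], [1, 1, 0, 0], 3) == pytest.approx(0.5)

    def test_censored_before_t_excluded(self):
        # the censored-at-2 patient is neither case nor control at t=3
        with_cens = auc_t([0.9, 0.5, 0.1], [1, 2, 5], [1, 0, 0], 3)
        without = auc_t([0.9, 0.1], [1, 5], [1, 0], 3)
        assert with_cens == without == 1.0

    def test_empty_case_or_control_set_rejected(self):
        with pytest.raises(ValueError):
            auc_t([0.5, 0.5], [1, 2], [0, 0], 3)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        done = 0
        while done < 50:
            scores, times, events = _random_instance(rng)
            t = float(rng.uniform(1, 8))
            try:
                ours = auc_t(scores, times, events, t)
            except ValueError:
                continue
            assert ours == pytest.approx(brute_auc_t(scores, times, events, t), abs=1e-12)
            done += 1

    def test_invariant_to_monotone_score_transforms(self):
        rng = np.random.default_rng(1)
        scores, times, events = _random_instance(rng, 100)
        events[:5] = 1
        times[:5] = 1.0
        t = 4.0
        base = auc_t(scores, times, events, t)
        assert auc_t(np.exp(scores), times, events, t) == pytest.approx(base)
        assert auc_t(3 * scores + 7, times, events, t) == pytest.approx(base)


class TestTimeVaryingAP:
    def test_perfect_ranking(self):
        assert ap_t([4, 3, 2, 1], [1, 1, 9, 9], [1, 1, 0, 0], 5) == 1.0

    def test_worst_ranking_single_case(self):
        # one case ranked below three controls: precision at its rank is 1/4
        assert ap_t([0.1, 0.9, 0.8, 0.7], [1, 9, 9, 9], [1, 0, 0, 0], 5) == 0.25

    def test_matches_brute_force_precision_at_ranks(self):
        rng = np.random.default_rng(2)
        done = 0
        while done < 50:
            scores, times, events = _random_instance(rng)
            t = float(rng.uniform(1, 8))
            try:
                ours = ap_t(scores, times, events, t)
            except ValueError:
                continue
            assert ours == pytest.approx(brute_ap_t(scores, times, events, t), abs=1e-12)
            done += 1

    def test_agrees_with_sklearn_on_tie_free_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(80)
        times = np.where(rng.integers(0, 2, 80) == 1, 1.0, 9.0)
        events = (times == 1.0).astype(int)
        if events.sum() in (0, 80):
            events[0] = 1 - events[0]
        ours = ap_t(scores, times, events, 5.0)
        ref = average_precision_score(events, scores)
        assert ours == pytest.approx(ref, abs=1e-12)


class TestRegularAUC:
    def test_direct(self):
        assert regular_auc([0.9, 0.1], [1, 0]) == 1.0
        assert regular_auc([0.5, 0.5, 0.5], [1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            regular_auc([0.5, 0.6], [1, 1])
        with pytest.raises(ValueError):
            regular_ap([0.5, 0.6], [0, 0])

    def test_early_censored_future_case_inflates_regular_auc(self):
        # six patients; one true future case is censored early, so the
        # regular AUC rewards calling them negative while auc_t on the
        # latent labels penalises it
        scores = np.array([0.9, 0.8, 0.05, 0.3, 0.2, 0.1])
        latent_E = np.array([2.0, 3.0, 4.0, np.inf, np.inf, np.inf])
        C = np.array([9.0, 9.0, 0.5, 9.0, 9.0, 9.0])
        T = np.minimum(latent_E, C)
        S = (latent_E <= C).astype(int)
        inflated = regular_auc(scores, S)
        latent_labels = (latent_E <= 5.0).astype(int)
        honest = regular_auc(scores, latent_labels)
        assert inflated > honest


class TestHarrellC:
    def test_perfect_and_reversed_ordering(self):
        assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 0]) == 1.0
        assert harrell_c([1, 2, 3], [1, 2, 3], [1, 1, 0]) == 0.0

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2], [3, 1], [0, 0])

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(5, 101))
            scores = rng.standard_normal(n)
            times = rng.uniform(0, 10, n)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            assert harrell_c(scores, times, events) == pytest.approx(
                brute_harrell_c(scores, times, events), abs=1e-12
            )

    def test_agrees_with_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(300)
        times = rng.uniform(0, 10, 300)
        events = rng.integers(0, 2, 300)
        events[0] = 1
        # lifelines' convention: larger predictions mean longer survival
        assert harrell_c(scores, times, events) == pytest.approx(
            concordance_index(times, -scores, events), abs=1e-12
        )


class TestCensoringConcordance:
    def test_pathological_alignment_scores_one(self):
        # earlier-censored patients receiving higher non-event probability is
        # exactly the follow-up dependence the metric flags
        c_times = np.array([1.0, 2.0, 3.0, 4.0])
        nonevent = np.array([0.9, 0.7, 0.5, 0.3])
        assert censoring_concordance(nonevent, c_times, np.zeros(4)) == 1.0

    def test_independent_scores_are_near_half(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(0, 1, 4000)
        c = rng.uniform(0, 10, 4000)
        val = censoring_concordance(scores, c, np.zeros(4000, int))
        assert abs(val - 0.5) < 0.03

    def test_reduces_to_harrell_on_censored_subset(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0, 1, 50)
        times = rng.uniform(0, 10, 50)
        events = rng.integers(0, 2, 50)
        events[:2] = 0
        cens = events == 0
        expected = harrell_c(
            scores[cens], times[cens], np.ones(int(cens.sum()), int)
        )
        assert censoring_concordance(scores, times, events) == pytest.approx(
            expected, abs=1e-12
        )

    def test_fewer_than_two_censored_rejected(self):
        with pytest.raises(ValueError):
            censoring_concordance([0.5, 0.4], [1, 2], [1, 1])


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        km = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        assert km.survival_at(1) == pytest.approx(0.75)
        assert km.survival_at(3) == pytest.approx(0.375)

    def test_no_events_gives_constant_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.survival_at(10) == 1.0

    def test_no_censoring_reduces_to_ecdf_complement(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(0, 5, 200)
        km = km_estimate(t, np.ones(200, int))
        for q in (0.5, 1.5, 3.0, 4.9):
            assert km.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(9)
        t = rng.uniform(0, 5, 300)
        e = rng.integers(0, 2, 300)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in (0.5, 1.0, 2.5, 4.0):
            assert km.survival_at(q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-10
            )


class TestCalibrationCurve:
    def test_constant_predictions_collapse_to_cohort_incidence(self):
        rng = np.random.default_rng(10)
        t = rng.uniform(0.1, 6, 300)
        e = rng.integers(0, 2, 300)
        pred = np.full(300, 0.3)
        mp, obs, counts, _ = calibration_curve(pred, t, e, t=3.0)
        km = km_estimate(t, e)
        assert len(mp) == 1
        assert counts[0] == 300
        assert obs[0] == pytest.approx(1 - km.survival_at(3.0))

    def test_true_probabilities_land_on_diagonal(self):
        # discrete event times with known per-patient risk, no censoring:
        # observed incidence per bin tracks the mean predicted probability
        rng = np.random.default_rng(11)
        n = 6000
        p_true = rng.uniform(0.05, 0.8, n)
        event_now = rng.uniform(size=n) < p_true
        times = np.where(event_now, 1.0, 9.0)
        events = event_now.astype(int)
        mp, obs, counts, _ = calibration_curve(p_true, times, events, t=2.0)
        se = np.sqrt(mp * (1 - mp) / counts)
        assert np.all(np.abs(mp - obs) < 3.5 * se + 1e-9)

    def test_small_bins_merged(self):
        pred = np.concatenate([np.zeros(5), np.ones(100) * 0.5])
        t = np.ones(105)
        e = np.ones(105, int)
        mp, obs, counts, _ = calibration_curve(pred, t, e, t=1.0, n_bins=10)
        assert all(c >= 20 for c in counts[:-1])

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.5, 1.2], [1, 2], [1, 0], 1.0)


class TestBootstrap:
    def test_constant_metric_has_zero_width(self):
        est = bootstrap_ci(lambda idx: 0.7, 50, n_boot=30, seed=0)
        assert est.ci_low == est.ci_high == est.point == 0.7

    def test_ci_brackets_point_for_smooth_statistic(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(200)
        est = bootstrap_ci(lambda idx: float(np.mean(x[idx])), 200, seed=1)
        assert est.ci_low <= est.point <= est.ci_high

    def test_degenerate_resamples_redrawn(self):
        x = np.array([1.0, 0.0, 0.0, 0.0])

        def metric(idx):
            if x[idx].sum() == 0:
                raise ValueError("undefined")
            return float(x[idx].mean())

        est = bootstrap_ci(metric, 4, n_boot=40, seed=2)
        assert est.n_boot == 40

    def test_auc_t_interval_coverage(self):
        # cases ~ N(1,1) vs controls ~ N(0,1): true AUC = Phi(1/sqrt(2));
        # the 95% percentile interval should cover it in most replicates
        from scipy.stats import norm

        truth = norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(13)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 150
            y = rng.integers(0, 2, n)
            scores = rng.standard_normal(n) + y
            times = np.where(y == 1, 1.0, 9.0)
            est = bootstrap_ci(
                lambda idx: auc_t(scores[idx], times[idx], y[idx], 5.0),
                n,
                n_boot=100,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            covered += est.ci_low <= truth <= est.ci_high
        assert covered / n_rep >= 0.88


def test_auc_t_equals_regular_auc_without_censoring():
    # when nobody is censored inside the horizon the exclusion-based AUC at
    # the horizon coincides exactly with the regular AUC on latent labels
    rng = np.random.default_rng(14)
    n = 400
    E = np.where(rng.uniform(size=n) < 0.3, rng.uniform(0.5, 7.5, n), np.inf)
    C = np.full(n, 20.0)
    T = np.minimum(E, C)
    S = (E <= C).astype(int)
    scores = rng.uniform(size=n)
    horizon = 8.0
    labels = ((S == 1) & (T <= horizon)).astype(int)
    assert auc_t(scores, T, S, horizon) == regular_auc(scores, labels)
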