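"""Synthetic cohort generator, filters and censoring transformations."""
import dataclasses

import numpy as np
import pytest

from censorbench import (
    CohortConfig,
    FilterSpec,
    PatientRecord,
    apply_filter,
    apply_semisynthetic_censoring,
    cohort_from_csv,
    cohort_to_csv,
    generate_cohort,
    truncate_features,
)
from censorbench.cohort import cohort_to_frames


def _record(T, S, E=None, C=None, yob=2016, ages=(), codes=None):
    ages = np.asarray(ages, dtype=float)
    codes = np.asarray(
        codes if codes is not None else [f"C{i:04d}" for i in range(len(ages))],
        dtype=object,
    )
    if E is None:
        E = T if S else np.inf
    if C is None:
        C = T if not S else T + 1.0
    return PatientRecord(
        patient_id=f"P{abs(hash((T, S, yob))) % 10**6}",
        birth_year=yob,
        sex="male",
        race="C",
        insurance="public",
        code_ages=ages,
        codes=codes,
        event_time=float(E),
        censoring_time=float(C),
        observed_time=float(T),
        event=int(S),
    )


class TestGenerateCohort:
    def test_observed_data_invariants_hold_on_large_cohort(self):
        cfg = CohortConfig(
            n_patients=10_000, mean_codes_per_year=2.0, dropout_rate=0.1, seed=3
        )
        cohort = generate_cohort(cfg)
        E = np.array([p.event_time for p in cohort])
        C = np.array([p.censoring_time for p in cohort])
        T = np.array([p.observed_time for p in cohort])
        S = np.array([p.event for p in cohort])
        assert np.all(T == np.minimum(E, C))
        assert np.array_equal(S, (E <= C).astype(int))
        assert np.all(C > 0)
        assert np.all(T[S == 1] == E[S == 1])
        assert all(np.all(p.code_ages < p.observed_time) for p in cohort)
        assert all(np.all(np.diff(p.code_ages) >= 0) for p in cohort)

    def test_zero_hazard_forces_no_events(self):
        cfg = CohortConfig(n_patients=200, baseline_hazards=(0.0,) * 5, seed=0)
        cohort = generate_cohort(cfg)
        assert all(p.event == 0 for p in cohort)
        assert all(np.isinf(p.event_time) for p in cohort)

    def test_single_censoring_source_is_administrative(self):
        cfg = CohortConfig(
            n_patients=300,
            dropout_rate=0.0,
            extraction_year=2040.0,
            baseline_hazards=(0.05,) * 8,
            seed=1,
        )
        cohort = generate_cohort(cfg)
        for p in cohort:
            admin = cfg.extraction_year - p.birth_year
            assert admin - 1.0 <= p.censoring_time <= admin

    def test_empirical_incidence_matches_geometric_closed_form(self):
        # constant hazard 0.1 per yearly bin, no covariates: cumulative
        # incidence by bin k is 1 - 0.9^k
        n = 50_000
        cfg = CohortConfig(
            n_patients=n,
            baseline_hazards=(0.1,) * 8,
            covariate_effects={},
            prevalence_trend=0.0,
            risk_effect=0.0,
            dropout_rate=0.0,
            extraction_year=2040.0,
            mean_codes_per_year=0.5,
            seed=11,
        )
        cohort = generate_cohort(cfg)
        E = np.array([p.event_time for p in cohort])
        for k in range(1, 9):
            expected = 1.0 - 0.9**k
            emp = np.mean(E <= k)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(emp - expected) < max(0.01, 3 * se)

    def test_same_seed_reproduces_cohort_exactly(self):
        cfg = CohortConfig(n_patients=300, mean_codes_per_year=3.0, seed=9)
        a, _ = cohort_to_frames(generate_cohort(cfg))
        b, _ = cohort_to_frames(generate_cohort(cfg))
        assert a.equals(b)
        ca = generate_cohort(cfg)
        cb = generate_cohort(cfg)
        assert all(
            np.array_equal(x.code_ages, y.code_ages)
            and np.array_equal(x.codes, y.codes)
            for x, y in zip(ca, cb)
        )

    def test_attribute_codes_prepended_when_enabled(self):
        cfg = CohortConfig(n_patients=50, emit_attribute_codes=True, seed=2)
        cohort = generate_cohort(cfg)
        p = cohort[0]
        assert any(c.startswith("SEX_") for c in p.codes)
        assert f"ERA_{p.birth_year}" in set(p.codes)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(baseline_hazards=(0.2, 1.0)),
            dict(baseline_hazards=(-0.1,)),
            dict(n_patients=0),
            dict(birth_year_range=(2020, 2014)),
            dict(dropout_rate=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            CohortConfig(**bad)


class TestApplyFilter:
    def test_prediction_age_cutoff_removes_early_outcomes(self):
        cohort = [
            _record(0.1, 0),
            _record(2, 1),
            _record(6, 0),
            _record(7, 1),
        ]
        out = apply_filter(cohort, FilterSpec(prediction_age_cutoff=0.25))
        assert len(out) == 3

    def test_min_followup_removes_short_censored_only(self):
        cohort = [_record(2, 0), _record(6, 0), _record(3, 1)]
        out = apply_filter(
            cohort, FilterSpec(prediction_age_cutoff=0.1, min_followup_years=5)
        )
        # early censored removed, early observed event kept by default
        assert {p.observed_time for p in out} == {6, 3}
        strict = apply_filter(
            cohort,
            FilterSpec(
                prediction_age_cutoff=0.1, min_followup_years=5, drop_early_events=True
            ),
        )
        assert {p.observed_time for p in strict} == {6}

    def test_yob_max_keeps_earlier_birth_years(self):
        cohort = [_record(6, 0, yob=y) for y in (2017, 2019, 2020)]
        out = apply_filter(cohort, FilterSpec(prediction_age_cutoff=0.1, yob_max=2018))
        assert len(out) == 1 and out[0].birth_year == 2017

    def test_filter_is_idempotent(self, small_cohort):
        spec = FilterSpec(prediction_age_cutoff=0.5, yob_max=2020, min_followup_years=2)
        once = apply_filter(small_cohort, spec)
        twice = apply_filter(once, spec)
        assert [p.patient_id for p in once] == [p.patient_id for p in twice]

    def test_errors(self, small_cohort):
        with pytest.raises(ValueError):
            apply_filter([], FilterSpec(prediction_age_cutoff=0.5))
        with pytest.raises(ValueError):
            apply_filter(small_cohort, FilterSpec(prediction_age_cutoff=99.0))


class TestTruncateFeatures:
    def test_cutoff_threshold(self):
        p = _record(5, 0, ages=[0.1, 0.2, 1.4])
        out = truncate_features(p, 0.25)
        assert len(out.codes) == 2
        assert np.all(out.code_ages < 0.25)

    def test_leakage_rule_dominates(self):
        p = _record(0.15, 1, E=0.15, ages=[0.1, 0.2])
        # records at or after the diagnosis age are removed even below cutoff
        p = p.replace(observed_time=0.15, event_time=0.15)
        out = truncate_features(p, 1.25)
        assert len(out.codes) == 1

    def test_empty_sequence_is_identity(self):
        p = _record(4, 1, ages=[])
        out = truncate_features(p, 1.0)
        assert len(out.codes) == 0
        assert out.observed_time == p.observed_time and out.event == p.event


class TestSemisyntheticCensoring:
    def test_censoring_times_rescaled_to_max_age(self):
        cohort = [_record(2, 0, C=2), _record(4, 0, C=4), _record(6, 0, C=6)]
        out = apply_semisynthetic_censoring(cohort, 1.2)
        assert np.allclose([p.censoring_time for p in out], [0.4, 0.8, 1.2])
        assert max(p.censoring_time for p in out) == pytest.approx(1.2)

    def test_event_before_new_censoring_stays_event(self):
        p = _record(0.3, 1, E=0.3, C=6)
        (out,) = apply_semisynthetic_censoring([p], 1.2)
        assert out.event == 1 and out.observed_time == pytest.approx(0.3)

    def test_event_after_new_censoring_becomes_censored(self):
        p = _record(2.0, 1, E=2.0, C=6)
        (out,) = apply_semisynthetic_censoring([p], 1.2)
        assert out.event == 0 and out.observed_time == pytest.approx(1.2)

    def test_latent_event_times_unchanged_and_events_nonincreasing(self, small_cohort):
        out = apply_semisynthetic_censoring(small_cohort, 1.2)
        assert all(
            a.event_time == b.event_time for a, b in zip(small_cohort, out)
        )
        assert sum(p.event for p in out) <= sum(p.event for p in small_cohort)
        assert all(np.all(p.code_ages < p.observed_time) for p in out)

    def test_errors(self):
        with pytest.raises(ValueError):
            apply_semisynthetic_censoring([], 1.2)
        with pytest.raises(ValueError):
            apply_semisynthetic_censoring([_record(1, 0, C=1)], -1.0)


def test_cohort_csv_round_trip(tmp_path, small_cohort):
    cohort_to_csv(small_cohort[:50], tmp_path)
    back = cohort_from_csv(tmp_path)
    assert len(back) == 50
    for a, b in zip(small_cohort[:50], back):
        assert a.patient_id == b.patient_id
        assert a.event == b.event
        assert a.observed_time == pytest.approx(b.observed_time)
        assert np.allclose(a.code_ages, b.code_ages)
        assert list(a.codes) == list(b.codes)
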