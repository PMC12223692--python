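"""Synthetic cohort generation, filtering and censoring transformations.

A patient is the triplet {X, T, S}: covariates and a timestamped code
sequence X, an observed time T = min(E, C), and an event indicator
S = 1[E <= C], where E is the latent diagnosis age (infinity if the
diagnosis never occurs within the modelled horizon) and C the censoring age.

Event times follow a discrete-time hazard model on yearly bins,

    h_i(k) = expit(logit(h0_k) + beta' x_i + trend * (yob_i - yob_ref)
             + risk_effect * z_i),

with z_i a latent standard-normal risk score.  z_i (together with the
covariate and trend contributions) also shifts the share of "risk codes" in
the patient's code sequence, so the hazard is learnable from the codes alone.
Administrative censoring is driven by a fixed extraction date relative to the
birth date, which makes follow-up length a deterministic function of birth
year; optional exponential dropout adds loss to follow-up.
"""
from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import CohortConfig, FilterSpec

__all__ = [
    "PatientRecord",
    "generate_cohort",
    "apply_filter",
    "truncate_features",
    "apply_semisynthetic_censoring",
    "cohort_to_frames",
    "cohort_to_csv",
    "cohort_from_csv",
    "true_horizon_incidence",
]


@dataclass
class PatientRecord:
    """One simulated child."""

    patient_id: str
    birth_year: int
    sex: str
    race: str
    insurance: str
    code_ages: np.ndarray  # float ages in years, sorted, strictly < observed_time
    codes: np.ndarray  # token strings, aligned with code_ages
    event_time: float  # latent E; np.inf if the event never occurs
    censoring_time: float  # latent C
    observed_time: float  # T = min(E, C)
    event: int  # S = 1[E <= C]

    @property
    def code_sequence(self) -> list[tuple[float, str]]:
        return list(zip(self.code_ages.tolist(), self.codes.tolist()))

    def replace(self, **kw) -> "PatientRecord":
        return dataclasses.replace(self, **kw)


def _sample_categories(rng, freqs: dict, n: int) -> np.ndarray:
    levels = np.array(sorted(freqs))
    p = np.array([freqs[l] for l in levels], dtype=float)
    p = p / p.sum()
    return levels[rng.choice(len(levels), size=n, p=p)]


def _linear_predictor(cfg: CohortConfig, sex, race, insurance, birth_year, z):
    eta = np.zeros(len(sex), dtype=float)
    attrs = {"sex": sex, "race": race, "insurance": insurance}
    for key, beta in cfg.covariate_effects.items():
        attr, _, level = key.partition(":")
        if attr not in attrs:
            raise ValueError(f"unknown covariate effect key: {key!r}")
        eta += float(beta) * (attrs[attr] == level)
    eta += cfg.prevalence_trend * (birth_year - cfg.birth_year_range[0])
    eta += cfg.risk_effect * z
    return eta


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> list[PatientRecord]:
    """Simulate a cohort of patients under ``config``.

    Deterministic given the seed (``config.seed`` unless overridden).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    lo, hi = config.birth_year_range

    birth_year = rng.integers(lo, hi + 1, size=n)
    birth_offset = rng.uniform(0.0, 1.0, size=n)
    sex = _sample_categories(rng, config.sex_freqs, n)
    race = _sample_categories(rng, config.race_freqs, n)
    insurance = _sample_categories(rng, config.insurance_freqs, n)
    z = rng.standard_normal(n)
    eta = _linear_predictor(config, sex, race, insurance, birth_year, z)

    # Discrete-time event sampling on yearly bins with within-bin jitter.
    h0 = np.asarray(config.baseline_hazards, dtype=float)
    K = h0.size
    with np.errstate(divide="ignore"):
        base_logit = logit(h0)  # -inf where h0 == 0
    hazard = expit(base_logit[None, :] + eta[:, None])
    hazard[:, h0 == 0.0] = 0.0
    if config.immune_fraction > 0:
        immune = rng.uniform(size=n) < config.immune_fraction
        hazard[immune] = 0.0
    fired = rng.uniform(size=(n, K)) < hazard
    any_fire = fired.any(axis=1)
    first_bin = np.where(any_fire, fired.argmax(axis=1), -1)
    jitter = rng.uniform(size=n)
    event_time = np.where(any_fire, first_bin + jitter, np.inf)

    c_admin = config.extraction_year - (birth_year + birth_offset)
    if config.dropout_rate > 0:
        c_drop = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        c_drop = np.full(n, np.inf)
    censoring_time = np.minimum(c_admin, c_drop)
    observed_time = np.minimum(event_time, censoring_time)
    event = (event_time <= censoring_time).astype(int)

    # Code sequences: marked Poisson process on (0, T), risk codes enriched
    # according to the same linear predictor that drives the hazard.
    vocab = np.array([f"C{i:04d}" for i in range(config.vocabulary_size)])
    n_risk = max(1, int(round(config.risk_code_fraction * config.vocabulary_size)))
    share = expit(logit(config.risk_code_fraction) + eta)
    counts = rng.poisson(config.mean_codes_per_year * observed_time)
    total = int(counts.sum())
    owner = np.repeat(np.arange(n), counts)
    ages = rng.uniform(0.0, observed_time[owner])
    is_risk = rng.uniform(size=total) < share[owner]
    idx = np.where(
        is_risk,
        rng.integers(0, n_risk, size=total),
        rng.integers(n_risk, config.vocabulary_size, size=total),
    )
    tokens = vocab[idx]
    order = np.lexsort((ages, owner))
    ages, tokens, owner = ages[order], tokens[order], owner[order]
    bounds = np.concatenate(([0], np.cumsum(counts)))

    records: list[PatientRecord] = []
    for i in range(n):
        a = ages[bounds[i]:bounds[i + 1]]
        c = tokens[bounds[i]:bounds[i + 1]]
        if config.emit_attribute_codes:
            attr = np.array(
                [
                    f"SEX_{sex[i]}",
                    f"RACE_{race[i]}",
                    f"INS_{insurance[i]}",
                    f"ERA_{birth_year[i]}",
                ]
            )
            a = np.concatenate((np.zeros(attr.size), a))
            c = np.concatenate((attr, c))
        records.append(
            PatientRecord(
                patient_id=f"P{i:06d}",
                birth_year=int(birth_year[i]),
                sex=str(sex[i]),
                race=str(race[i]),
                insurance=str(insurance[i]),
                code_ages=a,
                codes=c,
                event_time=float(event_time[i]),
                censoring_time=float(censoring_time[i]),
                observed_time=float(observed_time[i]),
                event=int(event[i]),
            )
        )
    return records


def apply_filter(cohort: Sequence[PatientRecord], spec: FilterSpec) -> list[PatientRecord]:
    """Apply a cohort-selection rule; returns a new list, input untouched.

    Patients diagnosed or censored at or before the prediction-age cutoff are
    removed; optional birth-year and minimum-follow-up criteria are applied
    conjunctively.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    out = []
    for p in cohort:
        if p.observed_time <= spec.prediction_age_cutoff:
            continue
        if spec.yob_max is not None and p.birth_year > spec.yob_max:
            continue
        if spec.min_followup_years is not None and p.observed_time < spec.min_followup_years:
            if p.event == 0 or spec.drop_early_events:
                continue
        out.append(p)
    if not out:
        raise ValueError("filter removed every patient")
    return out


def truncate_features(patient: PatientRecord, prediction_age_cutoff: float) -> PatientRecord:
    """Restrict the code sequence to ages before the cutoff and before E.

    The second condition removes any code recorded at or after the (latent)
    diagnosis, preventing post-diagnosis leakage into the features.
    """
    keep = (patient.code_ages < prediction_age_cutoff) & (
        patient.code_ages < patient.event_time
    )
    return patient.replace(code_ages=patient.code_ages[keep], codes=patient.codes[keep])


def apply_semisynthetic_censoring(
    cohort: Sequence[PatientRecord], max_age: float
) -> list[PatientRecord]:
    """Rescale the censoring distribution so its maximum equals ``max_age``.

    Latent event times are unchanged; observed times and event indicators are
    recomputed under the rescaled censoring times, emulating a much more
    heavily censored version of the same cohort with known true labels.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if max_age <= 0:
        raise ValueError("max_age must be positive")
    m = max(p.censoring_time for p in cohort)
    if not np.isfinite(m) or m <= 0:
        raise ValueError("maximum censoring time must be positive and finite")
    scale = max_age / m
    out = []
    for p in cohort:
        c = p.censoring_time * scale
        t = min(p.event_time, c)
        s = int(p.event_time <= c)
        keep = p.code_ages < t
        out.append(
            p.replace(
                censoring_time=c,
                observed_time=t,
                event=s,
                code_ages=p.code_ages[keep],
                codes=p.codes[keep],
            )
        )
    return out


def true_horizon_incidence(
    config: CohortConfig, horizon: Optional[float] = None, n_mc: int = 200_000, seed: int = 12345
) -> float:
    """True mean cumulative incidence P(E <= horizon) under ``config``.

    Computed by Monte-Carlo integration over the covariate/latent-risk
    distribution (independent of any generated cohort); the default draw is
    large enough for ~3 decimal places.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.birth_year_range
    birth_year = rng.integers(lo, hi + 1, size=n_mc)
    sex = _sample_categories(rng, config.sex_freqs, n_mc)
    race = _sample_categories(rng, config.race_freqs, n_mc)
    insurance = _sample_categories(rng, config.insurance_freqs, n_mc)
    z = rng.standard_normal(n_mc)
    eta = _linear_predictor(config, sex, race, insurance, birth_year, z)
    h0 = np.asarray(config.baseline_hazards, dtype=float)
    K = h0.size if horizon is None else min(int(np.ceil(horizon)), h0.size)
    with np.errstate(divide="ignore"):
        base_logit = logit(h0[:K])
    hazard = expit(base_logit[None, :] + eta[:, None])
    hazard[:, h0[:K] == 0.0] = 0.0
    surv = np.prod(1.0 - hazard, axis=1)
    inc = 1.0 - surv
    if config.immune_fraction > 0:
        inc *= 1.0 - config.immune_fraction
    return float(inc.mean())


def cohort_to_frames(cohort: Sequence[PatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flat tabular view: one row per patient, plus long-format codes."""
    patients = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "birth_year": [p.birth_year for p in cohort],
            "sex": [p.sex for p in cohort],
            "race": [p.race for p in cohort],
            "insurance": [p.insurance for p in cohort],
            "event_time": [p.event_time for p in cohort],
            "censoring_time": [p.censoring_time for p in cohort],
            "observed_time": [p.observed_time for p in cohort],
            "event": [p.event for p in cohort],
        }
    )
    codes = pd.DataFrame(
        {
            "patient_id": np.repeat(
                [p.patient_id for p in cohort], [len(p.codes) for p in cohort]
            ),
            "age": np.concatenate([p.code_ages for p in cohort])
            if cohort
            else np.array([]),
            "code": np.concatenate([p.codes for p in cohort])
            if cohort
            else np.array([]),
        }
    )
    return patients, codes


def cohort_to_csv(cohort: Sequence[PatientRecord], outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    patients, codes = cohort_to_frames(cohort)
    patients.to_csv(os.path.join(outdir, "patients.csv"), index=False)
    codes.to_csv(os.path.join(outdir, "codes.csv"), index=False)


def cohort_from_csv(outdir) -> list[PatientRecord]:
    patients = pd.read_csv(os.path.join(outdir, "patients.csv"))
    codes = pd.read_csv(os.path.join(outdir, "codes.csv"))
    grouped: dict[str, list[tuple[float, str]]] = {}
    for pid, age, code in zip(codes["patient_id"], codes["age"], codes["code"]):
        grouped.setdefault(pid, []).append((float(age), str(code)))
    records = []
    for row in patients.itertuples(index=False):
        seq = grouped.get(row.patient_id, [])
        ages = np.array([a for a, _ in seq], dtype=float)
        toks = np.array([c for _, c in seq], dtype=object)
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                birth_year=int(row.birth_year),
                sex=str(row.sex),
                race=str(row.race),
                insurance=str(row.insurance),
                code_ages=ages,
                codes=toks,
                event_time=float(row.event_time),
                censoring_time=float(row.censoring_time),
                observed_time=float(row.observed_time),
                event=int(row.event),
            )
        )
    return records
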