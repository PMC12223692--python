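"""End-to-end experiment orchestration.

A scenario generates a cohort, applies the base prediction-age /
birth-year filter, splits 60/20/20 at patient level, trains the five
canonical setups (binary classifier under three filtering strategies plus
the discrete-time network and the deep Cox model under the base filter),
and evaluates every model on one shared test split so that metric
differences are attributable to training-time choices only.  All randomness
flows from a single root seed split into named substreams recorded in the
report manifest.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cohort import (
    PatientRecord,
    apply_filter,
    apply_semisynthetic_censoring,
    generate_cohort,
    truncate_features,
)
from .config import FilterSpec, ScenarioConfig
from .discrete import TimeGrid
from .metrics import (
    MetricEstimate,
    ap_t,
    auc_t,
    bootstrap_ci,
    calibration_curve,
    censoring_concordance,
    harrell_c,
    regular_ap,
    regular_auc,
)
from .train import TrainedModel, train_model

__all__ = [
    "ModelSetup",
    "ExperimentReport",
    "split_cohort",
    "canonical_setups",
    "prepare_splits",
    "evaluate_model",
    "run_scenario",
    "subgroup_summary",
    "ood_evaluation",
    "find_semisynthetic_max_age",
    "run_semisynthetic_experiment",
]


@dataclass(frozen=True)
class ModelSetup:
    """One (model kind, training filter) combination with a display label."""

    model_kind: str
    filter: FilterSpec
    label: str


@dataclass
class ExperimentReport:
    """Tidy result tables plus provenance."""

    metrics: pd.DataFrame
    calibration: pd.DataFrame
    subgroups: pd.DataFrame
    manifest: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.metrics.to_csv(os.path.join(outdir, "metrics.csv"), index=False)
        self.calibration.to_csv(os.path.join(outdir, "calibration.csv"), index=False)
        self.subgroups.to_csv(os.path.join(outdir, "subgroups.csv"), index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def split_cohort(
    cohort: Sequence[PatientRecord],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
):
    """Random patient-level partition into train/validation/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(cohort)
    order = np.random.default_rng(seed).permutation(n)
    bounds = np.rint(np.cumsum(fractions) * n).astype(int)
    parts = np.split(order, bounds[:-1])
    return tuple([cohort[i] for i in part] for part in parts)


def canonical_setups(config: ScenarioConfig) -> list[ModelSetup]:
    """The five canonical setups: BC under three filters, DTNN and DCPH."""
    cutoff = config.prediction_age_cutoff
    base = FilterSpec(prediction_age_cutoff=cutoff, yob_max=config.yob_max)
    strict = FilterSpec(prediction_age_cutoff=cutoff, yob_max=config.yob_max_strict)
    followup = FilterSpec(
        prediction_age_cutoff=cutoff,
        yob_max=config.yob_max,
        min_followup_years=config.min_followup_years,
    )
    y, ys = config.yob_max, config.yob_max_strict
    return [
        ModelSetup("BC", base, f"BC_yob<={y}"),
        ModelSetup("BC", strict, f"BC_yob<={ys}"),
        ModelSetup("BC", followup, f"BC_t>={config.min_followup_years:g}"),
        ModelSetup("DTNN", base, f"DTNN_yob<={y}"),
        ModelSetup("DCPH", base, f"DCPH_yob<={y}"),
    ]


def _derive_seeds(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    names = ("simulate", "split", "train", "bootstrap")
    return {k: int(v) for k, v in zip(names, rng.integers(0, 2**31 - 1, size=len(names)))}


def prepare_splits(config: ScenarioConfig):
    """Generate, base-filter, feature-truncate and split a scenario cohort.

    Returns ``(train, val, test, grid, seeds)``.  The base filter applies the
    prediction-age cutoff and the scenario's birth-year cap; the shared test
    split is fixed here, before any setup-specific filtering.
    """
    seeds = _derive_seeds(config.seed)
    cohort = generate_cohort(config.cohort, seed=seeds["simulate"])
    base = FilterSpec(
        prediction_age_cutoff=config.prediction_age_cutoff, yob_max=config.yob_max
    )
    cohort = apply_filter(cohort, base)
    cohort = [truncate_features(p, config.prediction_age_cutoff) for p in cohort]
    train, val, test = split_cohort(cohort, seed=seeds["split"])
    grid = TimeGrid.regular(
        config.prediction_age_cutoff, config.cohort.horizon, width=config.bin_width
    )
    return train, val, test, grid, seeds


def _arrays(records):
    times = np.array([p.observed_time for p in records])
    events = np.array([p.event for p in records], dtype=int)
    return times, events


def evaluate_model(
    model: TrainedModel,
    test_records: Sequence[PatientRecord],
    eval_times: Sequence[float],
    n_boot: int = 100,
    seed: int = 0,
    label: Optional[str] = None,
):
    """Full metric suite with bootstrap CIs on one test cohort.

    Returns ``(metrics_df, calibration_df)`` in tidy long form.
    """
    label = label or model.kind
    times, events = _arrays(test_records)
    horizon_scores = model.predict_horizon_probability(test_records)
    scores_by_t = {t: model.predict_event_probability(test_records, t) for t in eval_times}
    n = len(test_records)
    rows = []

    def add(est: MetricEstimate):
        rows.append(
            {
                "model": label,
                "metric": est.metric_name,
                "eval_time": est.eval_time,
                "point": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_boot": est.n_boot,
            }
        )

    bseed = np.random.default_rng(seed).integers(0, 2**31 - 1, size=4 + len(eval_times) * 2)
    for k, t in enumerate(eval_times):
        s_t = scores_by_t[t]
        add(
            bootstrap_ci(
                lambda i, s_t=s_t, t=t: auc_t(s_t[i], times[i], events[i], t),
                n, n_boot=n_boot, seed=int(bseed[2 * k]), metric_name="auc_t", eval_time=t,
            )
        )
        add(
            bootstrap_ci(
                lambda i, s_t=s_t, t=t: ap_t(s_t[i], times[i], events[i], t),
                n, n_boot=n_boot, seed=int(bseed[2 * k + 1]), metric_name="ap_t", eval_time=t,
            )
        )
    base = 2 * len(eval_times)
    add(
        bootstrap_ci(
            lambda i: regular_auc(horizon_scores[i], events[i]),
            n, n_boot=n_boot, seed=int(bseed[base]), metric_name="regular_auc",
        )
    )
    add(
        bootstrap_ci(
            lambda i: regular_ap(horizon_scores[i], events[i]),
            n, n_boot=n_boot, seed=int(bseed[base + 1]), metric_name="regular_ap",
        )
    )
    add(
        bootstrap_ci(
            lambda i: harrell_c(horizon_scores[i], times[i], events[i]),
            n, n_boot=n_boot, seed=int(bseed[base + 2]), metric_name="harrell_c",
        )
    )
    add(
        bootstrap_ci(
            lambda i: censoring_concordance(
                1.0 - horizon_scores[i], times[i], events[i]
            ),
            n, n_boot=n_boot, seed=int(bseed[base + 3]),
            metric_name="censoring_concordance",
        )
    )

    calib_rows = []
    for t in eval_times:
        pred, obs, counts, ses = calibration_curve(scores_by_t[t], times, events, t)
        for p_, o_, c_, se_ in zip(pred, obs, counts, ses):
            calib_rows.append(
                {
                    "model": label,
                    "eval_time": t,
                    "mean_predicted": p_,
                    "observed_incidence": o_,
                    "n": c_,
                    "observed_se": se_,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(calib_rows)


def subgroup_summary(predictions, records: Sequence[PatientRecord], attribute: str):
    """Distribution of predicted probabilities per level of an attribute.

    For the ordered attributes (birth_year, followup_length) the returned
    frame's ``attrs`` carry Spearman rank correlations between prediction
    and level, both patient-level and across stratum means.
    """
    p = np.asarray(predictions, dtype=float)
    if len(p) != len(records):
        raise ValueError("predictions and cohort are misaligned")
    if attribute == "birth_year":
        levels = np.array([r.birth_year for r in records])
    elif attribute == "followup_length":
        levels = np.floor([r.observed_time for r in records]).astype(int)
    elif attribute in ("sex", "race", "insurance"):
        levels = np.array([getattr(r, attribute) for r in records])
    else:
        raise ValueError(f"unknown attribute: {attribute}")
    df = (
        pd.DataFrame({"level": levels, "pred": p})
        .groupby("level")["pred"]
        .agg(
            n="count",
            mean="mean",
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    ordered = attribute in ("birth_year", "followup_length")
    if ordered:
        df = df.sort_values("level").reset_index(drop=True)
        rho, pval = spearmanr(levels.astype(float), p)
        df.attrs["rank_corr"] = float(rho)
        df.attrs["rank_corr_p"] = float(pval)
        if len(df) > 2:
            rho_m, pval_m = spearmanr(df["level"].astype(float), df["mean"])
            df.attrs["stratum_rank_corr"] = float(rho_m)
            df.attrs["stratum_rank_corr_p"] = float(pval_m)
    return df


@dataclass
class OODReport:
    strata: pd.DataFrame
    calibration: Optional[pd.DataFrame]


def ood_evaluation(
    model: TrainedModel,
    cohort: Sequence[PatientRecord],
    setup: ModelSetup,
    eval_time: Optional[float] = None,
) -> OODReport:
    """Evaluate a trained model on strata its training filter excluded.

    Birth-year levels above the setup's ``yob_max`` and follow-up levels
    below its ``min_followup_years`` are flagged out-of-distribution; a
    calibration curve restricted to the OOD patients is computed when an
    evaluation time is given.
    """
    f = setup.filter
    has_criteria = f.yob_max is not None or f.min_followup_years is not None
    horizon_scores = model.predict_horizon_probability(cohort)
    frames = []
    ood_mask = np.zeros(len(cohort), dtype=bool)
    for attribute in ("birth_year", "followup_length"):
        df = subgroup_summary(horizon_scores, cohort, attribute)
        if attribute == "birth_year":
            flags = (
                df["level"] > f.yob_max if f.yob_max is not None else False
            )
            ood_mask |= (
                np.array([r.birth_year for r in cohort]) > f.yob_max
                if f.yob_max is not None
                else False
            )
        else:
            flags = (
                df["level"] < f.min_followup_years
                if f.min_followup_years is not None
                else False
            )
            ood_mask |= (
                np.array([r.observed_time for r in cohort]) < f.min_followup_years
                if f.min_followup_years is not None
                else False
            )
        df = df.assign(attribute=attribute, ood=np.asarray(flags, dtype=bool))
        frames.append(df)
    strata = pd.concat(frames, ignore_index=True)
    if has_criteria and not ood_mask.any():
        raise ValueError("cohort contains no patients outside the setup's filter")
    calib = None
    if eval_time is not None and ood_mask.any():
        sub = [cohort[i] for i in np.flatnonzero(ood_mask)]
        times, events = _arrays(sub)
        scores = model.predict_event_probability(sub, eval_time)
        pred, obs, counts, ses = calibration_curve(
            scores, times, events, eval_time, n_bins=5
        )
        calib = pd.DataFrame(
            {
                "eval_time": eval_time,
                "mean_predicted": pred,
                "observed_incidence": obs,
                "n": counts,
                "observed_se": ses,
            }
        )
    return OODReport(strata=strata, calibration=calib)


def run_scenario(
    config: ScenarioConfig,
    outdir=None,
    setups: Optional[Sequence[ModelSetup]] = None,
    embeddings=None,
) -> ExperimentReport:
    """Train and evaluate every setup of a scenario on one shared test split."""
    train, val, test, grid, seeds = prepare_splits(config)
    embeddings = embeddings if embeddings is not None else config.embeddings
    setups = list(setups) if setups is not None else canonical_setups(config)
    train_rng = np.random.default_rng(seeds["train"])
    metrics_frames, calib_frames, subgroup_frames = [], [], []
    models = {}
    for setup in setups:
        tr = apply_filter(train, setup.filter)
        va = apply_filter(val, setup.filter)
        tcfg = dataclass_replace_seed(config.train, int(train_rng.integers(0, 2**31 - 1)))
        model = train_model(
            setup.model_kind, tr, va, tcfg, config.encoder,
            time_grid=grid, embeddings=embeddings,
        )
        models[setup.label] = model
        m_df, c_df = evaluate_model(
            model, test, config.eval_times,
            n_boot=config.n_boot, seed=seeds["bootstrap"], label=setup.label,
        )
        metrics_frames.append(m_df)
        calib_frames.append(c_df)
        horizon_scores = model.predict_horizon_probability(test)
        for attribute in ("birth_year", "followup_length", "sex", "race", "insurance"):
            sg = subgroup_summary(horizon_scores, test, attribute)
            sg = sg.assign(model=setup.label, attribute=attribute)
            for key in ("rank_corr", "rank_corr_p"):
                sg[key] = sg.attrs.get(key, np.nan)
            subgroup_frames.append(sg)
    manifest = {
        "scenario": config.name,
        "root_seed": config.seed,
        "substream_seeds": seeds,
        "n_train": len(train),
        "n_val": len(val),
        "n_test": len(test),
        "setups": [s.label for s in setups],
        "selected_hyperparameters": {k: m.selected for k, m in models.items()},
    }
    report = ExperimentReport(
        metrics=pd.concat(metrics_frames, ignore_index=True),
        calibration=pd.concat(calib_frames, ignore_index=True),
        subgroups=pd.concat(subgroup_frames, ignore_index=True),
        manifest=manifest,
        models=models,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def dataclass_replace_seed(train_config, seed: int):
    import dataclasses

    return dataclasses.replace(train_config, seed=seed)


def find_semisynthetic_max_age(
    records: Sequence[PatientRecord], event_retention: float = 0.5
) -> float:
    """Smallest rescaled-censoring maximum age retaining the target fraction
    of observed events.

    Under censoring rescaled by ``a / max(C)``, an event survives iff
    ``E <= C * a / max(C)``; the retained fraction is monotone in ``a``, so
    the threshold is found by direct inspection of the event patients.
    """
    if not 0 < event_retention <= 1:
        raise ValueError("event_retention must lie in (0, 1]")
    m = max(p.censoring_time for p in records)
    ratios = np.sort(
        [m * p.event_time / p.censoring_time for p in records if p.event == 1]
    )
    if ratios.size == 0:
        raise ValueError("no observed events")
    k = int(np.ceil(event_retention * ratios.size))
    return float(ratios[k - 1])


def run_semisynthetic_experiment(
    config: ScenarioConfig,
    max_age: float,
    outdir=None,
    embeddings=None,
) -> ExperimentReport:
    """Censoring-rescaling experiment: retrain under simulated early
    censoring, evaluate on the untouched original test split.

    The censoring transformation is applied to the training and validation
    splits only; DTNN and BC are retrained on the transformed data and
    reported side by side with their original-data counterparts, restricted
    to evaluation times at or below ``max_age`` (beyond it the comparison
    would be unfair: those observation times were unavailable in training).
    """
    train, val, test, grid, seeds = prepare_splits(config)
    embeddings = embeddings if embeddings is not None else config.embeddings
    max_c = max(p.censoring_time for p in train)
    if max_age > max_c:
        raise ValueError("max_age exceeds the original maximum censoring age")
    eval_times = [t for t in config.eval_times if t <= max_age]
    if not eval_times:
        raise ValueError("no evaluation times at or below max_age")
    cutoff_filter = FilterSpec(prediction_age_cutoff=config.prediction_age_cutoff)
    train_ss = apply_filter(apply_semisynthetic_censoring(train, max_age), cutoff_filter)
    val_ss = apply_filter(apply_semisynthetic_censoring(val, max_age), cutoff_filter)

    train_rng = np.random.default_rng(seeds["train"])
    metrics_frames, calib_frames = [], []
    models = {}
    for label, kind, tr, va in (
        ("BC_original", "BC", train, val),
        ("DTNN_original", "DTNN", train, val),
        ("BC_semisynthetic", "BC", train_ss, val_ss),
        ("DTNN_semisynthetic", "DTNN", train_ss, val_ss),
    ):
        tcfg = dataclass_replace_seed(config.train, int(train_rng.integers(0, 2**31 - 1)))
        model = train_model(
            kind, tr, va, tcfg, config.encoder, time_grid=grid, embeddings=embeddings
        )
        models[label] = model
        m_df, c_df = evaluate_model(
            model, test, eval_times, n_boot=config.n_boot,
            seed=seeds["bootstrap"], label=label,
        )
        metrics_frames.append(m_df)
        calib_frames.append(c_df)
    manifest = {
        "scenario": config.name,
        "experiment": "semisynthetic_censoring",
        "max_age": max_age,
        "root_seed": config.seed,
        "substream_seeds": seeds,
        "eval_times": eval_times,
        "n_train_events_original": int(sum(p.event for p in train)),
        "n_train_events_semisynthetic": int(sum(p.event for p in train_ss)),
    }
    report = ExperimentReport(
        metrics=pd.concat(metrics_frames, ignore_index=True),
        calibration=pd.concat(calib_frames, ignore_index=True),
        subgroups=pd.DataFrame(),
        manifest=manifest,
        models=models,
    )
    if outdir is not None:
        report.write(outdir)
    return report
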