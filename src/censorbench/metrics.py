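"""Censoring-aware evaluation metrics.

The time-indexed discrimination metrics follow the exclusion construction:
at evaluation age t the cases are patients diagnosed by t (S=1 and T <= t),
the controls are patients known event-free beyond t (T > t), and patients
censored at or before t are excluded entirely — unlike the regular AUC/AP,
which treat every non-diagnosed patient as a negative no matter how short
their follow-up.  The censoring concordance quantifies the pathological
dependence of a model's non-event probabilities on follow-up length among
censored patients (0.5 = no dependence).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "MetricEstimate",
    "KMEstimate",
    "auc_t",
    "ap_t",
    "regular_auc",
    "regular_ap",
    "harrell_c",
    "censoring_concordance",
    "km_estimate",
    "calibration_curve",
    "bootstrap_ci",
]


@dataclass
class MetricEstimate:
    """A point estimate with a percentile-bootstrap confidence interval."""

    metric_name: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    eval_time: Optional[float] = None

    @property
    def half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _case_control_sets(times, events, t):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cases = (events == 1) & (times <= t)
    controls = times > t
    return cases, controls


def auc_t(scores_at_t, times, events, t: float) -> float:
    """Time-varying AUC at age ``t`` (exclusion-based, ties count 1/2)."""
    scores = np.asarray(scores_at_t, dtype=float)
    cases, controls = _case_control_sets(times, events, t)
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError(f"auc_t undefined at t={t}: empty case or control set")
    keep = cases | controls
    return float(roc_auc_score(cases[keep].astype(int), scores[keep]))


def ap_t(scores_at_t, times, events, t: float) -> float:
    """Time-varying average precision over the same case/control sets.

    Mean of the precision at each case's rank in descending-score order
    (score ties broken by index, so continuous scores are unambiguous).
    """
    scores = np.asarray(scores_at_t, dtype=float)
    cases, controls = _case_control_sets(times, events, t)
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError(f"ap_t undefined at t={t}: empty case or control set")
    keep = cases | controls
    y = cases[keep].astype(int)
    s = scores[keep]
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    hits = np.cumsum(y_sorted)
    ranks = np.arange(1, len(y_sorted) + 1)
    precision_at_case = (hits / ranks)[y_sorted == 1]
    return float(precision_at_case.mean())


def regular_auc(scores, observed_labels) -> float:
    """Standard AUC against the observed-diagnosis indicator S.

    Censored patients count as negatives regardless of follow-up, which is
    exactly the construction that inflates under heavy censoring.
    """
    y = np.asarray(observed_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("regular_auc needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def regular_ap(scores, observed_labels) -> float:
    """Standard average precision against the observed-diagnosis indicator."""
    y = np.asarray(observed_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("regular_ap needs both classes present")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def harrell_c(scores, times, events) -> float:
    """Harrell's concordance index for a risk score.

    Comparable pairs are (i, j) with ``T_i < T_j`` and ``S_i = 1``; the index
    is the fraction with ``score_i > score_j``, counting score ties 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(s)
    concordant = 0.0
    comparable = 0
    chunk = 512
    ev_idx = np.flatnonzero(e == 1)
    for start in range(0, len(ev_idx), chunk):
        ii = ev_idx[start : start + chunk]
        later = t[None, :] > t[ii][:, None]  # (c, n)
        comparable += int(later.sum())
        diff = s[ii][:, None] - s[None, :]
        concordant += float(((diff > 0) * later).sum() + 0.5 * ((diff == 0) * later).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return concordant / comparable


def censoring_concordance(nonevent_scores, censor_times, events) -> float:
    """Concordance between predicted non-event probabilities and censoring
    times among censored patients.

    Implemented as Harrell's index on the censored subset with every
    censoring time treated as an outcome and the non-event probability as
    the score: the earlier-censored patient of a pair is counted concordant
    when it received the higher non-event probability.  0.5 means the
    predictions carry no information about follow-up length; larger values
    flag the pathological coupling of predictions to the censoring
    distribution.
    """
    s = np.asarray(nonevent_scores, dtype=float)
    t = np.asarray(censor_times, dtype=float)
    e = np.asarray(events, dtype=int)
    censored = e == 0
    if censored.sum() < 2:
        raise ValueError("need at least two censored patients")
    return harrell_c(s[censored], t[censored], np.ones(int(censored.sum()), dtype=int))


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate with Greenwood standard errors."""

    times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time, non-increasing
    se: np.ndarray  # Greenwood standard error at each event time

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step evaluation of S(t) = P(T > t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate(([1.0], self.survival))
        out = padded[idx]
        return float(out) if out.ndim == 0 else out

    def se_at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate(([0.0], self.se))
        out = padded[idx]
        return float(out) if out.ndim == 0 else out


def km_estimate(times, events) -> KMEstimate:
    """Product-limit estimator of S(t) = P(T > t).

    Censored observations shrink the risk sets without contributing steps;
    with no censoring the estimate reduces to the empirical survival
    function.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv = []
    var_terms = []
    running = 1.0
    cum = 0.0
    for et in event_times:
        at_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        running *= 1.0 - d / at_risk
        if at_risk > d:
            cum += d / (at_risk * (at_risk - d))
        surv.append(running)
        var_terms.append(cum)
    surv = np.asarray(surv)
    se = surv * np.sqrt(np.asarray(var_terms))
    return KMEstimate(times=event_times, survival=surv, se=se)


def calibration_curve(
    predicted_probs_at_t,
    times,
    events,
    t: float,
    n_bins: int = 10,
    min_bin_size: int = 20,
):
    """Observed-vs-predicted incidence at age ``t`` over quantile bins.

    Patients are grouped into quantile bins of predicted probability; within
    each bin the observed incidence is ``1 - S_KM(t)``.  Bins smaller than
    ``min_bin_size`` are merged with their neighbour so the KM estimates stay
    stable.  Returns (mean_predicted, observed_incidence, bin_count,
    observed_se) arrays.
    """
    p = np.asarray(predicted_probs_at_t, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    t_arr = np.asarray(times, dtype=float)
    e_arr = np.asarray(events, dtype=int)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # constant predictions: a single effective bin
        groups = [np.arange(len(p))]
    else:
        assignment = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
        groups = [np.flatnonzero(assignment == k) for k in range(edges.size - 1)]
        groups = [g for g in groups if g.size > 0]
        merged: list[np.ndarray] = []
        for g in groups:  # merge small bins into the previous one
            if merged and (g.size < min_bin_size or merged[-1].size < min_bin_size):
                merged[-1] = np.concatenate([merged[-1], g])
            else:
                merged.append(g)
        groups = merged
    mean_pred, observed, counts, ses = [], [], [], []
    for g in groups:
        km = km_estimate(t_arr[g], e_arr[g])
        mean_pred.append(float(p[g].mean()))
        observed.append(1.0 - km.survival_at(t))
        ses.append(km.se_at(t))
        counts.append(int(g.size))
    return (
        np.asarray(mean_pred),
        np.asarray(observed),
        np.asarray(counts),
        np.asarray(ses),
    )


def bootstrap_ci(
    metric: Callable[[np.ndarray], float],
    n: int,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    metric_name: str = "metric",
    eval_time: Optional[float] = None,
    max_redraws: int = 1000,
) -> MetricEstimate:
    """Percentile bootstrap over patients.

    ``metric`` maps an index array (a resample of ``range(n)``) to a float;
    the point estimate uses the identity indexing.  Resamples on which the
    metric is undefined are redrawn (and logged).
    """
    idx0 = np.arange(n)
    point = float(metric(idx0))
    rng = np.random.default_rng(seed)
    values = []
    redraws = 0
    while len(values) < n_boot:
        sample = rng.integers(0, n, size=n)
        try:
            values.append(float(metric(sample)))
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise ValueError(
                    f"{metric_name}: metric undefined on {max_redraws} resamples"
                )
    if redraws:
        logger.info("%s: redrew %d degenerate bootstrap resamples", metric_name, redraws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return MetricEstimate(
        metric_name=metric_name,
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        eval_time=eval_time,
    )
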