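"""Prediction heads and their losses.

Three heads share one encoder:

* DTNN (discrete-time neural network): softmax over time bins plus a
  beyond-horizon bin, trained with the censored discrete-time likelihood

      L = -( s * log p(t_bin) + (1 - s) * log P(t_bin) ),

  where P(t_bin) is the survival mass strictly after the censoring bin.
* BC (binary classifier): one log-odds output, binary cross-entropy against
  the observed-diagnosis indicator S; its predicted probability is constant
  in the evaluation time by construction.
* DCPH (deep Cox proportional hazards): one log-hazard-ratio output, trained
  with the Cox negative partial log-likelihood (Breslow tie handling);
  absolute probabilities derive from the Breslow baseline cumulative hazard.
"""
from __future__ import annotations

from typing import Union

import numpy as np
from scipy.special import expit, softmax

from .discrete import DiscreteDistribution, TimeGrid

EPS = 1e-12

__all__ = [
    "dtnn_loss",
    "dtnn_loss_batch",
    "softmax_distribution",
    "bc_head_and_loss",
    "bce_loss_batch",
    "cox_partial_loglik",
    "cox_loss_batch",
    "BreslowBaseline",
    "dcph_survival",
]


# ---------------------------------------------------------------------------
# DTNN
# ---------------------------------------------------------------------------
def softmax_distribution(logits: np.ndarray, grid: TimeGrid) -> DiscreteDistribution:
    """Softmax head output as a valid DiscreteDistribution."""
    return DiscreteDistribution(softmax(np.asarray(logits, float), axis=-1), grid)


def dtnn_loss(
    dist: DiscreteDistribution, t_bin: int, s: int, grid: TimeGrid
) -> float:
    """Censored discrete-time negative log-likelihood for one observation.

    For an event (s=1) in bin ``t_bin``: -log of that bin's mass.  For a
    censored observation: -log of the total mass strictly after ``t_bin``
    (for the beyond-horizon bin itself, the beyond mass: the patient survived
    the whole horizon).  Clamped at -log(1e-12).
    """
    t_bin = int(t_bin)
    if not 0 <= t_bin <= grid.beyond_index:
        raise ValueError("t_bin out of range")
    p = np.asarray(dist.bin_probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("dtnn_loss expects a single distribution")
    if s == 1:
        mass = p[t_bin]
    else:
        mass = p[-1] if t_bin == grid.beyond_index else p[t_bin + 1 :].sum()
    return float(-np.log(max(mass, EPS)))


def dtnn_loss_batch(logits: np.ndarray, t_bins: np.ndarray, s: np.ndarray):
    """Mean loss and gradient wrt logits for a batch.

    ``logits``: (B, K+1); ``t_bins``: ints in [0, K]; ``s``: 0/1.
    """
    B, Kp1 = logits.shape
    K = Kp1 - 1
    p = softmax(logits, axis=-1)
    rows = np.arange(B)
    # survival mass strictly after each bin (beyond bin maps to beyond mass)
    csum = np.cumsum(p, axis=-1)
    after = 1.0 - csum[rows, t_bins]
    after = np.where(t_bins == K, p[:, -1], after)
    event_mass = p[rows, t_bins]
    mass = np.where(s == 1, event_mass, after)
    loss = float(np.mean(-np.log(np.maximum(mass, EPS))))

    # gradient
    grad = np.empty_like(p)
    onehot = np.zeros_like(p)
    onehot[rows, t_bins] = 1.0
    grad_event = p - onehot
    with np.errstate(divide="ignore", invalid="ignore"):
        ind_after = (np.arange(Kp1)[None, :] > t_bins[:, None]).astype(float)
        ind_after[t_bins == K, -1] = 1.0  # beyond-bin censoring targets beyond mass
        q = np.maximum(mass, EPS)[:, None]
        grad_cens = p - p * ind_after / q
    grad = np.where((s == 1)[:, None], grad_event, grad_cens) / B
    return loss, grad


# ---------------------------------------------------------------------------
# BC
# ---------------------------------------------------------------------------
def bc_head_and_loss(log_odds: Union[float, np.ndarray], s) -> tuple:
    """Predicted probability and binary cross-entropy for the BC head.

    The probability is the logistic transform of the log-odds and is used
    unchanged at every evaluation time.
    """
    z = np.asarray(log_odds, dtype=float)
    y = np.asarray(s, dtype=float)
    p = expit(z)
    pc = np.clip(p, EPS, 1 - EPS)
    loss = -(y * np.log(pc) + (1 - y) * np.log(1 - pc))
    if z.ndim == 0:
        return float(p), float(loss)
    return p, loss


def bce_loss_batch(logits: np.ndarray, s: np.ndarray):
    """Mean BCE and gradient wrt the (B, 1) logit column."""
    z = logits[:, 0]
    p = expit(z)
    pc = np.clip(p, EPS, 1 - EPS)
    loss = float(np.mean(-(s * np.log(pc) + (1 - s) * np.log(1 - pc))))
    grad = ((p - s) / len(s))[:, None]
    return loss, grad


# ---------------------------------------------------------------------------
# DCPH
# ---------------------------------------------------------------------------
def cox_partial_loglik(
    log_hazard_ratios: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Cox negative partial log-likelihood with Breslow tie handling.

    Sum over events of ``-(r_i - log sum_{j: T_j >= T_i} exp(r_j))``; tied
    event times share the full risk set.  Invariant to adding a constant to
    all log-hazard ratios.
    """
    r = np.asarray(log_hazard_ratios, dtype=float)
    t = np.asarray(times, dtype=float)
    s = np.asarray(events, dtype=int)
    if not (len(r) == len(t) == len(s)):
        raise ValueError("inputs must have equal length")
    if s.sum() == 0:
        raise ValueError("partial likelihood undefined without events")
    order = np.argsort(t, kind="stable")
    r, t, s = r[order], t[order], s[order]
    shift = r.max()
    exp_r = np.exp(r - shift)
    rev = np.cumsum(exp_r[::-1])[::-1]
    # risk set for time T_i includes all ties: first index with that time
    first = np.searchsorted(t, t, side="left")
    log_risk = np.log(rev[first]) + shift
    return float(np.sum((log_risk - r)[s == 1]))


def cox_loss_batch(logits: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Mean (per event) Breslow partial-likelihood loss and gradient.

    Gradient wrt r_j:  sum_{events i: T_i <= T_j} exp(r_j) / S_i  minus the
    event indicator, scaled by 1 / #events.
    """
    r = logits[:, 0]
    t = np.asarray(times, dtype=float)
    s = np.asarray(events, dtype=int)
    d = int(s.sum())
    if d == 0:
        return 0.0, np.zeros_like(logits)
    order = np.argsort(t, kind="stable")
    ro, to, so = r[order], t[order], s[order]
    shift = ro.max()
    exp_r = np.exp(ro - shift)
    rev = np.cumsum(exp_r[::-1])[::-1]
    first = np.searchsorted(to, to, side="left")
    log_risk = np.log(rev[first]) + shift
    loss = float(np.sum((log_risk - ro)[so == 1]) / d)

    inv_risk = np.where(so == 1, 1.0 / rev[first], 0.0)
    # A_j = sum over events with T_i <= T_j of 1/S_i  (ties included)
    csum = np.cumsum(inv_risk)
    last = np.searchsorted(to, to, side="right") - 1
    A = csum[last]
    grad_sorted = (exp_r * A - so) / d
    grad = np.zeros_like(r)
    grad[order] = grad_sorted
    return loss, grad[:, None]


class BreslowBaseline:
    """Breslow estimator of the baseline cumulative hazard H0(t).

    Fitted on training data given the predicted log-hazard ratios; beyond the
    last training time the cumulative hazard is carried forward flat.
    """

    def __init__(self, log_hazard_ratios, times, events):
        r = np.asarray(log_hazard_ratios, dtype=float)
        t = np.asarray(times, dtype=float)
        s = np.asarray(events, dtype=int)
        if s.sum() == 0:
            raise ValueError("cannot fit a baseline hazard without events")
        order = np.argsort(t, kind="stable")
        r, t, s = r[order], t[order], s[order]
        shift = r.max()
        exp_r = np.exp(r - shift)
        rev = np.cumsum(exp_r[::-1])[::-1]
        event_times, counts = np.unique(t[s == 1], return_counts=True)
        first = np.searchsorted(t, event_times, side="left")
        increments = counts / (rev[first] * np.exp(shift))
        self.times = event_times
        self.cumhaz = np.cumsum(increments)

    def cumulative_hazard(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate(([0.0], self.cumhaz))
        return padded[idx]


def dcph_survival(log_hazard_ratio, baseline: BreslowBaseline, t) -> np.ndarray:
    """Event probability by time t: ``1 - exp(-H0(t) * exp(r))``.

    Non-decreasing in t and order-preserving in the log-hazard ratio at
    every t (the proportional-hazards property).
    """
    H0 = baseline.cumulative_hazard(t)
    r = np.asarray(log_hazard_ratio, dtype=float)
    out = 1.0 - np.exp(-H0 * np.exp(r))
    if out.ndim == 0:
        return float(out)
    return out
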