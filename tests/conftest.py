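"""Shared fixtures and independent brute-force oracles.

The oracle functions enumerate pairs / ranks / risk sets explicitly and are
kept deliberately naive so that they stay independent of the vectorised
implementations they check.
"""
from __future__ import annotations

import numpy as np
import pytest

from censorbench import CohortConfig, generate_cohort


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------
def brute_auc_t(scores, times, events, t):
    num = den = 0.0
    for i in range(len(scores)):
        if not (events[i] == 1 and times[i] <= t):
            continue
        for j in range(len(scores)):
            if times[j] > t:
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brute_ap_t(scores, times, events, t):
    keep = [
        i
        for i in range(len(scores))
        if (events[i] == 1 and times[i] <= t) or times[i] > t
    ]
    y = [1 if (events[i] == 1 and times[i] <= t) else 0 for i in keep]
    s = [scores[i] for i in keep]
    order = sorted(range(len(s)), key=lambda k: -s[k])
    precisions, hits = [], 0
    for rank, k in enumerate(order, start=1):
        if y[k] == 1:
            hits += 1
            precisions.append(hits / rank)
    return sum(precisions) / len(precisions)


def brute_harrell_c(scores, times, events):
    num = den = 0.0
    for i in range(len(scores)):
        if events[i] != 1:
            continue
        for j in range(len(scores)):
            if times[i] < times[j]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brute_cox_npll(log_hr, times, events):
    """Breslow negative partial log-likelihood via explicit risk sets."""
    total = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        total += np.log(np.sum(np.exp([log_hr[j] for j in risk]))) - log_hr[i]
    return total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------
@pytest.fixture(scope="session")
def small_cohort():
    """A small generic cohort with events, censoring and code sequences."""
    cfg = CohortConfig(
        n_patients=400,
        baseline_hazards=(0.05, 0.08, 0.08, 0.06, 0.05, 0.05),
        mean_codes_per_year=4.0,
        dropout_rate=0.08,
        seed=42,
    )
    return generate_cohort(cfg)
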