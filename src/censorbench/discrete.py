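"""Time discretisation and per-patient discrete event-time distributions.

A :class:`TimeGrid` partitions the prediction window ``(left, E_max]`` into
half-open bins ``(edge_{k-1}, edge_k]`` plus an implicit beyond-horizon
category for times after ``E_max`` (including "the event never occurs within
the horizon").  A :class:`DiscreteDistribution` holds one probability mass
per bin plus the beyond-horizon mass; survival functions and cumulative
incidence derive from it by partial sums.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeGrid", "DiscreteDistribution"]


@dataclass(frozen=True)
class TimeGrid:
    """Right bin edges over ``(left, E_max]``; ``edges[-1]`` is the horizon."""

    edges: tuple[float, ...]
    left: float = 0.0

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size == 0 or np.any(np.diff(e) <= 0) or e[0] <= self.left:
            raise ValueError("edges must be strictly increasing and exceed left")
        object.__setattr__(self, "edges", tuple(float(x) for x in e))

    @classmethod
    def regular(cls, left: float, horizon: float, width: float = 1.0) -> "TimeGrid":
        """Evenly spaced bins of ``width`` from ``left`` up to (at least) ``horizon``."""
        if horizon <= left or width <= 0:
            raise ValueError("need horizon > left and positive width")
        k = int(np.ceil((horizon - left) / width - 1e-12))
        return cls(edges=tuple(left + width * np.arange(1, k + 1)), left=left)

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def e_max(self) -> float:
        return self.edges[-1]

    @property
    def beyond_index(self) -> int:
        """Index of the beyond-horizon category."""
        return self.n_bins

    def bin_of(self, times) -> np.ndarray:
        """Map times in ``(left, inf]`` to bin indices; > E_max maps to beyond."""
        t = np.asarray(times, dtype=float)
        if np.any(t <= self.left):
            raise ValueError("times must exceed the grid's left boundary")
        idx = np.searchsorted(np.asarray(self.edges), t, side="left")
        return idx if idx.shape else int(idx)

    def n_complete_bins_by(self, t: float) -> int:
        """Number of bins entirely at or before time ``t``."""
        return int(np.searchsorted(np.asarray(self.edges), t, side="right"))


class DiscreteDistribution:
    """Probability mass over the grid's bins plus the beyond-horizon entry.

    Accepts a single distribution (shape ``(n_bins+1,)``) or a batch
    (shape ``(n, n_bins+1)``).
    """

    def __init__(self, bin_probs, grid: TimeGrid, atol: float = 1e-6):
        p = np.asarray(bin_probs, dtype=float)
        if p.shape[-1] != grid.n_bins + 1:
            raise ValueError(
                f"expected {grid.n_bins + 1} entries (bins + beyond), got {p.shape[-1]}"
            )
        if np.any(p < -atol):
            raise ValueError("probabilities must be non-negative")
        total = p.sum(axis=-1)
        if np.any(np.abs(total - 1.0) > atol):
            raise ValueError("probabilities must sum to 1")
        self.bin_probs = np.clip(p, 0.0, None)
        self.grid = grid

    @property
    def beyond_mass(self) -> np.ndarray:
        return self.bin_probs[..., -1]

    def event_probability_by(self, t: float) -> np.ndarray:
        """Cumulative incidence at ``t``: mass of bins completed by ``t``.

        Piecewise constant between bin edges (mass is attributed when a bin
        completes); at E_max this equals 1 minus the beyond-horizon mass.
        """
        if not (self.grid.left < t <= self.grid.e_max):
            raise ValueError("t must lie in (left, E_max]")
        m = self.grid.n_complete_bins_by(t)
        return self.bin_probs[..., :m].sum(axis=-1)

    def survival_beyond_bin(self, k) -> np.ndarray:
        """P(T in a bin strictly after bin k), vectorised over k.

        For k equal to the beyond index this returns the beyond-horizon mass
        itself (the probability of surviving the whole horizon).
        """
        csum = np.cumsum(self.bin_probs, axis=-1)
        total = csum[..., -1]
        k = np.asarray(k)
        after = total - np.take_along_axis(
            csum, np.broadcast_to(k, csum.shape[:-1])[..., None], axis=-1
        )[..., 0]
        beyond = self.bin_probs[..., -1]
        return np.where(k == self.grid.beyond_index, beyond, after)

    def survival_curve(self) -> np.ndarray:
        """S(edge_k) = P(T > edge_k) for each right edge; non-increasing."""
        return 1.0 - np.cumsum(self.bin_probs[..., :-1], axis=-1)
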