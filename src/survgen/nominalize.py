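"""Kaplan-Meier estimation and area-maximizing dichotomization.

To show a numeric attribute in a survival plot it must first be
*nominalized*: split at a cutoff ``c`` into the two groups ``A <= c`` and
``A > c``, whose Kaplan-Meier curves ``S(t | A <= c)`` and ``S(t | A > c)``
are then drawn.  The cutoff is chosen to maximize the area between the two
curves — the most discriminating split.

Candidate cutoffs are the midpoints between consecutive distinct sorted
attribute values (so ``A <= c`` is unambiguous under floating-point
noise); every candidate is evaluated exhaustively, and since one
Kaplan-Meier pass over time-sorted data is linear, the whole search is
O(N^2) in the number of subjects.  Ties in the objective are broken toward
the smallest cutoff, and the area is integrated over the pooled follow-up
range (curves are undefined beyond it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import NoValidCutoffError, ParameterError

__all__ = [
    "KMCurve",
    "CutoffResult",
    "km_estimate",
    "area_between_curves",
    "find_best_cutoff",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate of S(t) as a right-continuous step function.

    ``times`` is the strictly increasing grid of event times at which the
    curve steps; ``survival`` the estimate just after each step;
    ``n_at_risk`` the risk-set size at each event time.  S(t) = 1 for t
    before the first event time.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def survival_at(self, t):
        """Evaluate the step function at scalar or array ``t`` (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate(([1.0], self.survival))
        out = padded[idx]
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CutoffResult:
    """Best dichotomization of a numeric attribute against survival."""

    cutoff: float
    area: float
    n_low: int
    n_high: int


def _km_from_sorted(times: np.ndarray, events: np.ndarray):
    """Product-limit steps from time-sorted inputs; ties are handled by the
    standard convention that subjects censored at t remain at risk for
    events at t (events before censorings)."""
    n = len(times)
    event_times = times[events == 1]
    if len(event_times) == 0:
        return (
            np.empty(0, dtype=float),
            np.empty(0, dtype=float),
            np.empty(0, dtype=int),
        )
    step_times, deaths = np.unique(event_times, return_counts=True)
    # risk set at t: everyone with observed time >= t
    at_risk = n - np.searchsorted(times, step_times, side="left")
    survival = np.cumprod(1.0 - deaths / at_risk)
    return step_times, survival, at_risk


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier (product-limit) estimate from times and 0/1 event flags.

    Censored observations (event = 0) shrink the risk set without
    producing a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ParameterError("km_estimate requires at least one observation")
    if times.shape != events.shape:
        raise ParameterError("times and events must have equal length")
    if np.any(times <= 0):
        raise ParameterError("observation times must be > 0")
    if not np.all(np.isin(events, (0, 1))):
        raise ParameterError("events must be 0 (censored) or 1 (event)")
    order = np.argsort(times, kind="stable")
    step_times, survival, at_risk = _km_from_sorted(times[order], events[order])
    return KMCurve(times=step_times, survival=survival, n_at_risk=at_risk)


def _area_between_steps(t1, s1, t2, s2, t_max: float) -> float:
    """Exact integral of |S1 - S2| on [0, t_max] over the merged step grid."""
    grid = np.unique(np.concatenate(([0.0], t1, t2, [t_max])))
    grid = grid[(grid >= 0.0) & (grid <= t_max)]
    if grid[-1] < t_max:
        grid = np.append(grid, t_max)
    left = grid[:-1]
    widths = np.diff(grid)
    pad1 = np.concatenate(([1.0], s1))
    pad2 = np.concatenate(([1.0], s2))
    v1 = pad1[np.searchsorted(t1, left, side="right")]
    v2 = pad2[np.searchsorted(t2, left, side="right")]
    return float(np.sum(np.abs(v1 - v2) * widths))


def area_between_curves(c1: KMCurve, c2: KMCurve, t_max: float) -> float:
    """Area enclosed between two survival step curves up to ``t_max``.

    Computed exactly as the integral of the absolute difference over the
    union of both step grids; identical curves give 0.
    """
    if not t_max > 0:
        raise ParameterError(f"t_max must be > 0, got {t_max}")
    return _area_between_steps(c1.times, c1.survival, c2.times, c2.survival, t_max)


def find_best_cutoff(
    values,
    times,
    events,
    min_group_size: int = 1,
    t_max: Optional[float] = None,
) -> CutoffResult:
    """Exhaustive search for the area-maximizing dichotomization cutoff.

    Evaluates every midpoint between consecutive distinct attribute
    values; each candidate splits the cohort into ``A <= c`` / ``A > c``,
    whose Kaplan-Meier curves and enclosed area are computed on
    time-pre-sorted arrays (one linear pass per candidate, O(N^2) total).
    Returns the maximizer; exact objective ties resolve to the smallest
    cutoff.  ``min_group_size`` excludes degenerate splits.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(values) == len(times) == len(events)):
        raise ParameterError("values, times and events must have equal length")
    if min_group_size < 1:
        raise ParameterError(f"min_group_size must be >= 1, got {min_group_size}")
    distinct = np.unique(values)
    if len(distinct) < 2:
        raise NoValidCutoffError(
            "attribute is constant: no cutoff can split it into two groups"
        )
    if t_max is None:
        t_max = float(times.max())

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    v_sorted = values[order]

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best: Optional[CutoffResult] = None
    for c in candidates:
        low = v_sorted <= c
        n_low = int(low.sum())
        n_high = len(values) - n_low
        if n_low < min_group_size or n_high < min_group_size:
            continue
        lt, ls, _ = _km_from_sorted(t_sorted[low], e_sorted[low])
        ht, hs, _ = _km_from_sorted(t_sorted[~low], e_sorted[~low])
        area = _area_between_steps(lt, ls, ht, hs, t_max)
        if best is None or area > best.area:
            best = CutoffResult(
                cutoff=float(c), area=area, n_low=n_low, n_high=n_high
            )
    if best is None:
        raise NoValidCutoffError(
            f"no cutoff leaves at least {min_group_size} subjects on each side"
        )
    return best
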