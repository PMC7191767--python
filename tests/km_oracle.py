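"""Independent reference implementations used as test oracles.

The Kaplan-Meier curves come from lifelines and the area/cutoff search is
a deliberately naive re-derivation, sharing no code with the package.
"""

import numpy as np
from lifelines import KaplanMeierFitter


def lifelines_survival_at(times, events, query_times):
    """Right-continuous KM step values at ``query_times`` via lifelines."""
    kmf = KaplanMeierFitter().fit(times, events)
    return np.asarray(kmf.predict(np.asarray(query_times, dtype=float)), dtype=float)


def naive_area(times_a, events_a, times_b, events_b, t_max):
    """Exact area between two KM step curves on [0, t_max].

    The grid of all observed times is a superset of both curves' step
    points, so evaluating at interval left endpoints integrates exactly.
    """
    grid = np.unique(np.concatenate(([0.0], times_a, times_b, [t_max])))
    grid = grid[grid <= t_max]
    if grid[-1] < t_max:
        grid = np.append(grid, t_max)
    lefts = grid[:-1]
    sa = lifelines_survival_at(times_a, events_a, lefts)
    sb = lifelines_survival_at(times_b, events_b, lefts)
    return float(np.sum(np.abs(sa - sb) * np.diff(grid)))


def naive_best_cutoff(values, times, events, min_group_size=1, t_max=None):
    """Brute-force area-maximizing cutoff; ties toward the smallest cutoff."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if t_max is None:
        t_max = float(times.max())
    distinct = np.unique(values)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        c = (lo + hi) / 2.0
        low = values <= c
        if low.sum() < min_group_size or (~low).sum() < min_group_size:
            continue
        area = naive_area(times[low], events[low], times[~low], events[~low], t_max)
        if best is None or area > best[1]:
            best = (float(c), area)
    return best
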