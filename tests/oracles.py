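"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: rank tests are
computed by full enumeration of sign patterns / rank assignments, and
flux-event detection by an explicit per-sample run-and-merge loop.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def signed_rank_exact_p(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n
    sign patterns of the non-zero differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ]
    )
    p = 2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, float(p))


def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n+m, n) rank
    assignments to the first sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [
            ranks[list(comb)].sum() - n * (n + 1) / 2
            for comb in itertools.combinations(range(n + m), n)
        ]
    )
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, float(p))


def detect_events_bruteforce(times, values, threshold, merge_window):
    """Per-sample run construction followed by an explicit gap-merge
    loop; returns a list of (start_index, end_index) episodes."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    runs = []
    i = 0
    while i < len(values):
        if values[i] >= threshold:
            j = i
            while j + 1 < len(values) and values[j + 1] >= threshold:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and times[run[0]] - times[merged[-1][1]] < merge_window:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [tuple(r) for r in merged]


def total_flux_time_bruteforce(values, threshold, dt) -> float:
    return sum(1 for v in values if v > threshold) * dt
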