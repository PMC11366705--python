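"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a method unrelated to the library
implementation it checks: dense-grid scanning for half-level crossings,
exhaustive permutation enumeration for the Mann-Whitney null, and a naive
neighbour scan for local extrema.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def dense_half_crossing(
    values: np.ndarray,
    positions: np.ndarray,
    flank: tuple[int, int],
    level: float,
    near_position: float,
    resolution: float = 1e-4,
) -> float:
    """Half-level crossing of the piecewise-linear profile within a flank.

    Evaluates the linear interpolant on a dense grid and returns the
    sign-change location (refined by linear inversion on the bracketing
    grid cell) nearest ``near_position``.
    """
    a, b = flank
    xs = np.arange(positions[a], positions[b] + resolution / 2, resolution)
    ys = np.interp(xs, positions[a : b + 1], values[a : b + 1])
    sign = np.sign(ys - level)
    idx = np.flatnonzero(np.diff(sign) != 0)
    hits = []
    for i in idx:
        y0, y1 = ys[i], ys[i + 1]
        hits.append(xs[i] + (level - y0) / (y1 - y0) * resolution)
    exact = xs[np.flatnonzero(sign == 0)]
    hits.extend(exact.tolist())
    if not hits:
        raise AssertionError("oracle found no half-level crossing in flank")
    hits = np.asarray(hits)
    return float(hits[np.argmin(np.abs(hits - near_position))])


def mann_whitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data).

    Enumerates all C(n+m, n) assignments of the pooled sample to the two
    groups, computes the U statistic of group A for each, and reports the
    symmetric two-sided tail probability of the observed U.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == n + m, "oracle requires tie-free data"
    u_obs = sum(1 for x in a for y in b if x > y)
    total = comb(n + m, n)
    count_le = 0
    count_ge = 0
    idx_all = set(range(n + m))
    for combo in combinations(range(n + m), n):
        ga = pooled[list(combo)]
        gb = pooled[list(idx_all - set(combo))]
        u = sum(1 for x in ga for y in gb if x > y)
        if u <= u_obs:
            count_le += 1
        if u >= u_obs:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return min(1.0, p)


def scan_local_minima(values: np.ndarray) -> list[int]:
    """Strict local minima (plateau minima report their central index)."""
    v = np.asarray(values, float)
    out = []
    i = 1
    while i < len(v) - 1:
        j = i
        while j + 1 < len(v) and v[j + 1] == v[i]:
            j += 1
        if v[i - 1] > v[i] and j + 1 < len(v) and v[j + 1] > v[i]:
            out.append((i + j) // 2)
        i = j + 1
    return out
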