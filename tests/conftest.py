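"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (index-wise
scanning, exhaustive path enumeration) so they share no code path with the
library implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenocycle import NDVISeries


@pytest.fixture
def make_series():
    def _make(values, pixel_id="test"):
        return NDVISeries.from_values(values, pixel_id=pixel_id)

    return _make


def brute_force_cycle_count(
    values,
    vegetation_floor: float = 0.3,
    peak_fraction: float = 0.70,
    valley_fraction: float = 0.20,
) -> int:
    """Direct prose reading of the adaptive counting rule, index by index.

    Independent of the library's run-length-compression implementation: each
    index is examined against its nearest differing neighbours on each side.
    """
    v = [float(x) for x in values]
    n = len(v)
    m = max(v)
    if m < vegetation_floor:
        return 0
    peak_thr = peak_fraction * m
    valley_thr = valley_fraction * m

    def nearest_differing(i, step):
        j = i + step
        while 0 <= j < n and v[j] == v[i]:
            j += step
        return v[j] if 0 <= j < n else None

    def plateau_first(i):
        return i == 0 or v[i - 1] != v[i]

    def plateau_last(i):
        return i == n - 1 or v[i + 1] != v[i]

    peaks, valleys = [], []
    for i in range(n):
        if not plateau_first(i):
            continue
        left = nearest_differing(i, -1)
        right = nearest_differing(i, +1)
        if left is None and right is None:
            continue
        higher_left = left is None or left < v[i]
        higher_right = right is None or right < v[i]
        lower_left = left is None or left > v[i]
        lower_right = right is None or right > v[i]
        if higher_left and higher_right and v[i] >= peak_thr:
            peaks.append(i)
        if lower_left and lower_right and v[i] <= valley_thr:
            valleys.append(i)

    count = 0
    for p in peaks:
        e = p
        while not plateau_last(e):
            e += 1
        left_ok = any(q < p for q in valleys)
        right_ok = any(q > e for q in valleys)
        if p > 0 and e < n - 1:
            accepted = left_ok and right_ok
        elif p == 0 and e == n - 1:
            accepted = False
        elif p == 0:
            accepted = right_ok
        else:
            accepted = left_ok
        if accepted:
            count += 1
    return count


def brute_force_dtw(a, b) -> float:
    """DTW cost by exhaustive enumeration of every monotone warping path."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n, m = len(a), len(b)
    best = float("inf")
    # depth-first over all paths from (0,0) to (n-1,m-1) stepping
    # right/down/diagonal, accumulating |a_i - b_j| at every visited cell
    stack = [(0, 0, abs(a[0] - b[0]))]
    while stack:
        i, j, cost = stack.pop()
        if i == n - 1 and j == m - 1:
            best = min(best, cost)
            continue
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                stack.append((ni, nj, cost + abs(a[ni] - b[nj])))
    return best
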