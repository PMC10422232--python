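"""Adaptive-threshold crop-cycle counting.

Crop intensity is the number of complete sow–grow–harvest cycles a pixel
exhibits in one year, labelled 0–3.  Each cycle appears in a reconstructed
NDVI series as a peak flanked by valleys.  Fixed peak thresholds undercount
low-amplitude crops, so the thresholds here adapt to each series: with
``m = max(series)``,

* if ``m < vegetation_floor`` (0.3) the series cannot be actively cropped
  (bare soil, rock, water, sparse vegetation) and is labelled 0 outright;
* otherwise peaks qualify at ``peak_fraction * m`` (0.70 m) and valleys at
  ``valley_fraction * m`` (0.20 m), which rejects the small spurious bumps
  weeds leave in the series while keeping genuine low-amplitude crop peaks.

A qualifying peak is counted as a cycle when a qualifying valley lies on each
side; a peak at a series endpoint needs a valley on its single inward side
only.  Plateaus of equal values collapse to one extremum at their first index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import NDVISeries

__all__ = [
    "CycleThresholds",
    "CLASS_ZERO",
    "derive_thresholds",
    "find_extrema",
    "count_cycles",
    "count_cycles_static",
    "label_intensity",
]

#: Sentinel returned by :func:`derive_thresholds` when the series maximum is
#: below the vegetation floor and the pixel is labelled class 0 outright.
CLASS_ZERO = "CLASS_ZERO"


@dataclass(frozen=True)
class CycleThresholds:
    """Adaptive thresholding parameters.

    ``vegetation_floor`` is an absolute NDVI level; ``peak_fraction`` and
    ``valley_fraction`` multiply the series' own maximum.
    """

    vegetation_floor: float = 0.3
    peak_fraction: float = 0.70
    valley_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (0 < self.valley_fraction < self.peak_fraction <= 1):
            raise ValueError("require 0 < valley_fraction < peak_fraction <= 1")
        if not (0 < self.vegetation_floor < 1):
            raise ValueError("vegetation_floor must lie in (0, 1)")


def _require_gap_free(series: NDVISeries) -> np.ndarray:
    if len(series) == 0:
        raise ValueError("empty series")
    if not series.is_gap_free:
        raise ValueError("cycle counting requires a reconstructed, gap-free series")
    return series.values


def derive_thresholds(
    series: NDVISeries, params: CycleThresholds | None = None
):
    """Per-series peak/valley thresholds, or :data:`CLASS_ZERO`.

    Returns ``(peak_threshold, valley_threshold)`` computed from the series
    maximum ``m`` as ``(peak_fraction * m, valley_fraction * m)``, or the
    :data:`CLASS_ZERO` flag when ``m`` is strictly below the vegetation floor.
    """
    params = params or CycleThresholds()
    v = _require_gap_free(series)
    m = float(np.max(v))
    if m < params.vegetation_floor:
        return CLASS_ZERO
    return params.peak_fraction * m, params.valley_fraction * m


def _runs(values: np.ndarray):
    """Run-length encode equal consecutive values -> (start, end, value) triples."""
    runs = []
    start = 0
    n = len(values)
    for i in range(1, n + 1):
        if i == n or values[i] != values[start]:
            runs.append((start, i - 1, float(values[start])))
            start = i
    return runs


def find_extrema(series: NDVISeries, peak_threshold: float, valley_threshold: float):
    """Indices of qualifying peaks and valleys.

    A peak is a local maximum with value >= ``peak_threshold``; a valley a
    local minimum with value <= ``valley_threshold`` (both inclusive, since
    the thresholds derive from the series itself).  Plateaus collapse to
    their first index; endpoints are compared against their single
    neighbour.  A constant series has no extrema.
    """
    v = _require_gap_free(series)
    runs = _runs(v)
    peaks: list[int] = []
    valleys: list[int] = []
    for j, (start, _end, val) in enumerate(runs):
        left = runs[j - 1][2] if j > 0 else None
        right = runs[j + 1][2] if j < len(runs) - 1 else None
        if left is None and right is None:
            continue  # constant series: no well-defined extremum
        is_max = (left is None or val > left) and (right is None or val > right)
        is_min = (left is None or val < left) and (right is None or val < right)
        if is_max and val >= peak_threshold:
            peaks.append(start)
        if is_min and val <= valley_threshold:
            valleys.append(start)
    return peaks, valleys


def _count_from_thresholds(
    v: np.ndarray, series: NDVISeries, peak_thr: float, valley_thr: float
) -> int:
    peaks, valleys = find_extrema(series, peak_thr, valley_thr)
    if not peaks:
        return 0
    valleys_arr = np.asarray(valleys)
    runs = _runs(v)
    run_span = {start: end for start, end, _ in runs}
    n = len(v)
    count = 0
    for p in peaks:
        end = run_span[p]
        need_left = p > 0
        need_right = end < n - 1
        has_left = bool(valleys_arr.size) and bool(np.any(valleys_arr < p))
        has_right = bool(valleys_arr.size) and bool(np.any(valleys_arr > end))
        if need_left and need_right:
            ok = has_left and has_right
        elif need_left:
            ok = has_left  # peak at the right endpoint: valley must lead it
        elif need_right:
            ok = has_right  # peak at the left endpoint: valley must follow it
        else:
            ok = False  # plateau spanning the whole series
        if ok:
            count += 1
    return count


def count_cycles(series: NDVISeries, params: CycleThresholds | None = None) -> int:
    """Number of crop cycles under adaptive thresholds (0 on CLASS_ZERO)."""
    params = params or CycleThresholds()
    v = _require_gap_free(series)
    thr = derive_thresholds(series, params)
    if thr == CLASS_ZERO:
        return 0
    peak_thr, valley_thr = thr
    return _count_from_thresholds(v, series, peak_thr, valley_thr)


def count_cycles_static(
    series: NDVISeries,
    static_peak_threshold: float,
    params: CycleThresholds | None = None,
) -> int:
    """Cycle count under a fixed absolute peak threshold (baseline method).

    Same acceptance logic as :func:`count_cycles`, but the peak threshold is
    a fixed NDVI value and the valley threshold is scaled from it by the same
    valley/peak ratio.  Low-amplitude crops whose peaks fall below the fixed
    threshold are undercounted — the failure mode the adaptive method avoids.
    """
    params = params or CycleThresholds()
    v = _require_gap_free(series)
    valley_thr = static_peak_threshold * params.valley_fraction / params.peak_fraction
    return _count_from_thresholds(v, series, static_peak_threshold, valley_thr)


def label_intensity(series: NDVISeries, params: CycleThresholds | None = None) -> int:
    """Crop-intensity class label: cycle count clamped to the range 0-3."""
    return min(count_cycles(series, params), 3)
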