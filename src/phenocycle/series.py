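"""Per-pixel NDVI series and the three-stage time-series reconstruction.

NDVI (Normalized Difference Vegetation Index) is computed from near-infrared
and red surface reflectance as ``(NIR - red) / (NIR + red)`` and lies in
``[-1, 1]``.  One pixel-year at 15-day compositing gives a 24-point series.
Cloud cover leaves gaps; atmospheric residuals leave implausible jumps.
Reconstruction proceeds in three fixed stages:

1. **Gap filling** — iterative neighbour-averaging: every missing point with
   at least one observed immediate neighbour is replaced by the mean of its
   observed immediate neighbours; passes repeat so runs of missing values
   close from their edges inward.
2. **Jump correction** — a left-to-right scan replaces any point whose jump
   from its (already corrected) left neighbour exceeds ``jump_threshold``
   with the midpoint of its neighbours.
3. **Savitzky–Golay smoothing** — a sliding-window least-squares polynomial
   smoother.

A window-3 / order-2 Savitzky–Golay filter — the default — is mathematically
the identity transform (three points determine a parabola exactly), so the
default smoothing stage passes the series through unchanged; order 1 (a
3-point moving average) is selectable for effective smoothing, at the cost of
attenuating narrow crop peaks by roughly 20%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralSample",
    "NDVISeries",
    "ReconstructionConfig",
    "UnrecoverableSeriesError",
    "compute_ndvi",
    "fill_gaps",
    "correct_jumps",
    "savgol_smooth",
    "reconstruct",
]


class UnrecoverableSeriesError(ValueError):
    """Raised when a series has no observed values to reconstruct from."""


@dataclass(frozen=True)
class SpectralSample:
    """Surface reflectance in the near-infrared and red bands (unitless, >= 0)."""

    nir: float
    red: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.nir) and np.isfinite(self.red)):
            raise ValueError("reflectances must be finite")
        if self.nir < 0 or self.red < 0:
            raise ValueError("reflectances must be non-negative")


def compute_ndvi(sample: SpectralSample) -> float:
    """NDVI = (NIR - red)/(NIR + red); ``nan`` (missing) when both bands are zero."""
    denom = sample.nir + sample.red
    if denom == 0:
        return float("nan")
    return (sample.nir - sample.red) / denom


@dataclass
class NDVISeries:
    """One pixel-year of NDVI observations.

    Missing observations are carried as a boolean mask; the value slots under
    the mask hold ``nan`` and are never interpreted.  ``times`` are composite
    indices (0..T-1), strictly increasing; nominally T = 24 for one year of
    15-day composites.
    """

    values: np.ndarray
    missing: np.ndarray
    times: np.ndarray
    pixel_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.times = np.asarray(self.times)
        self.validate()

    @classmethod
    def from_values(
        cls,
        values,
        times=None,
        pixel_id: str = "",
    ) -> "NDVISeries":
        """Build a series from a value sequence; ``nan`` entries become missing."""
        v = np.asarray(values, dtype=float)
        miss = ~np.isfinite(v)
        v = np.where(miss, np.nan, v)
        t = np.arange(len(v)) if times is None else np.asarray(times)
        s = cls(values=v, missing=miss, times=t, pixel_id=pixel_id)
        s.validate()
        return s

    def validate(self) -> None:
        if len(self.values) != len(self.times) or len(self.values) != len(self.missing):
            raise ValueError("values, missing and times must have equal length")
        if len(self.values) < 1:
            raise ValueError("series must contain at least one point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        obs = self.values[~self.missing]
        if obs.size and (np.any(obs < -1) or np.any(obs > 1)):
            raise ValueError("observed NDVI values must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_gap_free(self) -> bool:
        return not bool(self.missing.any())

    def with_values(self, values: np.ndarray, missing=None) -> "NDVISeries":
        miss = (
            np.zeros(len(values), dtype=bool)
            if missing is None
            else np.asarray(missing, dtype=bool)
        )
        return NDVISeries(
            values=np.asarray(values, dtype=float),
            missing=miss,
            times=self.times.copy(),
            pixel_id=self.pixel_id,
        )


@dataclass(frozen=True)
class ReconstructionConfig:
    """Knobs of the three reconstruction stages.

    jump_threshold
        NDVI difference between adjacent composites above which the second
        point is treated as an artefact (default 0.4, roughly half the
        largest NDVI value a crop pixel attains).
    sg_window, sg_polyorder
        Savitzky–Golay window length (odd) and polynomial order.  Order 2
        with window 3 (default) is the identity filter; order 1 with window
        3 is a 3-point moving average.
    max_fill_iterations
        Cap on gap-filling passes; each pass closes every missing run by one
        point from each end.
    """

    jump_threshold: float = 0.4
    sg_window: int = 3
    sg_polyorder: int = 2
    max_fill_iterations: int = 10

    def __post_init__(self) -> None:
        if self.jump_threshold <= 0:
            raise ValueError("jump_threshold must be positive")
        if self.sg_window % 2 == 0 or self.sg_window < 1:
            raise ValueError("sg_window must be odd and positive")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be smaller than sg_window")
        if self.max_fill_iterations < 1:
            raise ValueError("max_fill_iterations must be positive")
        if self.sg_window == 3 and self.sg_polyorder == 2:
            logger.info(
                "Savitzky-Golay window 3 with polynomial order 2 is the "
                "identity filter; smoothing will not alter the series."
            )


def fill_gaps(series: NDVISeries, config: ReconstructionConfig | None = None) -> NDVISeries:
    """Close missing values by iterative neighbour averaging.

    Each pass replaces every missing point that has at least one observed
    immediate neighbour with the mean of its observed immediate neighbours
    (one neighbour at the series ends, so leading/trailing runs copy the
    nearest observed value).  All replacements in a pass read the state at
    the start of the pass, so runs close symmetrically from both edges.
    """
    config = config or ReconstructionConfig()
    if series.missing.all():
        raise UnrecoverableSeriesError(
            f"series {series.pixel_id!r} has no observed values"
        )
    if series.is_gap_free:
        return series.with_values(series.values.copy())

    v = series.values.copy()
    miss = series.missing.copy()
    n = len(v)
    for _ in range(config.max_fill_iterations):
        if not miss.any():
            break
        v_prev, miss_prev = v.copy(), miss.copy()
        for i in np.flatnonzero(miss_prev):
            neigh = []
            if i > 0 and not miss_prev[i - 1]:
                neigh.append(v_prev[i - 1])
            if i < n - 1 and not miss_prev[i + 1]:
                neigh.append(v_prev[i + 1])
            if neigh:
                v[i] = float(np.mean(neigh))
                miss[i] = False
    if miss.any():
        # cap reached with a long run still open: take the nearest observed value
        obs_idx = np.flatnonzero(~miss)
        for i in np.flatnonzero(miss):
            v[i] = v[obs_idx[np.argmin(np.abs(obs_idx - i))]]
        logger.warning(
            "gap filling hit max_fill_iterations=%d; %d points set to nearest "
            "observed value",
            config.max_fill_iterations,
            int(miss.sum()),
        )
    return series.with_values(v)


def correct_jumps(series: NDVISeries, config: ReconstructionConfig | None = None) -> NDVISeries:
    """Replace points that jump more than ``jump_threshold`` from their left neighbour.

    Single left-to-right pass; the comparison uses the already corrected left
    value, the replacement is the midpoint of the corrected left neighbour and
    the *original* right neighbour.  A flagged final point (no right
    neighbour) copies its left neighbour.
    """
    config = config or ReconstructionConfig()
    if not series.is_gap_free:
        raise ValueError("correct_jumps requires a gap-free series")
    v = series.values.copy()
    orig = series.values
    n = len(v)
    for i in range(1, n):
        if abs(orig[i] - v[i - 1]) > config.jump_threshold:
            if i < n - 1:
                v[i] = (v[i - 1] + orig[i + 1]) / 2.0
            else:
                v[i] = v[i - 1]
    return series.with_values(v)


def savgol_smooth(series: NDVISeries, config: ReconstructionConfig | None = None) -> NDVISeries:
    """Savitzky–Golay smoothing with edge-window polynomial evaluation.

    Boundary points are handled by fitting the polynomial over the window
    nearest the edge and evaluating it at the boundary position (scipy's
    ``mode='interp'``).  Output is clipped to the NDVI range ``[-1, 1]``.
    Series shorter than the window are returned unchanged with a warning.
    """
    config = config or ReconstructionConfig()
    if not series.is_gap_free:
        raise ValueError("savgol_smooth requires a gap-free series")
    if len(series) < config.sg_window:
        logger.warning(
            "series %r shorter than smoothing window (%d < %d); smoothing skipped",
            series.pixel_id,
            len(series),
            config.sg_window,
        )
        return series.with_values(series.values.copy())
    sm = savgol_filter(
        series.values, config.sg_window, config.sg_polyorder, mode="interp"
    )
    return series.with_values(np.clip(sm, -1.0, 1.0))


def reconstruct(series: NDVISeries, config: ReconstructionConfig | None = None) -> NDVISeries:
    """Full reconstruction: fill gaps, correct jumps, then smooth."""
    config = config or ReconstructionConfig()
    return savgol_smooth(correct_jumps(fill_gaps(series, config), config), config)
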