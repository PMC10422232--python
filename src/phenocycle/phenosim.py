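"""Synthetic NDVI phenology generator.

Emulates the statistical structure of per-pixel Sentinel-2 NDVI sample sets:
24 composites per year (15-day compositing), crop growth cycles as Gaussian
greenness bumps over a bare-ground base level, optional low-amplitude weed
bumps, non-crop confuser classes (water, bare soil, forest), additive Gaussian
noise, and cloud-induced missing values.

Crop curve model for a pixel with ``k`` cycles::

    v(t) = base + sum_k A_k * exp(-(t - mu_k)^2 / (2 sigma_k^2)) + weed + noise

clipped to [-1, 1].  Default amplitudes are drawn in [0.55, 0.9] so clean crop
peaks always exceed 0.5; per-series peak jitter is kept within a few percent so
every true peak clears the adaptive 0.70-of-maximum threshold.  Default
centres and widths narrow as the cycle count grows so that inter-cycle minima
stay below the adaptive 0.20-of-maximum valley threshold — the generator and
the cycle counter are consistent by construction, which each emitted crop
series verifies on its clean curve (a violating parameter set raises
:class:`GeneratorError`).

Weed bumps are capped at 0.3x the main amplitude, mirroring the fact that
weed flushes green up far less than a closed crop canopy, and are placed in
the off-season tail of single-cycle series.

True labels are recorded from the requested ``n_cycles`` at generation time,
never from the counting algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .cycles import CycleThresholds, label_intensity
from .datasets import LabeledDataset
from .raster import ClassMap, GridTransform, RasterStack
from .series import NDVISeries

logger = logging.getLogger(__name__)

__all__ = [
    "PhenoParams",
    "GeneratorError",
    "simulate_series",
    "simulate_extent_dataset",
    "simulate_intensity_dataset",
    "simulate_raster",
    "default_layout",
    "truth_sites_geojson",
    "CROP_CLASS_NAMES",
    "EXTENT_CLASS_NAMES",
    "INTENSITY_CLASS_NAMES",
]

N_COMPOSITES = 24

CROP_CLASS_NAMES = {"crop", "water", "bare_soil", "forest"}
EXTENT_CLASS_NAMES = {0: "non-cropland", 1: "cropland"}
INTENSITY_CLASS_NAMES = {0: "0 cycles", 1: "1 cycle", 2: "2 cycles", 3: "3 cycles"}

# Default cycle geometry: integer centres (so the sampled grid hits each bump
# top exactly) spread over the year, widths narrow enough that inter-cycle and
# tail minima stay below the adaptive 0.20-of-maximum valley threshold even at
# the lowest drawn amplitude.  Triple cropping packs three bumps into 24
# composites, which forces narrow bumps; a cloud gap right on such a bump top
# (filled by neighbour averaging) can still cost that peak.
_DEFAULT_CENTERS = {1: (11.5,), 2: (6.0, 16.0), 3: (4.0, 12.0, 19.0)}
_DEFAULT_WIDTHS = {1: (2.0,), 2: (1.3, 1.3), 3: (1.1, 1.1, 1.1)}

_AMPLITUDE_RANGE = (0.55, 0.90)
_PEAK_JITTER = (0.97, 1.03)


class GeneratorError(ValueError):
    """Raised when requested parameters cannot yield a well-defined label."""


@dataclass(frozen=True)
class PhenoParams:
    """Parameters of one synthetic pixel-year.

    ``peak_amplitudes``, ``peak_times`` and ``peak_widths`` may be ``None``
    (drawn/derived from defaults at simulation time) or per-cycle tuples.
    ``weed_bump`` is ``(amplitude, center, width)`` or ``None``.
    """

    n_cycles: int = 0
    base_level: float = 0.12
    peak_amplitudes: tuple[float, ...] | None = None
    peak_times: tuple[float, ...] | None = None
    peak_widths: tuple[float, ...] | None = None
    weed_bump: tuple[float, float, float] | None = None
    noise_sd: float = 0.02
    missing_prob: float = 0.1
    land_class: str = "crop"
    n_points: int = N_COMPOSITES

    def __post_init__(self) -> None:
        if self.n_cycles not in (0, 1, 2, 3):
            raise ValueError("n_cycles must be in {0, 1, 2, 3}")
        if self.land_class not in CROP_CLASS_NAMES:
            raise ValueError(f"unknown land_class {self.land_class!r}")
        if self.land_class != "crop" and self.n_cycles != 0:
            raise ValueError("only crop pixels have growth cycles")
        if not (0 <= self.missing_prob < 1):
            raise ValueError("missing_prob must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points < 1:
            raise ValueError("n_points must be positive")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _resolve_crop_geometry(params: PhenoParams, rng: np.random.Generator):
    k = params.n_cycles
    centers = params.peak_times or _DEFAULT_CENTERS[k]
    widths = params.peak_widths or _DEFAULT_WIDTHS[k]
    if params.peak_amplitudes is not None:
        amps = params.peak_amplitudes
    else:
        base_amp = rng.uniform(*_AMPLITUDE_RANGE)
        amps = tuple(base_amp * rng.uniform(*_PEAK_JITTER) for _ in range(k))
    if not (len(amps) == len(centers) == len(widths) == k):
        raise GeneratorError("per-cycle parameter tuples must have length n_cycles")
    return tuple(amps), tuple(centers), tuple(widths)


def _crop_curve(params: PhenoParams, amps, centers, widths) -> np.ndarray:
    t = np.arange(params.n_points, dtype=float)
    v = np.full(params.n_points, params.base_level)
    for a, mu, sig in zip(amps, centers, widths):
        v += a * np.exp(-((t - mu) ** 2) / (2 * sig**2))
    if params.weed_bump is not None:
        w_amp, w_mu, w_sig = params.weed_bump
        main = max(amps) if amps else 0.0
        if amps and w_amp > 0.3 * main + 1e-12:
            raise GeneratorError(
                "weed bump amplitude must not exceed 0.3x the main peak amplitude"
            )
        v += w_amp * np.exp(-((t - w_mu) ** 2) / (2 * w_sig**2))
    return v


def _clean_curve(params: PhenoParams, rng: np.random.Generator) -> np.ndarray:
    """Noise-free, gap-free curve for the requested land class."""
    t = np.arange(params.n_points, dtype=float)
    if params.land_class == "crop":
        if params.n_cycles == 0:
            return np.full(params.n_points, params.base_level)
        amps, centers, widths = _resolve_crop_geometry(params, rng)
        return _crop_curve(params, amps, centers, widths)
    if params.land_class == "water":
        level = rng.uniform(-0.4, -0.05)
        return np.full(params.n_points, level)
    if params.land_class == "bare_soil":
        level = params.base_level * rng.uniform(0.8, 1.2)
        return np.full(params.n_points, min(level, 0.2))
    # forest: high plateau with a gentle seasonal swing, no deep valleys
    level = rng.uniform(0.62, 0.80)
    swing = rng.uniform(0.02, 0.06)
    phase = rng.uniform(0, 2 * np.pi)
    return level + swing * np.sin(2 * np.pi * t / params.n_points + phase)


def simulate_series(params: PhenoParams, seed=None) -> tuple[NDVISeries, int]:
    """Draw one pixel-year; returns the series and its true intensity label.

    The true label is ``n_cycles`` for crop pixels and 0 otherwise.  For crop
    pixels with cycles, the clean curve is checked against the cycle counter;
    geometry that merges or masks cycles raises :class:`GeneratorError`.
    Fully reproducible: same seed and params give an identical series.
    """
    rng = _as_rng(seed)
    clean = np.clip(_clean_curve(params, rng), -1.0, 1.0)
    if params.land_class == "crop" and params.n_cycles > 0:
        check = NDVISeries.from_values(clean)
        got = label_intensity(check, CycleThresholds())
        if got != params.n_cycles:
            raise GeneratorError(
                f"requested {params.n_cycles} cycles but the clean curve "
                f"labels as {got}; peaks overlap or fall below threshold"
            )
    v = clean.copy()
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, params.n_points)
    v = np.clip(v, -1.0, 1.0)
    missing = (
        rng.random(params.n_points) < params.missing_prob
        if params.missing_prob > 0
        else np.zeros(params.n_points, dtype=bool)
    )
    if missing.all():  # never emit an unrecoverable series
        missing[int(rng.integers(params.n_points))] = False
    v = np.where(missing, np.nan, v)
    series = NDVISeries(
        values=v,
        missing=missing,
        times=np.arange(params.n_points),
        pixel_id="",
    )
    true_label = params.n_cycles if params.land_class == "crop" else 0
    return series, true_label


def _weed_for_single_cycle(rng: np.random.Generator) -> tuple[float, float, float]:
    """Off-season weed flush for a 1-cycle pixel: small, narrow, near a tail."""
    frac = rng.uniform(0.1, 0.3)
    center = float(rng.choice([2.0, 21.0]))
    return (frac, center, 1.0)  # fraction of main amplitude, resolved below


def _crop_params(
    rng: np.random.Generator, n_cycles: int, noise_sd: float, missing_prob: float,
    weed_prob: float = 0.5,
) -> PhenoParams:
    params = PhenoParams(
        n_cycles=n_cycles,
        noise_sd=noise_sd,
        missing_prob=missing_prob,
        land_class="crop",
    )
    if n_cycles == 1 and rng.random() < weed_prob:
        frac, center, width = _weed_for_single_cycle(rng)
        base_amp = rng.uniform(*_AMPLITUDE_RANGE)
        amps = (base_amp * rng.uniform(*_PEAK_JITTER),)
        params = replace(
            params,
            peak_amplitudes=amps,
            weed_bump=(frac * amps[0], center, width),
        )
    return params


def simulate_extent_dataset(
    n_crop: int = 75,
    n_noncrop: int = 75,
    seed=None,
    noise_sd: float = 0.02,
    missing_prob: float = 0.1,
) -> LabeledDataset:
    """Binary cropland-extent sample set (default 75 cropland / 75 non-cropland).

    Crop pixels draw 1-3 cycles uniformly; non-crop pixels draw uniformly over
    water, bare soil and forest.
    """
    if n_crop < 1 or n_noncrop < 1:
        raise ValueError("need at least one sample per class")
    rng = _as_rng(seed)
    series, labels = [], []
    for i in range(n_crop):
        params = _crop_params(
            rng, int(rng.integers(1, 4)), noise_sd, missing_prob
        )
        s, _ = simulate_series(params, rng)
        s.pixel_id = f"crop_{i:04d}"
        series.append(s)
        labels.append(1)
    noncrop_classes = ["water", "bare_soil", "forest"]
    for i in range(n_noncrop):
        params = PhenoParams(
            land_class=str(rng.choice(noncrop_classes)),
            noise_sd=noise_sd,
            missing_prob=missing_prob,
        )
        s, _ = simulate_series(params, rng)
        s.pixel_id = f"noncrop_{i:04d}"
        series.append(s)
        labels.append(0)
    return LabeledDataset(series, np.array(labels), dict(EXTENT_CLASS_NAMES))


def _intensity_counts(n_total: int, priors) -> np.ndarray:
    """Largest-remainder apportionment with at least one sample per class."""
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()
    raw = priors * n_total
    counts = np.floor(raw).astype(int)
    if n_total >= 4:
        counts = np.maximum(counts, 1)
    while counts.sum() > n_total:
        counts[np.argmax(counts)] -= 1
    rema = raw - np.floor(raw)
    while counts.sum() < n_total:
        order = np.argsort(-rema)
        for j in order:
            if counts.sum() >= n_total:
                break
            counts[j] += 1
    return counts


def simulate_intensity_dataset(
    n_total: int = 200,
    seed=None,
    priors=(0.4, 0.3, 0.2, 0.1),
    noise_sd: float = 0.02,
    missing_prob: float = 0.1,
) -> LabeledDataset:
    """Crop-intensity sample set with a deliberately imbalanced class prior.

    Class 0 pixels draw uniformly over water, bare soil and forest; classes
    1-3 are crop pixels.  The imbalance (default 0.4/0.3/0.2/0.1) exercises
    the oversampling path downstream.
    """
    if n_total < 4:
        raise ValueError("need n_total >= 4 to cover all intensity classes")
    rng = _as_rng(seed)
    counts = _intensity_counts(n_total, priors)
    series, labels = [], []
    noncrop_classes = ["water", "bare_soil", "forest"]
    i = 0
    for label, count in enumerate(counts):
        for _ in range(count):
            if label == 0:
                params = PhenoParams(
                    land_class=str(rng.choice(noncrop_classes)),
                    noise_sd=noise_sd,
                    missing_prob=missing_prob,
                )
            else:
                params = _crop_params(rng, label, noise_sd, missing_prob)
            s, true = simulate_series(params, rng)
            s.pixel_id = f"px_{i:04d}"
            series.append(s)
            labels.append(true)
            i += 1
    order = rng.permutation(len(series))
    return LabeledDataset(
        [series[j] for j in order],
        np.array(labels)[order],
        dict(INTENSITY_CLASS_NAMES),
    )


def default_layout(rows: int, cols: int) -> list[dict]:
    """Simple spatially coherent scene: bare background, a river strip,
    a forest block, and three rectangular fields of intensity 1, 2 and 3."""

    def frac(n, f):
        return max(1, int(round(n * f)))

    return [
        {"kind": "bare_soil", "row0": 0, "row1": rows, "col0": 0, "col1": cols},
        {"kind": "crop", "n_cycles": 1,
         "row0": frac(rows, 0.05), "row1": frac(rows, 0.40),
         "col0": 0, "col1": frac(cols, 0.35)},
        {"kind": "crop", "n_cycles": 2,
         "row0": frac(rows, 0.50), "row1": rows,
         "col0": 0, "col1": frac(cols, 0.35)},
        {"kind": "crop", "n_cycles": 3,
         "row0": frac(rows, 0.50), "row1": rows,
         "col0": frac(cols, 0.55), "col1": cols},
        {"kind": "water",
         "row0": 0, "row1": rows,
         "col0": frac(cols, 0.40), "col1": frac(cols, 0.50)},
        {"kind": "forest",
         "row0": 0, "row1": frac(rows, 0.35),
         "col0": frac(cols, 0.65), "col1": cols},
    ]

# Raster fields use a narrower, higher amplitude band than point samples:
# vigorous irrigated fields, with headroom against the 0.4 jump-correction
# threshold at steep bump flanks.
_FIELD_AMPLITUDE_RANGE = (0.75, 0.82)
_FIELD_PIXEL_JITTER = (0.98, 1.02)


def simulate_raster(
    rows: int = 32,
    cols: int = 32,
    region_layout: list[dict] | None = None,
    seed=None,
    noise_sd: float = 0.02,
    missing_prob: float = 0.1,
    transform: GridTransform | None = None,
    crs: str = "EPSG:4326",
) -> tuple[RasterStack, ClassMap, ClassMap]:
    """Emit a T x rows x cols NDVI cube plus ground-truth extent and intensity maps.

    Patches are applied in layout order (later patches overwrite earlier
    ones).  Within a patch all pixels share one clean curve, modulated per
    pixel by a small amplitude jitter, then noise and missing values are
    drawn independently per pixel.  The default georeferencing spans a
    0.5 x 0.5 degree tile.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    rng = _as_rng(seed)
    layout = region_layout if region_layout is not None else default_layout(rows, cols)
    transform = transform or GridTransform(
        x0=44.0, y0=36.0, dx=0.5 / cols, dy=-0.5 / rows
    )
    T = N_COMPOSITES
    cube = np.zeros((T, rows, cols))
    intensity = np.zeros((rows, cols), dtype=np.int16)
    extent = np.zeros((rows, cols), dtype=np.int16)
    for patch in layout:
        r0, r1 = patch["row0"], patch["row1"]
        c0, c1 = patch["col0"], patch["col1"]
        kind = patch["kind"]
        k = int(patch.get("n_cycles", 0))
        if kind == "crop" and k >= 1:
            amp = rng.uniform(*_FIELD_AMPLITUDE_RANGE)
            params = PhenoParams(
                n_cycles=k,
                peak_amplitudes=tuple([amp] * k),
                noise_sd=0.0,
                missing_prob=0.0,
                land_class="crop",
            )
        else:
            params = PhenoParams(
                land_class=kind, noise_sd=0.0, missing_prob=0.0
            )
        clean, _ = simulate_series(params, rng)
        base = params.base_level if kind == "crop" else 0.0
        bumps = clean.values - base
        jitter = rng.uniform(*_FIELD_PIXEL_JITTER, size=(r1 - r0, c1 - c0))
        cube[:, r0:r1, c0:c1] = base + bumps[:, None, None] * jitter[None, :, :]
        intensity[r0:r1, c0:c1] = k if kind == "crop" else 0
        extent[r0:r1, c0:c1] = 1 if (kind == "crop" and k >= 1) else 0
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd, cube.shape)
    cube = np.clip(cube, -1.0, 1.0)
    if missing_prob > 0:
        miss = rng.random(cube.shape) < missing_prob
        all_missing = miss.all(axis=0)
        if all_missing.any():  # keep at least one observation per pixel
            keep_t = rng.integers(0, T, size=all_missing.sum())
            rr, cc = np.nonzero(all_missing)
            miss[keep_t, rr, cc] = False
        cube = np.where(miss, np.nan, cube)
    stack = RasterStack(cube=cube, transform=transform, crs=crs)
    extent_map = ClassMap(
        grid=extent, legend=dict(EXTENT_CLASS_NAMES), transform=transform, crs=crs
    )
    intensity_map = ClassMap(
        grid=intensity, legend=dict(INTENSITY_CLASS_NAMES), transform=transform, crs=crs
    )
    return stack, extent_map, intensity_map


def truth_sites_geojson(
    truth: ClassMap, n_per_class: int = 10, seed=None
) -> dict:
    """Labelled sample points over a truth map, as a GeoJSON FeatureCollection.

    Mirrors the pin-style collection of labelled locations: up to
    ``n_per_class`` pixel centres are drawn per class present in the map.
    """
    rng = _as_rng(seed)
    features = []
    for code in sorted(np.unique(truth.grid).tolist()):
        if code == truth.nodata:
            continue
        rr, cc = np.nonzero(truth.grid == code)
        take = min(n_per_class, len(rr))
        idx = rng.choice(len(rr), size=take, replace=False)
        for j in idx:
            x, y = truth.transform.pixel_center(int(rr[j]), int(cc[j]))
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [x, y]},
                    "properties": {"label": int(code)},
                }
            )
    return {"type": "FeatureCollection", "features": features}
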