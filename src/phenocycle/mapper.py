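"""Map-scale inference: sampling labelled sites and per-pixel classification.

``sample_sites`` turns a GeoJSON collection of labelled points/polygons plus a
raster stack into a labelled dataset; ``predict_map`` reconstructs every
pixel's series and classifies it — with a trained model, or directly with the
adaptive-threshold cycle counter (``method="threshold"``) for intensity maps.
Inference is tiled so arbitrarily large grids run in bounded memory; tiling
never changes outputs because pixels are independent.
"""

from __future__ import annotations

import json
import logging
import time

import numpy as np
from shapely.geometry import Point, shape

from .classify import FittedModel, extract_features
from .cycles import CycleThresholds, label_intensity
from .datasets import LabeledDataset
from .raster import ClassMap, RasterStack
from .series import (
    NDVISeries,
    ReconstructionConfig,
    UnrecoverableSeriesError,
    reconstruct,
)

logger = logging.getLogger(__name__)

__all__ = ["sample_sites", "predict_map"]


def _pixels_for_geometry(geom, stack: RasterStack, cap: int | None, rng):
    """Pixel (row, col) list covered by a GeoJSON geometry (center containment)."""
    rows, cols = stack.shape
    if geom.geom_type == "Point":
        r, c = stack.transform.world_to_pixel(geom.x, geom.y)
        if 0 <= r < rows and 0 <= c < cols:
            return [(r, c)]
        return []
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        minx, miny, maxx, maxy = geom.bounds
        r_lo, c_lo = stack.transform.world_to_pixel(minx, maxy)
        r_hi, c_hi = stack.transform.world_to_pixel(maxx, miny)
        r_lo, r_hi = max(0, min(r_lo, r_hi)), min(rows - 1, max(r_lo, r_hi))
        c_lo, c_hi = max(0, min(c_lo, c_hi)), min(cols - 1, max(c_lo, c_hi))
        covered = []
        for r in range(r_lo, r_hi + 1):
            for c in range(c_lo, c_hi + 1):
                x, y = stack.transform.pixel_center(r, c)
                if geom.covers(Point(x, y)):
                    covered.append((r, c))
        if cap is not None and len(covered) > cap:
            idx = rng.choice(len(covered), size=cap, replace=False)
            covered = [covered[i] for i in sorted(idx)]
        return covered
    raise ValueError(f"unsupported geometry type {geom.geom_type}")


def sample_sites(
    stack: RasterStack,
    sites_path,
    label_property: str = "label",
    cap_per_polygon: int | None = None,
    seed=None,
    class_names: dict[int, str] | None = None,
) -> LabeledDataset:
    """Extract labelled pixel series at GeoJSON point/polygon sites.

    Points map to their containing pixel; polygons yield every pixel whose
    centre falls inside (optionally a capped random subset per polygon), each
    inheriting the polygon's label.  Sites outside the raster are skipped
    with a warning; a missing label property is an error.
    """
    rng = np.random.default_rng(seed)
    with open(sites_path) as fh:
        collection = json.load(fh)
    features = collection.get("features", [])
    if not features:
        logger.warning("%s contains no features; returning an empty dataset", sites_path)
        return LabeledDataset([], np.array([], dtype=int), class_names or {})
    series, labels = [], []
    for feat in features:
        props = feat.get("properties") or {}
        if label_property not in props:
            raise ValueError(
                f"feature without {label_property!r} property in {sites_path}"
            )
        label = int(props[label_property])
        geom = shape(feat["geometry"])
        pixels = _pixels_for_geometry(geom, stack, cap_per_polygon, rng)
        if not pixels:
            logger.warning("geometry outside raster bounds skipped: %s", geom.wkt)
            continue
        for r, c in pixels:
            series.append(stack.pixel_series(r, c))
            labels.append(label)
    return LabeledDataset(series, np.array(labels, dtype=int), class_names or {})


def predict_map(
    stack: RasterStack,
    model: FittedModel | None = None,
    task: str = "intensity",
    method: str = "model",
    recon_config: ReconstructionConfig | None = None,
    thresholds: CycleThresholds | None = None,
    tile_size: int = 256,
    legend: dict[int, str] | None = None,
) -> ClassMap:
    """Per-pixel classification of a time-series cube into a class map.

    Every pixel's series is reconstructed, then labelled either by the fitted
    model (``method="model"``) or, for intensity, directly by the adaptive
    cycle counter (``method="threshold"``).  Pixels with no observations at
    all propagate as nodata.
    """
    if task not in ("extent", "intensity"):
        raise ValueError("task must be 'extent' or 'intensity'")
    if method not in ("model", "threshold"):
        raise ValueError("method must be 'model' or 'threshold'")
    if method == "model":
        if model is None:
            raise ValueError("method='model' requires a fitted model")
        if model.n_features != stack.n_times:
            raise ValueError(
                f"stack has {stack.n_times} composites but the model expects "
                f"{model.n_features}"
            )
    if method == "threshold" and task != "intensity":
        raise ValueError("the threshold method produces intensity maps only")
    recon_config = recon_config or ReconstructionConfig()
    thresholds = thresholds or CycleThresholds()
    rows, cols = stack.shape
    grid = np.full((rows, cols), -1, dtype=np.int16)
    t_recon = t_classify = 0.0
    for r0 in range(0, rows, tile_size):
        for c0 in range(0, cols, tile_size):
            r1, c1 = min(r0 + tile_size, rows), min(c0 + tile_size, cols)
            t0 = time.perf_counter()
            feats, coords = [], []
            for r in range(r0, r1):
                for c in range(c0, c1):
                    s = stack.pixel_series(r, c)
                    try:
                        recon = reconstruct(s, recon_config)
                    except UnrecoverableSeriesError:
                        continue  # never-observed pixel -> nodata
                    if method == "threshold":
                        grid[r, c] = label_intensity(recon, thresholds)
                    else:
                        feats.append(extract_features(recon))
                        coords.append((r, c))
            t_recon += time.perf_counter() - t0
            if feats:
                t0 = time.perf_counter()
                pred = model.predict_features(np.stack(feats))
                for (r, c), p in zip(coords, pred):
                    grid[r, c] = int(p)
                t_classify += time.perf_counter() - t0
    logger.info(
        "predict_map: reconstruction %.2fs, classification %.2fs over %d pixels",
        t_recon,
        t_classify,
        rows * cols,
    )
    if legend is None:
        if task == "extent":
            legend = {0: "non-cropland", 1: "cropland"}
        else:
            legend = {0: "0 cycles", 1: "1 cycle", 2: "2 cycles", 3: "3 cycles"}
    params = {
        "task": task,
        "method": method,
        "jump_threshold": recon_config.jump_threshold,
        "sg_window": recon_config.sg_window,
        "sg_polyorder": recon_config.sg_polyorder,
        "vegetation_floor": thresholds.vegetation_floor,
        "peak_fraction": thresholds.peak_fraction,
        "valley_fraction": thresholds.valley_fraction,
    }
    return ClassMap(
        grid=grid,
        legend=legend,
        transform=stack.transform,
        crs=stack.crs,
        nodata=-1,
        params=params,
    )
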