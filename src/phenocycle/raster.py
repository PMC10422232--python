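"""Georeferenced raster containers and TIFF I/O.

A :class:`RasterStack` is a T x rows x cols cube of NDVI composites (band i =
composite i, time order); a :class:`ClassMap` is a single-band integer grid of
class codes.  Both are stored as multi-band TIFF with the georeferencing
metadata (affine transform, CRS identifier, nodata sentinel, legend, run
parameters) serialized as JSON in the TIFF ImageDescription tag, and round-trip
bit-exactly for finite values.

Coordinate convention: pixel (0, 0) is the upper-left cell; the world
coordinates of the centre of pixel (row, col) are
``(x0 + (col + 0.5) * dx, y0 + (row + 0.5) * dy)`` with ``dy`` negative for
north-up grids; point-in-pixel lookups use half-open cell intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "GridTransform",
    "RasterStack",
    "ClassMap",
    "read_stack",
    "write_stack",
    "read_map",
    "write_map",
]

STACK_NODATA = -9999.0
MAP_NODATA = -1


@dataclass(frozen=True)
class GridTransform:
    """Affine north-up georeferencing: origin at the upper-left corner."""

    x0: float
    y0: float
    dx: float
    dy: float

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.x0 + (col + 0.5) * self.dx, self.y0 + (row + 0.5) * self.dy)

    def world_to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """Containing pixel of a world point (half-open cells)."""
        col = int(np.floor((x - self.x0) / self.dx))
        row = int(np.floor((y - self.y0) / self.dy))
        return row, col

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "dx": self.dx, "dy": self.dy}

    @classmethod
    def from_dict(cls, d: dict) -> "GridTransform":
        return cls(x0=d["x0"], y0=d["y0"], dx=d["dx"], dy=d["dy"])


@dataclass
class RasterStack:
    """Time-series cube: ``cube[t, row, col]`` with ``nan`` marking missing."""

    cube: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    nodata: float = STACK_NODATA

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3 or self.cube.shape[0] < 1:
            raise ValueError("cube must be T x rows x cols with T >= 1")

    @property
    def n_times(self) -> int:
        return self.cube.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[1], self.cube.shape[2]

    def pixel_series(self, row: int, col: int):
        from .series import NDVISeries

        return NDVISeries.from_values(
            self.cube[:, row, col], pixel_id=f"r{row}c{col}"
        )


@dataclass
class ClassMap:
    """Single-band integer class grid sharing the stack's georeferencing."""

    grid: np.ndarray
    legend: dict[int, str]
    transform: GridTransform
    crs: str = "EPSG:4326"
    nodata: int = MAP_NODATA
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int16)
        if self.grid.ndim != 2:
            raise ValueError("grid must be rows x cols")
        codes = set(np.unique(self.grid).tolist())
        allowed = set(self.legend) | {self.nodata}
        if not codes <= allowed:
            raise ValueError(f"codes {sorted(codes - allowed)} not in legend")


def write_stack(stack: RasterStack, path) -> None:
    """Write a stack as multi-band TIFF; missing values become the nodata sentinel."""
    data = np.where(np.isfinite(stack.cube), stack.cube, stack.nodata)
    meta = {
        "phenocycle": "stack",
        "transform": stack.transform.to_dict(),
        "crs": stack.crs,
        "nodata": stack.nodata,
    }
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def _read_description(path) -> dict:
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description or ""
        data = tf.asarray()
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    return {"data": data, "meta": meta}


def read_stack(path) -> RasterStack:
    """Load a multi-band TIFF as a RasterStack; nodata becomes missing (nan)."""
    loaded = _read_description(path)
    data = np.asarray(loaded["data"], dtype=float)
    if data.ndim == 2:
        data = data[None, :, :]
    meta = loaded["meta"]
    if meta.get("phenocycle") not in ("stack", None):
        raise ValueError(f"{path} is not a phenocycle stack")
    if "transform" in meta:
        transform = GridTransform.from_dict(meta["transform"])
        crs = meta.get("crs", "EPSG:4326")
    else:
        logger.warning("%s carries no georeferencing; proceeding un-referenced", path)
        transform = GridTransform(0.0, 0.0, 1.0, -1.0)
        crs = ""
    nodata = float(meta.get("nodata", STACK_NODATA))
    cube = np.where(data == nodata, np.nan, data)
    if cube.shape[0] == 1:
        logger.warning("single-band stack: too short to label crop cycles")
    return RasterStack(cube=cube, transform=transform, crs=crs, nodata=nodata)


def write_map(class_map: ClassMap, path) -> None:
    """Write a class map as single-band integer TIFF with embedded legend."""
    meta = {
        "phenocycle": "classmap",
        "transform": class_map.transform.to_dict(),
        "crs": class_map.crs,
        "nodata": class_map.nodata,
        "legend": {str(k): v for k, v in class_map.legend.items()},
        "params": class_map.params,
    }
    tifffile.imwrite(
        path, class_map.grid.astype(np.int16), description=json.dumps(meta)
    )


def read_map(path) -> ClassMap:
    loaded = _read_description(path)
    meta = loaded["meta"]
    if meta.get("phenocycle") != "classmap":
        raise ValueError(f"{path} is not a phenocycle class map")
    return ClassMap(
        grid=np.asarray(loaded["data"], dtype=np.int16),
        legend={int(k): v for k, v in meta.get("legend", {}).items()},
        transform=GridTransform.from_dict(meta["transform"]),
        crs=meta.get("crs", "EPSG:4326"),
        nodata=int(meta.get("nodata", MAP_NODATA)),
        params=meta.get("params", {}),
    )
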