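"""Grid conventions, per-pixel areas, and raster/vector I/O.

All gridded layers in this package are plain 2-D numpy arrays sharing one
shape. Two integer conventions are used throughout:

* **class grids** — land-cover codes: ``0`` other, ``1`` industrial oil
  palm, ``2`` smallholder oil palm, ``3`` pulp plantation.
* **year grids** — per-pixel event years (tree loss or plantation
  establishment) with two sentinels: ``0`` means "no event" and ``2000``
  means "existed in / happened before 2000".

Rasters are stored as single-band TIFF files with a JSON sidecar carrying
the code table and georeference metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

# land-cover codes
OTHER = 0
INDUSTRIAL = 1
SMALLHOLDER = 2
PULP = 3
CLASS_NAMES = {OTHER: "other", INDUSTRIAL: "industrial",
               SMALLHOLDER: "smallholder", PULP: "pulp"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}
OIL_PALM_CODES = (INDUSTRIAL, SMALLHOLDER)

# year-grid sentinels
YEAR_NONE = 0
YEAR_PRE2000 = 2000

#: authalic Earth radius in metres (sphere of equal surface area)
EARTH_RADIUS_M = 6_371_007.181


def check_aligned(*grids: np.ndarray) -> tuple[int, int]:
    """Ensure all grids are 2-D and share one shape; return that shape."""
    if not grids:
        raise ValueError("no grids supplied")
    shape = np.asarray(grids[0]).shape
    for g in grids:
        a = np.asarray(g)
        if a.ndim != 2 or a.shape != shape:
            raise ValueError(
                f"grid shapes differ or are not 2-D: {a.shape} vs {shape}")
    return shape


def check_year_grid(years: np.ndarray, year_start: int, year_end: int) -> None:
    """Validate that a year grid only holds sentinels or in-range years."""
    vals = np.unique(np.asarray(years))
    ok = (vals == YEAR_NONE) | (vals == YEAR_PRE2000) | (
        (vals >= year_start) & (vals <= year_end))
    if not ok.all():
        bad = vals[~ok]
        raise ValueError(f"year grid holds out-of-range values: {bad.tolist()}")


def pixel_area_grid(shape: tuple[int, int], *,
                    cell_size_m: float | None = None,
                    res_deg: float | None = None,
                    lat_top_deg: float | None = None) -> np.ndarray:
    """Per-pixel area in hectares for a grid.

    Two modes:

    * projected / synthetic grids — pass ``cell_size_m``; every cell gets
      ``cell_size_m**2 / 1e4`` ha (e.g. 30 m cells -> 0.09 ha).
    * geographic grids — pass ``res_deg`` and ``lat_top_deg`` (latitude of
      the top edge); the cell area scales with the cosine of the row-centre
      latitude, the equal-area (sinusoidal-equivalent) convention.
    """
    rows, cols = shape
    if cell_size_m is not None:
        if cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        return np.full(shape, cell_size_m ** 2 / 1e4)
    if res_deg is None or lat_top_deg is None:
        raise ValueError(
            "declare either cell_size_m or (res_deg and lat_top_deg)")
    lat_centres = lat_top_deg - (np.arange(rows) + 0.5) * res_deg
    res_rad = np.deg2rad(res_deg)
    cell_m2 = (EARTH_RADIUS_M * res_rad) ** 2 * np.cos(np.deg2rad(lat_centres))
    if np.any(cell_m2 <= 0):
        raise ValueError("grid extends to or beyond a pole; areas degenerate")
    return np.repeat(cell_m2[:, None] / 1e4, cols, axis=1)


def write_raster(path: str | Path, grid: np.ndarray,
                 meta: dict | None = None) -> Path:
    """Write a single-band integer/float raster with a JSON sidecar."""
    path = Path(path)
    arr = np.asarray(grid)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(path, arr)
    sidecar = {"shape": list(arr.shape), "dtype": str(arr.dtype)}
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a raster written by :func:`write_raster`; returns (grid, meta)."""
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta


def rasterize_geojson(geojson: dict, shape: tuple[int, int],
                      origin: tuple[float, float],
                      cell: tuple[float, float]) -> np.ndarray:
    """Rasterize GeoJSON polygons onto a grid (center-of-pixel inclusion).

    ``origin`` is the (x, y) of the grid's top-left corner and ``cell`` the
    (dx, dy) cell size; row coordinates decrease from ``origin[1]``. A pixel
    is inside iff its centre point falls within any polygon.
    """
    from shapely import contains_xy, union_all
    from shapely.geometry import shape as shp_shape

    feats = geojson.get("features", [geojson])
    geoms = [shp_shape(f["geometry"] if "geometry" in f else f) for f in feats]
    geom = union_all(geoms)
    rows, cols = shape
    x0, y0 = origin
    dx, dy = cell
    xs = x0 + (np.arange(cols) + 0.5) * dx
    ys = y0 - (np.arange(rows) + 0.5) * dy
    xx, yy = np.meshgrid(xs, ys)
    return contains_xy(geom, xx, yy)
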