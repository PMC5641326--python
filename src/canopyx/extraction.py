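"""Cut an orthomosaic into per-plot mini-rasters from plot polygons.

Coordinate conventions (stated because mosaics are otherwise ambiguous):
pixel coordinates are 0-based, x runs along columns, y along rows with
rows increasing downward, and a pixel belongs to a polygon when its
*centre* ``(col + 0.5, row + 0.5)`` lies inside (centre-sampling rule).

Polygons arrive as GeoJSON features with a ``plot_id`` property, either
already in mosaic pixel coordinates (``pixel`` mode) or in world
coordinates (``geo`` mode).  Geo mode needs the mosaic's affine transform
``(a, b, c, d, e, f)`` mapping pixel ``(col, row)`` to world
``(x, y) = (a*col + b*row + c, d*col + e*row + f)``; without it the
extraction fails hard rather than guessing a registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon, shape

__all__ = [
    "PlotPolygon",
    "PlotRaster",
    "extract_plots",
    "inward_buffer",
    "read_plot_polygons",
    "write_extraction",
]


@dataclass
class PlotPolygon:
    plot_id: str
    polygon: Polygon
    coordinate_mode: str = "pixel"  # "pixel" | "geo"

    def __post_init__(self) -> None:
        if self.coordinate_mode not in ("pixel", "geo"):
            raise ValueError(f"unknown coordinate mode {self.coordinate_mode!r}")
        if len(self.polygon.exterior.coords) < 4:  # closed ring: 3 vertices + repeat
            raise ValueError(f"plot {self.plot_id}: polygon needs at least 3 vertices")
        if not self.polygon.is_valid:
            raise ValueError(f"plot {self.plot_id}: polygon is not simple/valid")


@dataclass
class PlotRaster:
    """One extracted mini-raster: masked values plus its window in the mosaic."""

    plot_id: str
    data: np.ma.MaskedArray  # (H, W) or (bands, H, W); mask True outside polygon
    row_off: int
    col_off: int

    @property
    def n_pixels(self) -> int:
        mask = self.data.mask
        if mask is np.ma.nomask:
            return int(np.prod(self.data.shape[-2:]))
        if self.data.ndim == 3:
            mask = mask[0]
        return int(np.count_nonzero(~mask))


def inward_buffer(poly: PlotPolygon, margin: float) -> PlotPolygon:
    """Erode the polygon inward by ``margin`` pixels (identity at 0).

    Trimming plot borders removes mixed border/alley pixels before the
    plot mean is taken.  Over-eroding to an empty polygon is an error.
    """
    if margin < 0:
        raise ValueError("buffer margin must be >= 0")
    if margin == 0:
        return poly
    eroded = poly.polygon.buffer(-margin, join_style="mitre")
    if eroded.is_empty or eroded.area <= 0:
        raise ValueError(f"plot {poly.plot_id}: inward buffer {margin} erases the polygon")
    if eroded.geom_type == "MultiPolygon":  # erosion split it: keep the largest part
        eroded = max(eroded.geoms, key=lambda g: g.area)
    return PlotPolygon(poly.plot_id, eroded, poly.coordinate_mode)


def _to_pixel(poly: PlotPolygon, transform: tuple[float, ...] | None) -> Polygon:
    if poly.coordinate_mode == "pixel":
        return poly.polygon
    if transform is None:
        raise ValueError(
            f"plot {poly.plot_id}: geo-mode polygon but the mosaic has no affine transform"
        )
    a, b, c, d, e, f = transform
    inv = np.linalg.inv(np.array([[a, b], [d, e]]))
    xy = np.asarray(poly.polygon.exterior.coords)
    px = (xy - np.array([c, f])) @ inv.T
    return Polygon(px)


def extract_plots(
    mosaic: np.ndarray,
    polygons: list[PlotPolygon],
    buffer: float = 0.0,
    transform: tuple[float, ...] | None = None,
) -> tuple[dict[str, PlotRaster], pd.DataFrame]:
    """Extract one masked mini-raster per polygon.

    Returns the rasters keyed by plot_id and a per-plot report
    (plot_id, status, n_pixels, message).  A polygon outside the mosaic
    produces an error record and the batch continues; duplicate plot_ids
    or a missing geo transform abort the whole extraction.
    """
    ids = [p.plot_id for p in polygons]
    if len(set(ids)) != len(ids):
        raise ValueError("plot_ids must be unique")

    arr = np.asarray(mosaic)
    # normalise to (bands, H, W) or (H, W)
    if arr.ndim == 3 and arr.shape[2] <= 16:  # (H, W, bands) -> (bands, H, W)
        arr = np.moveaxis(arr, 2, 0)
    height, width = arr.shape[-2:]

    out: dict[str, PlotRaster] = {}
    report_rows = []
    for poly in polygons:
        try:
            pix = _to_pixel(poly, transform)
        except ValueError:
            raise  # geo/transform problems are configuration errors: abort
        try:
            if buffer > 0:
                pix = inward_buffer(PlotPolygon(poly.plot_id, pix), buffer).polygon
            minx, miny, maxx, maxy = pix.bounds
            r0, r1 = int(np.floor(miny)), int(np.ceil(maxy))
            c0, c1 = int(np.floor(minx)), int(np.ceil(maxx))
            if r1 <= 0 or c1 <= 0 or r0 >= height or c0 >= width:
                raise ValueError("polygon lies outside mosaic bounds")
            r0c, r1c = max(r0, 0), min(r1, height)
            c0c, c1c = max(c0, 0), min(c1, width)
            cols, rows = np.meshgrid(
                np.arange(c0c, c1c) + 0.5, np.arange(r0c, r1c) + 0.5
            )
            inside = shapely.contains_xy(pix, cols.ravel(), rows.ravel()).reshape(cols.shape)
            if not inside.any():
                raise ValueError("polygon covers no pixel centres")
            window = arr[..., r0c:r1c, c0c:c1c]
            mask = ~inside
            if window.ndim == 3:
                mask = np.broadcast_to(mask, window.shape)
            mini = np.ma.MaskedArray(window.astype(np.float64), mask=mask)
            pr = PlotRaster(poly.plot_id, mini, r0c, c0c)
            out[poly.plot_id] = pr
            report_rows.append(
                {"plot_id": poly.plot_id, "status": "ok", "n_pixels": pr.n_pixels, "message": ""}
            )
        except ValueError as exc:
            report_rows.append(
                {"plot_id": poly.plot_id, "status": "error", "n_pixels": 0, "message": str(exc)}
            )
    return out, pd.DataFrame(report_rows)


def read_plot_polygons(path: str | Path, coordinate_mode: str = "pixel") -> list[PlotPolygon]:
    """Load a GeoJSON FeatureCollection with a ``plot_id`` property per feature."""
    with open(path) as fh:
        gj = json.load(fh)
    polys = []
    for feat in gj["features"]:
        pid = str(feat["properties"]["plot_id"])
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"plot {pid}: expected Polygon geometry, got {geom.geom_type}")
        polys.append(PlotPolygon(pid, geom, coordinate_mode))
    return polys


def write_extraction(
    rasters: dict[str, PlotRaster], report: pd.DataFrame, out_dir: str | Path
) -> None:
    """Write `<plot_id>.tif` mini-rasters (masked pixels as NaN) and the report CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pid, pr in rasters.items():
        tifffile.imwrite(str(out_dir / f"{pid}.tif"), pr.data.filled(np.nan).astype(np.float32))
    report.to_csv(out_dir / "extraction_report.csv", index=False)
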