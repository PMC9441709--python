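"""Minimal planar vector/raster containers with plain-text I/O.

Vector layers pair shapely geometries with a pandas attribute table and
round-trip through GeoJSON.  Rasters are numpy grids with an origin and a
square cell size, stored as Esri ASCII grid (``.asc``).  Everything lives in
one projected CRS in metres; the CRS is carried as an opaque tag and never
transformed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

DEFAULT_CRS = "local-metric"


@dataclass
class VectorLayer:
    """Geometries plus an aligned attribute table."""

    geometries: list[BaseGeometry]
    attributes: pd.DataFrame
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.attributes):
            raise ValueError(
                f"geometry/attribute length mismatch: "
                f"{len(self.geometries)} vs {len(self.attributes)}"
            )
        self.attributes = self.attributes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.geometries)

    def select(self, mask) -> "VectorLayer":
        mask = np.asarray(mask, dtype=bool)
        geoms = [g for g, m in zip(self.geometries, mask) if m]
        return VectorLayer(geoms, self.attributes.loc[mask], self.crs)

    def union(self) -> BaseGeometry:
        return shapely.union_all(self.geometries) if self.geometries else shapely.Polygon()

    def to_geojson(self, path) -> None:
        feats = []
        for geom, (_, row) in zip(self.geometries, self.attributes.iterrows()):
            props = {k: (v.item() if hasattr(v, "item") else v) for k, v in row.items()}
            feats.append(
                {"type": "Feature", "geometry": mapping(geom), "properties": props}
            )
        doc = {
            "type": "FeatureCollection",
            "crs_tag": self.crs,
            "features": feats,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, separators=(",", ":"))

    @classmethod
    def from_geojson(cls, path) -> "VectorLayer":
        with open(path) as fh:
            doc = json.load(fh)
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        attrs = pd.DataFrame([f.get("properties") or {} for f in doc["features"]])
        return cls(geoms, attrs, doc.get("crs_tag", DEFAULT_CRS))


@dataclass
class Raster:
    """Row-major grid; row 0 is the northern edge.

    ``origin`` is the (xmin, ymin) corner of the grid; cell centres are at
    ``xmin + (c + 0.5) * cell`` and ``ymax - (r + 0.5) * cell``.
    """

    data: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    crs: str = DEFAULT_CRS
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        nr, nc = self.data.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nc * self.cell_size, y0 + nr * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates as 2-D arrays matching ``data``."""
        nr, nc = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 + nr * self.cell_size - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nr, nc = self.data.shape
        x0, y0 = self.origin
        col = np.clip(((x - x0) / self.cell_size).astype(int), 0, nc - 1)
        row = np.clip(
            ((y0 + nr * self.cell_size - y) / self.cell_size).astype(int), 0, nr - 1
        )
        return row, col

    def values_at(self, x, y) -> np.ndarray:
        r, c = self.rowcol(x, y)
        return self.data[r, c]

    def to_asc(self, path) -> None:
        nr, nc = self.data.shape
        header = (
            f"ncols {nc}\nnrows {nr}\n"
            f"xllcorner {self.origin[0]!r}\nyllcorner {self.origin[1]!r}\n"
            f"cellsize {self.cell_size!r}\nNODATA_value {self.nodata!r}\n"
        )
        body = self.data.copy()
        body[~np.isfinite(body)] = self.nodata
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.6g")

    @classmethod
    def from_asc(cls, path, crs: str = DEFAULT_CRS) -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = header.get("nodata_value", -9999.0)
        data[data == nodata] = np.nan
        return cls(
            data,
            (header["xllcorner"], header["yllcorner"]),
            header["cellsize"],
            crs,
            nodata,
        )


@dataclass
class GridSpec:
    """Prediction-grid geometry: origin, square cell size, and extent."""

    origin: tuple[float, float]
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = DEFAULT_CRS

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return Raster(
            np.zeros((self.n_rows, self.n_cols)), self.origin, self.cell_size, self.crs
        ).cell_centers()

    def cell_polygon(self, row: int, col: int):
        x0, y0 = self.origin
        ymax = y0 + self.n_rows * self.cell_size
        cx0 = x0 + col * self.cell_size
        cy1 = ymax - row * self.cell_size
        return shapely.box(cx0, cy1 - self.cell_size, cx0 + self.cell_size, cy1)

    def raster(self, data: np.ndarray, nodata: float = -9999.0) -> Raster:
        if data.shape != (self.n_rows, self.n_cols):
            raise ValueError("data shape does not match grid")
        return Raster(data, self.origin, self.cell_size, self.crs, nodata)
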