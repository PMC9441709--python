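"""Gridded prediction surfaces of hourly and aggregate noise levels.

Predictions are made at cell centres of a square grid (default 50 m) for a
fixed monitor height of 4 m: each of the 24 hours gets its own surface —
day-model fixed effects plus that hour's intercept for hours 06-21, night
model for 22-05 — and the period aggregates (LAeq_24hr, L_den, L_day,
L_night) are computed per cell from those 24 values, so the aggregation
identity holds exactly by construction.

Cells are masked out of sample when they intersect water or when they are
entirely 'other' land cover (grassland/forest/bare) containing no road —
mirroring the restriction of predictions to areas resembling monitored
locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .acoustics import DAY_HOURS, period_metrics
from .features import FeatureMatrix, extract_features
from .geo import GridSpec, Raster
from .lur import LurModel
from .synthetic_city import LANDCOVER_CLASSES, CityLayers

METRIC_NAMES = ("laeq_24hr", "l_den", "l_day", "l_night")


class StandardizationMismatch(RuntimeError):
    """Grid features were standardized with different parameters than the
    model was trained on — predictions would be silently mis-scaled."""


@dataclass
class NoiseSurface:
    grid: GridSpec
    mask: np.ndarray  # True = in-sample, predictable
    hourly: np.ndarray  # (24, n_rows, n_cols), NaN outside the mask
    metrics: dict[str, np.ndarray]  # name -> (n_rows, n_cols), NaN outside

    def metric_raster(self, name: str) -> Raster:
        return self.grid.raster(self.metrics[name], nodata=-9999.0)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in METRIC_NAMES:
            self.metric_raster(name).to_asc(outdir / f"{name}.asc")
        self.grid.raster(self.mask.astype(float)).to_asc(outdir / "mask.asc")
        for h in range(24):
            self.grid.raster(self.hourly[h]).to_asc(outdir / f"laeq_1hr_h{h:02d}.asc")

    def cell_table(self) -> pd.DataFrame:
        """Masked-in cells as rows: coordinates plus all metric values."""
        gx, gy = self.grid.cell_centers()
        sel = self.mask
        out = pd.DataFrame({"x": gx[sel], "y": gy[sel]})
        for name in METRIC_NAMES:
            out[name] = self.metrics[name][sel]
        return out


def make_grid(
    city: CityLayers, cell_size_m: float = 50.0
) -> tuple[GridSpec, np.ndarray]:
    """Prediction grid covering the city extent with the out-of-sample mask.

    A cell is masked out when it intersects a water body, or when every
    land-cover cell centre it contains is 'other' and no road line touches
    the cell.
    """
    if cell_size_m <= 0:
        raise ValueError("cell size must be positive")
    w, h = city.extent_m
    n_cols = int(np.ceil(w / cell_size_m))
    n_rows = int(np.ceil(h / cell_size_m))
    grid = GridSpec((0.0, 0.0), cell_size_m, n_rows, n_cols)

    cells = []
    for r in range(n_rows):
        for c in range(n_cols):
            cells.append(grid.cell_polygon(r, c))
    cells = np.asarray(cells, dtype=object)
    mask = np.ones(n_rows * n_cols, dtype=bool)

    water_union = city.water.union()
    if not water_union.is_empty:
        mask &= ~shapely.intersects(cells, water_union)

    # 'other' land cover with no road in the cell
    lc = city.landcover
    gx, gy = lc.cell_centers()
    other_code = LANDCOVER_CLASSES.index("other")
    other_cells = lc.data == other_code
    # map each land-cover cell centre to its grid cell
    col = np.clip((gx / cell_size_m).astype(int), 0, n_cols - 1)
    row = np.clip(((n_rows * cell_size_m - gy) / cell_size_m).astype(int), 0, n_rows - 1)
    flat = row * n_cols + col
    n_lc = np.bincount(flat.ravel(), minlength=n_rows * n_cols)
    n_other = np.bincount(
        flat.ravel(), weights=other_cells.ravel().astype(float), minlength=n_rows * n_cols
    )
    fully_other = (n_lc > 0) & (n_other == n_lc)

    roads_union = city.roads.union()
    has_road = (
        shapely.intersects(cells, roads_union)
        if not roads_union.is_empty
        else np.zeros(len(cells), dtype=bool)
    )
    mask &= ~(fully_other & ~has_road)
    return grid, mask.reshape(n_rows, n_cols)


def grid_features(
    city: CityLayers,
    grid: GridSpec,
    mask: np.ndarray,
    reference: FeatureMatrix,
    monitor_height_m: float = 4.0,
) -> FeatureMatrix:
    """Features at masked-in cell centres, standardized with the reference
    (fitting-set) parameters."""
    gx, gy = grid.cell_centers()
    sel = mask.ravel()
    ids = [f"cell_{i}" for i in np.nonzero(sel)[0]]
    locs = pd.DataFrame(
        {
            "location_id": ids,
            "x": gx.ravel()[sel],
            "y": gy.ravel()[sel],
            "monitor_height_m": monitor_height_m,
        }
    )
    raw = extract_features(locs, city, reference.catalogue, reference.buffers)
    return reference.transform(raw)


def predict_surfaces(
    day_model: LurModel,
    night_model: LurModel,
    features: FeatureMatrix,
    grid: GridSpec,
    mask: np.ndarray,
) -> NoiseSurface:
    """24 hourly surfaces plus aggregates from the two period models."""
    for model in (day_model, night_model):
        if model.standardization != features.params:
            raise StandardizationMismatch(
                f"{model.period} model was fitted with different "
                "standardization parameters than the grid features"
            )
    n_cells = int(mask.sum())
    feats = features.table
    if len(feats) != n_cells:
        raise ValueError("feature rows do not match masked-in cells")

    hourly_flat = np.full((24, mask.size), np.nan)
    sel = np.nonzero(mask.ravel())[0]
    day_fixed = day_model.predict_fixed(feats)
    night_fixed = night_model.predict_fixed(feats)
    for h in range(24):
        if h in DAY_HOURS:
            vals = day_fixed + day_model.hour_intercepts.get(h, 0.0)
        else:
            vals = night_fixed + night_model.hour_intercepts.get(h, 0.0)
        hourly_flat[h, sel] = vals
    hourly = hourly_flat.reshape(24, grid.n_rows, grid.n_cols)

    # per-cell scalar aggregation: bit-identical to period_metrics applied
    # to the cell's 24 hourly values (the surface's defining identity)
    stacked = np.ascontiguousarray(hourly_flat[:, sel])
    agg = {name: np.empty(stacked.shape[1]) for name in METRIC_NAMES}
    for j in range(stacked.shape[1]):
        m = period_metrics(stacked[:, j])
        agg["laeq_24hr"][j] = m.laeq_24hr_dba
        agg["l_den"][j] = m.l_den_dba
        agg["l_day"][j] = m.l_day_dba
        agg["l_night"][j] = m.l_night_dba
    metrics = {}
    for name in METRIC_NAMES:
        layer = np.full(mask.size, np.nan)
        layer[sel] = agg[name]
        metrics[name] = layer.reshape(grid.n_rows, grid.n_cols)
    return NoiseSurface(grid=grid, mask=mask, hourly=hourly, metrics=metrics)


def summarize_by_roads(
    surface: NoiseSurface, city: CityLayers, buffer_m: float = 100.0
) -> pd.DataFrame:
    """Median and IQR of each metric among masked-in cells within
    ``buffer_m`` of each road class; empty classes are omitted."""
    import warnings

    cells = surface.cell_table()
    pts = shapely.points(cells["x"].to_numpy(), cells["y"].to_numpy())
    rows = []
    for road_class in city.roads.attributes["road_class"].unique():
        lines = city.roads_of_class(road_class)
        if len(lines) == 0:
            warnings.warn(f"road class {road_class!r} has no lines; omitted")
            continue
        tree = STRtree(lines.geometries)
        idx_pt, _ = tree.query(pts, predicate="dwithin", distance=buffer_m)
        in_buf = np.unique(idx_pt)
        if in_buf.size == 0:
            warnings.warn(f"no cells within {buffer_m} m of {road_class!r}; omitted")
            continue
        row = {"road_class": road_class, "n_cells": int(in_buf.size)}
        for name in METRIC_NAMES:
            vals = cells[name].to_numpy()[in_buf]
            q1, q3 = np.percentile(vals, [25, 75])
            row[f"{name}_median"] = float(np.median(vals))
            row[f"{name}_q1"] = float(q1)
            row[f"{name}_q3"] = float(q3)
        rows.append(row)
    return pd.DataFrame(rows)
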