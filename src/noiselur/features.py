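"""Buffer-based extraction of spatial predictor variables.

Each catalogue entry names a layer, a zonal statistic and an a-priori sign
expectation.  Buffered statistics are computed in closed disks (boundary
features count) at the configured radii; raster statistics use
cell-centre-in-buffer inclusion at the raster's native resolution; distance
variables are bufferless.  Standardization (z-scoring with the sample SD)
is fitted on a designated row set and its parameters are stored so that
prediction locations are transformed with exactly the fitting-set
parameters.  Count and presence variables stay on their raw scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .geo import Raster
from .synthetic_city import (
    CityLayers,
    LANDCOVER_CLASSES,
    POI_CATEGORIES,
    ROAD_CLASSES,
)

log = logging.getLogger(__name__)

STATISTICS = (
    "length_sum",
    "area_sum",
    "raster_mean",
    "point_count",
    "point_presence",
    "density_mean",
    "distance",
    "sqrt_distance",
)
RAW_STATISTICS = {"point_count", "point_presence"}  # never standardized


class CatalogueError(KeyError):
    """A catalogue entry does not resolve against the city layers."""


@dataclass(frozen=True)
class BufferSpec:
    radii_m: tuple[float, ...] = (50.0, 100.0, 200.0, 500.0)

    def __post_init__(self) -> None:
        r = self.radii_m
        if not r or any(x <= 0 for x in r) or any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("buffer radii must be positive and strictly increasing")


@dataclass(frozen=True)
class FeatureSpec:
    """One candidate predictor: where it comes from and how it is summarised."""

    name: str
    layer: str  # roads | landcover | ndvi | dem | pois | buildings | eas | water | airport
    statistic: str
    expected_sign: str = "either"  # '+', '-', 'either'
    subset: str | None = None  # road class / landcover class / POI category

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise CatalogueError(f"unknown statistic {self.statistic!r}")
        if self.expected_sign not in ("+", "-", "either"):
            raise CatalogueError(f"bad expected_sign {self.expected_sign!r}")

    @property
    def buffered(self) -> bool:
        return self.statistic not in ("distance", "sqrt_distance")


def default_catalogue() -> list[FeatureSpec]:
    """The standard noise-LUR candidate set.

    Roads and human-activity variables are expected to raise noise,
    vegetation and formal residential land use to lower it; distance
    variables fall off with distance (negative), airport/water carry no
    prior.
    """
    cat: list[FeatureSpec] = []
    for rc in ROAD_CLASSES:
        cat.append(FeatureSpec(f"{rc}_road_length", "roads", "length_sum", "+", rc))
    cat.append(FeatureSpec("all_road_length", "roads", "length_sum", "+"))
    signs = {
        "industrial_business_commercial": "+",
        "informal_high_density": "+",
        "formal_low_medium_residential": "-",
        "other": "either",
    }
    for lc in LANDCOVER_CLASSES:
        cat.append(FeatureSpec(f"{lc}_area", "landcover", "area_sum", signs[lc], lc))
    cat.append(FeatureSpec("ndvi", "ndvi", "raster_mean", "-"))
    cat.append(FeatureSpec("dem", "dem", "raster_mean", "either"))
    for pc in POI_CATEGORIES:
        cat.append(FeatureSpec(f"{pc}_count", "pois", "point_count", "+", pc))
        cat.append(FeatureSpec(f"{pc}_presence", "pois", "point_presence", "+", pc))
    cat.append(FeatureSpec("building_count", "buildings", "point_count", "+"))
    cat.append(FeatureSpec("population_density", "eas", "density_mean", "+"))
    cat.append(FeatureSpec("water_area", "water", "area_sum", "either"))
    cat.append(FeatureSpec("dist_major_road", "roads", "distance", "-", "major"))
    cat.append(
        FeatureSpec("sqrt_dist_major_road", "roads", "sqrt_distance", "-", "major")
    )
    cat.append(
        FeatureSpec(
            "dist_secondary_road", "roads", "distance", "-", "secondary_tertiary"
        )
    )
    cat.append(
        FeatureSpec(
            "sqrt_dist_secondary_road",
            "roads",
            "sqrt_distance",
            "-",
            "secondary_tertiary",
        )
    )
    cat.append(FeatureSpec("dist_airport", "airport", "distance", "either"))
    cat.append(FeatureSpec("sqrt_dist_airport", "airport", "sqrt_distance", "either"))
    return cat


def column_name(spec: FeatureSpec, radius_m: float | None) -> str:
    return spec.name if radius_m is None else f"{spec.name}_{int(radius_m)}"


def parse_buffer(column: str, catalogue: list[FeatureSpec]) -> tuple[str, float | None]:
    """Split a matrix column into (variable name, buffer radius or None)."""
    by_name = {s.name for s in catalogue}
    if column in by_name:
        return column, None
    stem, _, tail = column.rpartition("_")
    if stem in by_name:
        return stem, float(tail)
    raise CatalogueError(f"column {column!r} does not match the catalogue")


@dataclass
class FeatureMatrix:
    """Location-by-predictor table plus standardization state.

    ``table`` holds raw feature values indexed by location id together with
    ``x``, ``y`` and ``monitor_height_m``.  After :meth:`standardize`,
    ``params`` maps standardized columns to their fitting-set (mean, sd);
    raw-flagged columns pass through untouched.
    """

    table: pd.DataFrame
    catalogue: list[FeatureSpec]
    buffers: BufferSpec
    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    raw_columns: tuple[str, ...] = ()
    dropped_columns: tuple[str, ...] = ()

    META = ("x", "y", "monitor_height_m")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.META]

    @property
    def standardized(self) -> bool:
        return bool(self.params)

    def standardize(self, fit_ids=None) -> "FeatureMatrix":
        """Z-score continuous columns on ``fit_ids`` (default: all rows).

        Uses the sample (n-1) SD.  Constant columns cannot be standardized
        and are dropped from the candidate set with a warning.
        """
        fit = self.table if fit_ids is None else self.table.loc[fit_ids]
        if len(fit) < 2:
            raise ValueError("need at least two fitting rows to standardize")
        raw = {
            column_name(s, r)
            for s in self.catalogue
            if s.statistic in RAW_STATISTICS
            for r in (self.buffers.radii_m if s.buffered else (None,))
        }
        out = self.table.copy()
        params: dict[str, tuple[float, float]] = {}
        dropped: list[str] = []
        for col in self.feature_columns:
            if col in raw:
                continue
            mean = float(fit[col].mean())
            sd = float(fit[col].std(ddof=1))
            if sd == 0 or not np.isfinite(sd):
                log.warning("dropping constant column %r (zero SD)", col)
                dropped.append(col)
                out = out.drop(columns=col)
                continue
            params[col] = (mean, sd)
            out[col] = (out[col] - mean) / sd
        return FeatureMatrix(
            out,
            self.catalogue,
            self.buffers,
            params,
            tuple(sorted(raw & set(out.columns))),
            tuple(dropped),
        )

    def transform(self, other: "FeatureMatrix") -> "FeatureMatrix":
        """Apply this matrix's stored standardization to another raw matrix."""
        if not self.standardized:
            raise ValueError("standardize() must run before transform()")
        out = other.table.copy()
        for col, (mean, sd) in self.params.items():
            if col not in out.columns:
                raise CatalogueError(f"column {col!r} missing from target matrix")
            out[col] = (out[col] - mean) / sd
        out = out.drop(columns=[c for c in self.dropped_columns if c in out.columns])
        return FeatureMatrix(
            out, self.catalogue, self.buffers, dict(self.params),
            self.raw_columns, self.dropped_columns,
        )

    def values(self) -> pd.DataFrame:
        return self.table[self.feature_columns]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="location_id")
        sidecar = {
            "params": {k: list(v) for k, v in self.params.items()},
            "raw_columns": list(self.raw_columns),
            "dropped_columns": list(self.dropped_columns),
            "buffers": list(self.buffers.radii_m),
            "catalogue": [
                {
                    "name": s.name,
                    "layer": s.layer,
                    "statistic": s.statistic,
                    "expected_sign": s.expected_sign,
                    "subset": s.subset,
                }
                for s in self.catalogue
            ],
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        table = pd.read_csv(path, index_col="location_id")
        with open(str(path) + ".json") as fh:
            sc = json.load(fh)
        return cls(
            table,
            [FeatureSpec(**d) for d in sc["catalogue"]],
            BufferSpec(tuple(sc["buffers"])),
            {k: (v[0], v[1]) for k, v in sc["params"].items()},
            tuple(sc["raw_columns"]),
            tuple(sc["dropped_columns"]),
        )


# ---------------------------------------------------------------------------
# extraction


def _layer_geoms(city: CityLayers, spec: FeatureSpec):
    if spec.layer == "roads":
        layer = city.roads if spec.subset is None else city.roads_of_class(spec.subset)
        return layer.geometries
    if spec.layer == "pois":
        mask = city.pois.attributes["category"] == spec.subset
        return [g for g, m in zip(city.pois.geometries, mask) if m]
    if spec.layer == "buildings":
        return city.buildings.geometries
    if spec.layer == "water":
        return city.water.geometries
    if spec.layer == "airport":
        return [city.airport]
    raise CatalogueError(f"no vector geometries for layer {spec.layer!r}")


def _raster_for(city: CityLayers, spec: FeatureSpec) -> Raster:
    if spec.layer == "ndvi":
        return city.ndvi
    if spec.layer == "dem":
        return city.dem
    raise CatalogueError(f"no raster for layer {spec.layer!r}")


def _buffered_vector_stat(
    spec: FeatureSpec, points, radius: float, city: CityLayers
) -> np.ndarray:
    geoms = _layer_geoms(city, spec)
    n = len(points)
    out = np.zeros(n)
    if not geoms:
        return out
    tree = STRtree(geoms)
    if spec.statistic in ("point_count", "point_presence"):
        # closed disk computed on exact distances (boundary points count),
        # avoiding the polygonal buffer approximation
        idx_ctr, idx_geom = tree.query(
            points, predicate="dwithin", distance=radius * (1 + 1e-12)
        )
        counts = np.bincount(idx_ctr, minlength=n)
        if spec.statistic == "point_presence":
            return (counts > 0).astype(float)
        return counts.astype(float)
    buffers = shapely.buffer(points, radius, quad_segs=32)
    idx_buf, idx_geom = tree.query(buffers, predicate="intersects")
    if spec.statistic == "length_sum":
        pieces = shapely.intersection(buffers[idx_buf], np.asarray(geoms, dtype=object)[idx_geom])
        np.add.at(out, idx_buf, shapely.length(pieces))
    elif spec.statistic == "area_sum":
        pieces = shapely.intersection(buffers[idx_buf], np.asarray(geoms, dtype=object)[idx_geom])
        np.add.at(out, idx_buf, shapely.area(pieces))
    else:
        raise CatalogueError(f"statistic {spec.statistic!r} is not a vector buffer stat")
    return out


def _landcover_area(
    spec: FeatureSpec, xs: np.ndarray, ys: np.ndarray, radius: float, city: CityLayers
) -> np.ndarray:
    """Class area from land-cover cells whose centres fall in the buffer."""
    rast = city.landcover
    code = LANDCOVER_CLASSES.index(spec.subset)
    gx, gy = rast.cell_centers()
    match = rast.data == code
    cell_area = rast.cell_size**2
    out = np.empty(len(xs))
    mx, my = gx[match], gy[match]
    for i, (x, y) in enumerate(zip(xs, ys)):
        inside = (mx - x) ** 2 + (my - y) ** 2 <= radius**2
        out[i] = inside.sum() * cell_area
    return out


def _raster_mean(
    spec: FeatureSpec, xs: np.ndarray, ys: np.ndarray, radius: float, city: CityLayers
) -> np.ndarray:
    rast = _raster_for(city, spec)
    gx, gy = rast.cell_centers()
    vals = rast.data
    omit_negative = spec.layer == "ndvi"  # water shows as negative NDVI
    out = np.empty(len(xs))
    at_point = rast.values_at(xs, ys)
    for i, (x, y) in enumerate(zip(xs, ys)):
        inside = (gx - x) ** 2 + (gy - y) ** 2 <= radius**2
        v = vals[inside]
        if omit_negative:
            v = v[v >= 0]
        if v.size:
            out[i] = v.mean()
        else:
            # buffer smaller than the raster resolution (or all-water NDVI):
            # fall back to the location's own cell, floored at 0 for NDVI
            out[i] = max(at_point[i], 0.0) if omit_negative else at_point[i]
    return out


def _population_density(
    xs: np.ndarray, ys: np.ndarray, radius: float, city: CityLayers
) -> np.ndarray:
    """Area-weighted mean EA population density (people/km^2) in the buffer."""
    eas = city.eas
    dens = (
        eas.attributes["population"].to_numpy()
        / np.maximum(shapely.area(np.asarray(eas.geometries, dtype=object)), 1.0)
        * 1e6
    )
    tree = STRtree(eas.geometries)
    points = shapely.points(xs, ys)
    buffers = shapely.buffer(points, radius, quad_segs=32)
    idx_buf, idx_ea = tree.query(buffers, predicate="intersects")
    num = np.zeros(len(xs))
    den = np.zeros(len(xs))
    if len(idx_buf):
        pieces = shapely.intersection(
            buffers[idx_buf], np.asarray(eas.geometries, dtype=object)[idx_ea]
        )
        areas = shapely.area(pieces)
        np.add.at(num, idx_buf, areas * dens[idx_ea])
        np.add.at(den, idx_buf, areas)
    return np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)


def _distances(spec: FeatureSpec, points, city: CityLayers) -> np.ndarray:
    geoms = _layer_geoms(city, spec)
    if not geoms:
        return np.full(len(points), np.nan)
    target = shapely.union_all(geoms)
    d = shapely.distance(points, target)
    return np.sqrt(d) if spec.statistic == "sqrt_distance" else d


def extract_features(
    locations: pd.DataFrame,
    city: CityLayers,
    catalogue: list[FeatureSpec] | None = None,
    buffers: BufferSpec | None = None,
) -> FeatureMatrix:
    """Raw (unstandardized) feature matrix at ``locations``.

    ``locations`` must have columns ``site_id`` (or ``location_id``), ``x``,
    ``y`` and may carry ``monitor_height_m`` (default 4 m).
    """
    catalogue = catalogue if catalogue is not None else default_catalogue()
    buffers = buffers or BufferSpec()
    id_col = "site_id" if "site_id" in locations.columns else "location_id"
    xs = locations["x"].to_numpy(dtype=float)
    ys = locations["y"].to_numpy(dtype=float)
    w, h = city.extent_m
    if np.any((xs < 0) | (xs > w) | (ys < 0) | (ys > h)):
        raise ValueError("locations fall outside the city extent")
    points = shapely.points(xs, ys)
    cols: dict[str, np.ndarray] = {
        "x": xs,
        "y": ys,
        "monitor_height_m": (
            locations["monitor_height_m"].to_numpy(dtype=float)
            if "monitor_height_m" in locations.columns
            else np.full(len(xs), 4.0)
        ),
    }
    for spec in catalogue:
        if not spec.buffered:
            cols[spec.name] = _distances(spec, points, city)
            continue
        for radius in buffers.radii_m:
            col = column_name(spec, radius)
            if spec.statistic in ("length_sum", "point_count", "point_presence") or (
                spec.statistic == "area_sum" and spec.layer in ("water", "airport")
            ):
                cols[col] = _buffered_vector_stat(spec, points, radius, city)
            elif spec.statistic == "area_sum" and spec.layer == "landcover":
                cols[col] = _landcover_area(spec, xs, ys, radius, city)
            elif spec.statistic == "raster_mean":
                cols[col] = _raster_mean(spec, xs, ys, radius, city)
            elif spec.statistic == "density_mean":
                cols[col] = _population_density(xs, ys, radius, city)
            else:
                raise CatalogueError(
                    f"cannot evaluate {spec.statistic!r} for layer {spec.layer!r}"
                )
    out = pd.DataFrame(cols, index=pd.Index(locations[id_col], name="location_id"))
    return FeatureMatrix(out, list(catalogue), buffers)
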