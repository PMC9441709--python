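"""Synthetic city generator with a known acoustic ground truth.

The generator builds a miniature city — road network by class, categorical
land cover, NDVI and elevation rasters, points of interest, building
centroids, enumeration areas (EAs) with population and socioeconomic
attributes, water bodies and an airport polygon — on a small planar extent,
then simulates minute-resolution A-weighted sound levels at monitoring
sites from a linear model on standardized spatial features plus diurnal
structure, site random intercepts, Gaussian residuals and intermittent
sound events added on the energy scale.  Because the data-generating model
is known exactly, every downstream stage (feature extraction, model
selection, cross-validation, surfaces, exposure summaries) can be checked
against a recoverable truth.

Defaults emulate the study conditions of a West-African metropolis at desk
scale: a 4 km x 4 km extent instead of a whole metropolitan area, 136
rotating (7-day) plus 10 fixed (30-day) sites, land-cover classes
{industrial/business/commercial, informal high-density residential, formal
low/medium residential, other}, and Table-like effect sizes (dBA per
standardized unit) for roads, vegetation and human-activity predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

from .geo import DEFAULT_CRS, Raster, VectorLayer

LANDCOVER_CLASSES = (
    "industrial_business_commercial",
    "informal_high_density",
    "formal_low_medium_residential",
    "other",
)
ROAD_CLASSES = ("major", "secondary_tertiary", "minor")
POI_CATEGORIES = (
    "restaurant",
    "school",
    "hospital",
    "bus_station",
    "bar",
    "church",
    "mosque",
    "shopping_center",
)

NIGHT_HOURS = tuple(list(range(22, 24)) + list(range(0, 6)))
DAY_HOURS = tuple(range(6, 22))


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class PlacementError(RuntimeError):
    """Site placement could not satisfy its constraints."""


@dataclass(frozen=True)
class CityConfig:
    """Size/density knobs for the synthetic city."""

    extent_m: tuple[float, float] = (4000.0, 4000.0)
    landcover_res_m: float = 20.0
    ndvi_res_m: float = 30.0
    dem_res_m: float = 90.0
    n_eas: int = 40
    n_major_roads: int = 4
    n_secondary_roads: int = 8
    n_minor_roads: int = 60
    n_buildings: int = 800
    poi_counts: dict[str, int] = field(
        default_factory=lambda: {
            "restaurant": 60,
            "school": 25,
            "hospital": 8,
            "bus_station": 12,
            "bar": 30,
            "church": 35,
            "mosque": 20,
            "shopping_center": 10,
        }
    )
    water_fraction: float = 0.03
    ndvi_road_slope: float = 0.9  # NDVI drop from no-road to densest-road areas
    ndvi_texture_sd: float = 0.12  # cell-scale NDVI variability (trees/roofs/plots)
    mean_ea_population: float = 775.0

    def validate(self) -> None:
        if min(self.extent_m) <= 0:
            raise ConfigurationError("extent must be positive")
        for res in (self.landcover_res_m, self.ndvi_res_m, self.dem_res_m):
            if res <= 0:
                raise ConfigurationError("raster resolutions must be positive")
        if self.n_eas < 1:
            raise ConfigurationError("need at least one enumeration area")
        if not 0 <= self.water_fraction < 0.5:
            raise ConfigurationError("water_fraction must be in [0, 0.5)")


@dataclass
class CityLayers:
    """All geospatial layers of one synthetic city (single planar CRS)."""

    roads: VectorLayer
    landcover: Raster  # integer codes indexing LANDCOVER_CLASSES
    ndvi: Raster
    dem: Raster
    pois: VectorLayer
    buildings: VectorLayer
    eas: VectorLayer
    water: VectorLayer
    airport: Polygon
    extent_m: tuple[float, float]
    crs: str = DEFAULT_CRS

    @property
    def extent_polygon(self) -> Polygon:
        return shapely.box(0.0, 0.0, *self.extent_m)

    def roads_of_class(self, road_class: str) -> VectorLayer:
        return self.roads.select(self.attributes_mask("roads", "road_class", road_class))

    def attributes_mask(self, layer: str, column: str, value) -> np.ndarray:
        return (getattr(self, layer).attributes[column] == value).to_numpy()

    def landcover_class_at(self, x, y) -> np.ndarray:
        codes = self.landcover.values_at(x, y).astype(int)
        return np.asarray(LANDCOVER_CLASSES, dtype=object)[codes]

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.roads.to_geojson(outdir / "roads.geojson")
        self.pois.to_geojson(outdir / "pois.geojson")
        self.buildings.to_geojson(outdir / "buildings.geojson")
        self.eas.to_geojson(outdir / "eas.geojson")
        self.water.to_geojson(outdir / "water.geojson")
        VectorLayer([self.airport], pd.DataFrame({"name": ["airport"]}), self.crs).to_geojson(
            outdir / "airport.geojson"
        )
        self.landcover.to_asc(outdir / "landcover.asc")
        self.ndvi.to_asc(outdir / "ndvi.asc")
        self.dem.to_asc(outdir / "dem.asc")

    @classmethod
    def read(cls, outdir) -> "CityLayers":
        from pathlib import Path

        outdir = Path(outdir)
        landcover = Raster.from_asc(outdir / "landcover.asc")
        _, _, xmax, ymax = landcover.bounds
        airport_layer = VectorLayer.from_geojson(outdir / "airport.geojson")
        return cls(
            roads=VectorLayer.from_geojson(outdir / "roads.geojson"),
            landcover=landcover,
            ndvi=Raster.from_asc(outdir / "ndvi.asc"),
            dem=Raster.from_asc(outdir / "dem.asc"),
            pois=VectorLayer.from_geojson(outdir / "pois.geojson"),
            buildings=VectorLayer.from_geojson(outdir / "buildings.geojson"),
            eas=VectorLayer.from_geojson(outdir / "eas.geojson"),
            water=VectorLayer.from_geojson(outdir / "water.geojson"),
            airport=airport_layer.geometries[0],
            extent_m=(xmax, ymax),
        )


@dataclass(frozen=True)
class TruthModel:
    """Ground-truth data-generating model for minute levels.

    ``betas`` are dBA per standardized unit of the named feature column;
    ``hour_effects`` hold the within-block diurnal shape (mean zero over the
    day block 06-21 and over the night block 22-05 separately) while
    ``night_offset_dba`` carries the day-night level contrast.  Events occur
    as a Poisson stream per hour and add ``event_gain_dba`` on the energy
    scale to their minute.
    """

    beta0: float = 62.0
    betas: dict[str, float] = field(
        default_factory=lambda: {
            "major_road_length_100": 2.5,
            "secondary_tertiary_road_length_200": 1.8,
            "formal_low_medium_residential_area_200": -0.8,
            "ndvi_50": -2.8,
            "restaurant_count_100": 1.4,
        }
    )
    hour_effects: tuple[float, ...] = ()
    night_offset_dba: float = -7.0
    sigma_site: float = 2.0
    sigma_resid: float = 3.0
    event_rate: float = 2.0  # events per hour
    event_gain_dba: float = 10.0

    def __post_init__(self) -> None:
        for name, value in (
            ("sigma_site", self.sigma_site),
            ("sigma_resid", self.sigma_resid),
            ("event_rate", self.event_rate),
            ("event_gain_dba", self.event_gain_dba),
        ):
            if value < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.hour_effects and len(self.hour_effects) != 24:
            raise ConfigurationError("hour_effects must have 24 entries")

    def resolved_hour_effects(self) -> np.ndarray:
        if self.hour_effects:
            return np.asarray(self.hour_effects, dtype=float)
        return default_hour_effects()

    def full_hour_profile(self) -> np.ndarray:
        """Hour effects plus the night offset — the diurnal term actually
        added to each hour."""
        eff = self.resolved_hour_effects().copy()
        eff[list(NIGHT_HOURS)] += self.night_offset_dba
        return eff


def default_hour_effects() -> np.ndarray:
    """Smooth diurnal shape, centred within the day and night blocks.

    Morning/evening rush-hour bumps during the day; a decline towards the
    small hours at night.  Amplitudes of a few dBA mimic typical urban
    diurnal swings.
    """
    hours = np.arange(24)
    shape = 1.8 * np.sin((hours - 7.0) * np.pi / 12.0) + 1.2 * np.cos(
        (hours - 19.0) * np.pi / 6.0
    )
    eff = shape.copy()
    day = list(DAY_HOURS)
    night = list(NIGHT_HOURS)
    eff[day] -= eff[day].mean()
    eff[night] -= eff[night].mean()
    return eff


@dataclass(frozen=True)
class Site:
    id: str
    x: float
    y: float
    kind: str  # rotating | fixed
    monitor_height_m: float = 4.0
    land_use_class: str = "other"


def sites_frame(sites: list[Site]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.id for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
            "kind": [s.kind for s in sites],
            "monitor_height_m": [s.monitor_height_m for s in sites],
            "land_use_class": [s.land_use_class for s in sites],
        }
    )


# ---------------------------------------------------------------------------
# city generation


def _make_roads(cfg: CityConfig, rng: np.random.Generator) -> VectorLayer:
    w, h = cfg.extent_m
    geoms: list[LineString] = []
    classes: list[str] = []

    def jittered_span(horizontal: bool, offset: float) -> LineString:
        ts = np.linspace(0.0, 1.0, 9)
        wiggle = rng.normal(0.0, 0.02 * min(w, h), size=ts.size)
        wiggle[0] = wiggle[-1] = 0.0
        if horizontal:
            pts = [(t * w, np.clip(offset + dv, 0, h)) for t, dv in zip(ts, wiggle)]
        else:
            pts = [(np.clip(offset + dv, 0, w), t * h) for t, dv in zip(ts, wiggle)]
        return LineString(pts)

    # arterials: alternate horizontal/vertical spans at random offsets
    for i in range(cfg.n_major_roads):
        horizontal = i % 2 == 0
        span = h if horizontal else w
        offset = (0.15 + 0.7 * rng.random()) * span
        geoms.append(jittered_span(horizontal, offset))
        classes.append("major")
    for i in range(cfg.n_secondary_roads):
        horizontal = rng.random() < 0.5
        span = h if horizontal else w
        geoms.append(jittered_span(horizontal, rng.random() * span))
        classes.append("secondary_tertiary")
    # minor roads: short chords scattered around, denser near the centre
    for _ in range(cfg.n_minor_roads):
        cx = rng.normal(w / 2, w / 4)
        cy = rng.normal(h / 2, h / 4)
        angle = rng.random() * np.pi
        length = rng.uniform(150.0, 500.0)
        dx, dy = np.cos(angle) * length / 2, np.sin(angle) * length / 2
        line = LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)])
        clipped = line.intersection(shapely.box(0, 0, w, h))
        if not clipped.is_empty and clipped.geom_type == "LineString":
            geoms.append(clipped)
            classes.append("minor")
    return VectorLayer(geoms, pd.DataFrame({"road_class": classes}))


def _road_density_raster(
    roads: VectorLayer, cfg: CityConfig, res: float
) -> Raster:
    """Inverse-distance road-proximity score per cell (0..1-ish)."""
    w, h = cfg.extent_m
    nr, nc = int(round(h / res)), int(round(w / res))
    grid = Raster(np.zeros((nr, nc)), (0.0, 0.0), res)
    gx, gy = grid.cell_centers()
    pts = shapely.points(gx.ravel(), gy.ravel())
    dist = shapely.distance(pts, roads.union()).reshape(nr, nc)
    grid.data = 1.0 / (1.0 + dist / 150.0)
    return grid


def _smooth_noise(
    shape: tuple[int, int], rng: np.random.Generator, passes: int = 12
) -> np.ndarray:
    """Cheap smooth random field via repeated box blurring of white noise."""
    z = rng.normal(size=shape)
    for _ in range(passes):
        z = 0.2 * (
            z
            + np.roll(z, 1, axis=0)
            + np.roll(z, -1, axis=0)
            + np.roll(z, 1, axis=1)
            + np.roll(z, -1, axis=1)
        )
    z = (z - z.mean()) / (z.std() + 1e-12)
    return z


def _make_water(cfg: CityConfig, rng: np.random.Generator) -> VectorLayer:
    if cfg.water_fraction <= 0:
        return VectorLayer([], pd.DataFrame({"name": pd.Series(dtype=object)}))
    w, h = cfg.extent_m
    target = cfg.water_fraction * w * h
    n_lakes = 1 if target < 0.05 * w * h else 2
    geoms, names = [], []
    for i in range(n_lakes):
        area = target / n_lakes
        radius = float(np.sqrt(area / np.pi))
        cx = rng.uniform(0.2 * w, 0.8 * w)
        cy = rng.uniform(0.2 * h, 0.8 * h)
        lake = Point(cx, cy).buffer(radius, quad_segs=32)
        geoms.append(lake.intersection(shapely.box(0, 0, w, h)))
        names.append(f"lake_{i}")
    return VectorLayer(geoms, pd.DataFrame({"name": names}))


def _make_eas(
    cfg: CityConfig, rng: np.random.Generator, density_score: Raster
) -> VectorLayer:
    """Voronoi partition of the extent into enumeration areas.

    Each EA carries the zonal mean of the arterial-road proximity score over
    its polygon — the area-level quantity that population density and SES
    are generated from (an area's character, not a single point's).
    """
    w, h = cfg.extent_m
    seeds = rng.uniform((0, 0), (w, h), size=(cfg.n_eas, 2))
    cells = voronoi_diagram(MultiPoint([Point(*p) for p in seeds]), envelope=shapely.box(0, 0, w, h))
    extent = shapely.box(0, 0, w, h)
    polys = [geom.intersection(extent) for geom in cells.geoms]
    polys = [p for p in polys if not p.is_empty and p.area > 0]
    gx, gy = density_score.cell_centers()
    flat_x, flat_y = gx.ravel(), gy.ravel()
    flat_score = density_score.data.ravel()
    rows = []
    for i, poly in enumerate(polys):
        inside = shapely.contains_xy(poly, flat_x, flat_y)
        if inside.any():
            score = float(flat_score[inside].mean())
        else:  # sliver smaller than a score cell: fall back to the centroid
            c = poly.centroid
            score = float(density_score.values_at(c.x, c.y))
        rows.append({"ea_id": f"EA{i:03d}", "density_score": score, "area_m2": poly.area})
    attrs = pd.DataFrame(rows)
    return VectorLayer(polys, attrs)


def _populate_eas(
    eas: VectorLayer, cfg: CityConfig, rng: np.random.Generator
) -> VectorLayer:
    """Attach population and socioeconomic attributes.

    Population scales with the road-proximity score (denser near roads);
    log-consumption falls with that score so that, as in many rapidly
    urbanising cities, poorer areas sit closer to the loud road network.
    Education counts rise with consumption, unemployment falls with it.
    """
    attrs = eas.attributes.copy()
    n = len(attrs)
    score = attrs["density_score"].to_numpy()
    score_z = (score - score.mean()) / (score.std() + 1e-12)
    weights = np.exp(0.8 * score_z + rng.normal(0, 0.3, n))
    weights /= weights.mean()
    attrs["population"] = np.maximum(
        0, np.round(cfg.mean_ea_population * weights)
    ).astype(int)
    consumption = 8.0 - 0.35 * score_z + rng.normal(0, 0.25, n)
    attrs["ses_consumption"] = consumption
    frac_edu = 1.0 / (1.0 + np.exp(-(consumption - 8.0) * 2.0 + rng.normal(0, 0.4, n)))
    attrs["ses_education"] = np.round(attrs["population"] * 0.25 * frac_edu).astype(int)
    frac_unemp = 1.0 / (1.0 + np.exp((consumption - 8.0) * 1.5 + rng.normal(0, 0.4, n)))
    attrs["ses_unemployed"] = np.round(attrs["population"] * 0.15 * frac_unemp).astype(int)
    return VectorLayer(eas.geometries, attrs, eas.crs)


def _scatter_near_roads(
    n: int,
    roads_union,
    cfg: CityConfig,
    rng: np.random.Generator,
    near_fraction: float = 0.7,
    spread_m: float = 120.0,
) -> np.ndarray:
    """n points, a mix of road-hugging and uniform placement."""
    w, h = cfg.extent_m
    pts = np.empty((n, 2))
    n_near = int(round(n * near_fraction))
    if n_near and not roads_union.is_empty:
        dists = rng.random(n_near) * roads_union.length
        base = [roads_union.interpolate(d) for d in dists]
        jitter = rng.normal(0, spread_m, size=(n_near, 2))
        pts[:n_near, 0] = np.clip([p.x for p in base] + jitter[:, 0], 0, w)
        pts[:n_near, 1] = np.clip([p.y for p in base] + jitter[:, 1], 0, h)
    else:
        n_near = 0
    pts[n_near:] = rng.uniform((0, 0), (w, h), size=(n - n_near, 2))
    return pts


def generate_city(config: CityConfig | None = None, seed: int = 0) -> CityLayers:
    """Build all layers deterministically from (config, seed)."""
    cfg = config or CityConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    w, h = cfg.extent_m

    roads = _make_roads(cfg, rng)
    road_score_lc = _road_density_raster(roads, cfg, cfg.landcover_res_m)
    water = _make_water(cfg, rng)
    water_union = water.union()

    # land cover from road proximity + smooth noise
    smooth = _smooth_noise(road_score_lc.shape, rng)
    urban_score = 1.4 * (road_score_lc.data - road_score_lc.data.mean()) / (
        road_score_lc.data.std() + 1e-12
    ) + 0.8 * smooth
    codes = np.full(road_score_lc.shape, LANDCOVER_CLASSES.index("other"))
    q40, q65, q85 = np.quantile(urban_score, [0.40, 0.65, 0.85])
    codes[urban_score >= q40] = LANDCOVER_CLASSES.index("formal_low_medium_residential")
    codes[urban_score >= q65] = LANDCOVER_CLASSES.index("informal_high_density")
    codes[urban_score >= q85] = LANDCOVER_CLASSES.index("industrial_business_commercial")
    landcover = Raster(codes.astype(float), (0.0, 0.0), cfg.landcover_res_m)

    # NDVI: anti-correlated with road proximity by construction; negative on
    # water.  Real satellite NDVI carries strong cell-to-cell texture from
    # individual trees, roofs and plots, so the field mixes a smooth
    # neighbourhood component with white noise at the native resolution —
    # without the latter, buffer means at nearby radii would be nearly
    # indistinguishable.
    road_score_ndvi = _road_density_raster(roads, cfg, cfg.ndvi_res_m)
    ndvi_smooth = _smooth_noise(road_score_ndvi.shape, rng, passes=4)
    ndvi_texture = rng.normal(size=road_score_ndvi.shape)
    ndvi_vals = (
        0.55
        - cfg.ndvi_road_slope * road_score_ndvi.data
        + 0.06 * ndvi_smooth
        + cfg.ndvi_texture_sd * ndvi_texture
    )
    ndvi = Raster(np.clip(ndvi_vals, -1.0, 1.0), (0.0, 0.0), cfg.ndvi_res_m)
    if not water_union.is_empty:
        gx, gy = ndvi.cell_centers()
        wet = shapely.contains(water_union, shapely.points(gx.ravel(), gy.ravel()))
        data = ndvi.data.ravel()
        data[wet] = -0.1
        ndvi.data = data.reshape(ndvi.shape)

    # gentle coastal-plain elevation with smooth relief
    nr_d, nc_d = int(round(h / cfg.dem_res_m)), int(round(w / cfg.dem_res_m))
    dem_noise = _smooth_noise((nr_d, nc_d), rng, passes=20)
    xg = np.linspace(0, 1, nc_d)[None, :]
    dem = Raster(30.0 + 40.0 * xg + 15.0 * dem_noise, (0.0, 0.0), cfg.dem_res_m)

    roads_union = roads.union()
    poi_geoms, poi_cats = [], []
    for cat in POI_CATEGORIES:
        n = cfg.poi_counts.get(cat, 0)
        for x, y in _scatter_near_roads(n, roads_union, cfg, rng):
            poi_geoms.append(Point(x, y))
            poi_cats.append(cat)
    pois = VectorLayer(poi_geoms, pd.DataFrame({"category": poi_cats}))

    bpts = _scatter_near_roads(cfg.n_buildings, roads_union, cfg, rng, 0.6, 200.0)
    buildings = VectorLayer(
        [Point(x, y) for x, y in bpts],
        pd.DataFrame({"building_id": np.arange(cfg.n_buildings)}),
    )

    # EA socioeconomics follow arterial (major + secondary) road proximity,
    # scored on a coarse grid: informal, poorer, denser settlement clusters
    # along the loud arterial corridors
    arterials = roads.select(
        roads.attributes["road_class"].isin(["major", "secondary_tertiary"]).to_numpy()
    )
    arterial_score = _road_density_raster(arterials, cfg, res=100.0)
    eas = _populate_eas(_make_eas(cfg, rng, arterial_score), cfg, rng)

    # airport: rectangle tucked in the south-east corner
    aw, ah = 0.12 * w, 0.06 * h
    airport = shapely.box(w - 1.3 * aw, 0.08 * h, w - 0.3 * aw, 0.08 * h + ah)

    return CityLayers(
        roads=roads,
        landcover=landcover,
        ndvi=ndvi,
        dem=dem,
        pois=pois,
        buildings=buildings,
        eas=eas,
        water=water,
        airport=airport,
        extent_m=cfg.extent_m,
    )


def place_sites(
    city: CityLayers,
    n_rotating: int = 136,
    n_fixed: int = 10,
    seed: int = 0,
    stratify: bool = True,
) -> list[Site]:
    """Stratified random site placement across land-cover classes.

    Quotas are proportional to each class's areal share with a floor of two
    sites per class (monitoring designs want every stratum observed); water
    cells are never eligible.
    """
    n_total = n_rotating + n_fixed
    if n_total < 1:
        raise ConfigurationError("need at least one site")
    n_classes = len(LANDCOVER_CLASSES)
    if stratify and n_total < 2 * n_classes:
        stratify = False  # too few sites to hold quotas; fall back to random
    rng = np.random.default_rng(seed)
    w, h = city.extent_m
    water_union = city.water.union()

    def draw_candidates(k: int) -> pd.DataFrame:
        xy = rng.uniform((0, 0), (w, h), size=(k, 2))
        ok = np.ones(k, dtype=bool)
        if not water_union.is_empty:
            ok = ~shapely.intersects(shapely.points(xy[:, 0], xy[:, 1]), water_union)
        df = pd.DataFrame({"x": xy[ok, 0], "y": xy[ok, 1]})
        df["lclass"] = city.landcover_class_at(df["x"].to_numpy(), df["y"].to_numpy())
        return df

    chosen: list[tuple[float, float, str]] = []
    if stratify:
        shares = np.array(
            [(city.landcover.data == i).mean() for i in range(n_classes)]
        )
        quotas = np.maximum(2, np.round(shares * n_total)).astype(int)
        while quotas.sum() > n_total:
            quotas[int(np.argmax(quotas))] -= 1
        while quotas.sum() < n_total:
            quotas[int(np.argmax(shares))] += 1
        need = dict(zip(LANDCOVER_CLASSES, quotas))
        for _ in range(200):
            if all(v <= 0 for v in need.values()):
                break
            cands = draw_candidates(max(200, 10 * n_total))
            for _, row in cands.iterrows():
                if need.get(row["lclass"], 0) > 0:
                    chosen.append((row["x"], row["y"], row["lclass"]))
                    need[row["lclass"]] -= 1
        if any(v > 0 for v in need.values()):
            raise PlacementError(
                "could not fill land-cover strata; too little valid land "
                f"(unfilled: { {k: v for k, v in need.items() if v > 0} })"
            )
    else:
        cands = draw_candidates(max(200, 10 * n_total))
        if len(cands) < n_total:
            raise PlacementError("too little valid land for requested sites")
        cands = cands.iloc[:n_total]
        chosen = list(cands.itertuples(index=False, name=None))

    order = rng.permutation(n_total)
    kinds = np.array(["rotating"] * n_rotating + ["fixed"] * n_fixed)[order]
    heights = 4.0 + rng.uniform(-1.0, 1.0, size=n_total)  # ~4 m (+-1 m) mounts
    return [
        Site(
            id=f"S{i:03d}",
            x=float(x),
            y=float(y),
            kind=str(kinds[i]),
            monitor_height_m=float(heights[i]),
            land_use_class=str(lclass),
        )
        for i, (x, y, lclass) in enumerate(chosen)
    ]


# ---------------------------------------------------------------------------
# minute-level simulation


def energetic_add(base_dba: np.ndarray, gain_dba: float) -> np.ndarray:
    """Combine a base level with a superimposed event of base+gain on the
    energy scale."""
    base = np.asarray(base_dba, dtype=float)
    return 10.0 * np.log10(
        np.power(10.0, base / 10.0) + np.power(10.0, (base + gain_dba) / 10.0)
    )


def simulate_minute_levels(
    city: CityLayers,
    sites: list[Site],
    truth: TruthModel,
    days_per_site: int | dict[str, int] | None = None,
    seed: int = 0,
    start_date: str = "2020-01-06",
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate 1-minute LAeq logs for every site.

    The base level of site *s*, hour *h* is
    ``beta0 + sum_k beta_k z_k(s) + hour_effect_h + b_s`` with
    ``b_s ~ N(0, sigma_site^2)``; each minute adds N(0, sigma_resid^2);
    minutes hit by a Poisson event stream (``event_rate`` per hour) gain
    ``event_gain_dba`` energetically.  ``features`` may carry a precomputed
    standardized feature table indexed by site id (else it is extracted
    here); unknown beta names raise a configuration error.
    """
    from .features import default_catalogue, extract_features

    if days_per_site is None:
        days_per_site = {"rotating": 7, "fixed": 30}
    if isinstance(days_per_site, int):
        if days_per_site < 1:
            raise ConfigurationError("days_per_site must be >= 1")
        days_per_site = {"rotating": days_per_site, "fixed": days_per_site}
    if min(days_per_site.values()) < 1:
        raise ConfigurationError("days_per_site must be >= 1")

    if features is None:
        fm = extract_features(sites_frame(sites), city, default_catalogue())
        fm = fm.standardize()
        features = fm.values()
    missing = [k for k in truth.betas if k not in features.columns]
    if missing:
        raise ConfigurationError(f"unknown truth beta names: {missing}")

    rng = np.random.default_rng(seed)
    hour_profile = truth.full_hour_profile()
    start = pd.Timestamp(start_date)
    frames = []
    for site in sites:
        z = features.loc[site.id]
        fixed = truth.beta0 + sum(b * float(z[k]) for k, b in truth.betas.items())
        b_site = rng.normal(0.0, truth.sigma_site) if truth.sigma_site > 0 else 0.0
        n_days = days_per_site[site.kind]
        shape = (n_days, 24, 60)
        base = fixed + b_site + hour_profile[None, :, None] + (
            rng.normal(0.0, truth.sigma_resid, size=shape)
            if truth.sigma_resid > 0
            else 0.0
        )
        base = np.broadcast_to(base, shape).copy()
        levels = base
        if truth.event_rate > 0 and truth.event_gain_dba > 0:
            n_events = rng.poisson(truth.event_rate, size=(n_days, 24))
            n_events = np.minimum(n_events, 60)
            event_mask = np.zeros(shape, dtype=bool)
            for d, hh in zip(*np.nonzero(n_events)):
                idx = rng.choice(60, size=n_events[d, hh], replace=False)
                event_mask[d, hh, idx] = True
            levels = np.where(event_mask, energetic_add(base, truth.event_gain_dba), base)
        timestamps = start + pd.to_timedelta(np.arange(n_days * 24 * 60), unit="min")
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site.id,
                    "timestamp": timestamps,
                    "laeq_1min_dba": levels.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def with_betas(truth: TruthModel, betas: dict[str, float]) -> TruthModel:
    """Truth with a replaced fixed-effect map (convenience for experiments)."""
    return replace(truth, betas=dict(betas))
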