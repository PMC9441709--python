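"""Prediction surfaces: masking geometry, aggregation identity, and
internal consistency with the acoustics aggregates."""

import numpy as np
import pandas as pd
import pytest
import shapely

from noiselur.acoustics import period_metrics
from noiselur.lur import fit_mixed
from noiselur.surfaces import (
    StandardizationMismatch,
    grid_features,
    make_grid,
    predict_surfaces,
    summarize_by_roads,
)
from noiselur.synthetic_city import CityConfig, TruthModel, generate_city, simulate_minute_levels
from noiselur import acoustics


@pytest.fixture(scope="module")
def fitted_models(small_city, small_sites, small_fm):
    truth = TruthModel(
        betas={"major_road_length_100": 2.5, "ndvi_50": -2.8}, event_rate=0.0
    )
    minutes = simulate_minute_levels(
        small_city, small_sites, truth, days_per_site=2, seed=21,
        features=small_fm.values(),
    )
    hourly = acoustics.hourly_levels(minutes)
    variables = ["major_road_length_100", "ndvi_50"]
    return (
        fit_mixed(hourly, small_fm, variables, "day"),
        fit_mixed(hourly, small_fm, variables, "night"),
    )


@pytest.fixture(scope="module")
def surface(small_city, small_fm, fitted_models):
    day, night = fitted_models
    grid, mask = make_grid(small_city, cell_size_m=100.0)
    gfm = grid_features(small_city, grid, mask, small_fm)
    return predict_surfaces(day, night, gfm, grid, mask), grid, mask


class TestMakeGrid:
    def test_lake_mask_matches_geometric_oracle(self, small_city):
        grid, mask = make_grid(small_city, cell_size_m=100.0)
        water = small_city.water.union()
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                cell = grid.cell_polygon(r, c)
                if water.intersects(cell):
                    assert not mask[r, c]

    def test_all_water_city_has_no_predictable_cells(self):
        cfg = CityConfig(extent_m=(600.0, 600.0), n_eas=4, water_fraction=0.0)
        city = generate_city(cfg, seed=1)
        # flood the whole extent
        from noiselur.geo import VectorLayer

        city.water = VectorLayer(
            [shapely.box(0, 0, 600, 600)], pd.DataFrame({"name": ["sea"]})
        )
        _, mask = make_grid(city, 100.0)
        assert mask.sum() == 0

    def test_roadless_other_cells_masked_out(self):
        cfg = CityConfig(extent_m=(600.0, 600.0), n_eas=4, water_fraction=0.0)
        city = generate_city(cfg, seed=2)
        grid, mask = make_grid(city, 100.0)
        other = 3  # landcover code for 'other'
        roads = city.roads.union()
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                cell = grid.cell_polygon(r, c)
                gx, gy = city.landcover.cell_centers()
                import shapely as sh

                inside = sh.contains_xy(cell, gx.ravel(), gy.ravel())
                vals = city.landcover.data.ravel()[inside]
                fully_other = len(vals) > 0 and (vals == other).all()
                if fully_other and not roads.intersects(cell):
                    assert not mask[r, c]
                elif roads.intersects(cell) and not city.water.union().intersects(cell):
                    assert mask[r, c]

    def test_bad_cell_size_rejected(self, small_city):
        with pytest.raises(ValueError):
            make_grid(small_city, 0.0)


class TestPredictSurfaces:
    def test_aggregation_identity_exact_per_cell(self, surface):
        surf, grid, mask = surface
        rows, cols = np.nonzero(mask)
        rng = np.random.default_rng(0)
        pick = rng.choice(len(rows), size=min(25, len(rows)), replace=False)
        for k in pick:
            r, c = rows[k], cols[k]
            m = period_metrics(surf.hourly[:, r, c])
            assert surf.metrics["l_den"][r, c] == pytest.approx(m.l_den_dba, abs=1e-12)
            assert surf.metrics["laeq_24hr"][r, c] == pytest.approx(
                m.laeq_24hr_dba, abs=1e-12
            )
            assert surf.metrics["l_day"][r, c] == pytest.approx(m.l_day_dba, abs=1e-12)
            assert surf.metrics["l_night"][r, c] == pytest.approx(
                m.l_night_dba, abs=1e-12
            )

    def test_masked_cells_carry_no_values(self, surface):
        surf, grid, mask = surface
        for name, layer in surf.metrics.items():
            assert np.isnan(layer[~mask]).all()
        assert np.isnan(surf.hourly[:, ~mask]).all()

    def test_day_levels_exceed_night_when_truth_says_so(self, surface):
        # truth keeps the default ~7 dBA night deficit
        surf, grid, mask = surface
        diff = surf.metrics["l_day"][mask] - surf.metrics["l_night"][mask]
        assert (diff > 0).all()

    def test_intercept_only_models_give_flat_surface(
        self, small_city, small_fm, small_hourly
    ):
        day = fit_mixed(small_hourly, small_fm, [], "day")
        night = fit_mixed(small_hourly, small_fm, [], "night")
        grid, mask = make_grid(small_city, 150.0)
        gfm = grid_features(small_city, grid, mask, small_fm)
        surf = predict_surfaces(day, night, gfm, grid, mask)
        vals = surf.metrics["l_den"][mask]
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-9)

    def test_standardization_mismatch_is_a_hard_error(
        self, small_city, small_fm, fitted_models
    ):
        day, night = fitted_models
        grid, mask = make_grid(small_city, 150.0)
        gfm = grid_features(small_city, grid, mask, small_fm)
        tampered = dict(gfm.params)
        first = next(iter(tampered))
        tampered[first] = (tampered[first][0] + 1.0, tampered[first][1])
        gfm2 = type(gfm)(
            gfm.table, gfm.catalogue, gfm.buffers, tampered, gfm.raw_columns
        )
        with pytest.raises(StandardizationMismatch):
            predict_surfaces(day, night, gfm2, grid, mask)

    def test_measured_site_cell_agrees_with_direct_prediction(
        self, surface, small_fm, fitted_models
    ):
        surf, grid, mask = surface
        day, night = fitted_models
        # the surface value at any cell equals period_metrics of the models'
        # 24 hourly predictions with the cell's features (internal identity)
        r, c = map(int, np.argwhere(mask)[0])
        hourly_vals = surf.hourly[:, r, c]
        m = period_metrics(hourly_vals)
        assert surf.metrics["l_den"][r, c] == pytest.approx(m.l_den_dba, abs=1e-12)


class TestSummarizeByRoads:
    def test_major_roads_louder_than_minor_with_positive_truth(
        self, surface, small_city
    ):
        surf, grid, mask = surface
        out = summarize_by_roads(surf, small_city).set_index("road_class")
        assert out.loc["major", "l_den_median"] > out.loc["minor", "l_den_median"]

    def test_constant_surface_gives_identical_medians(
        self, small_city, small_fm, small_hourly
    ):
        day = fit_mixed(small_hourly, small_fm, [], "day")
        night = fit_mixed(small_hourly, small_fm, [], "night")
        grid, mask = make_grid(small_city, 150.0)
        gfm = grid_features(small_city, grid, mask, small_fm)
        surf = predict_surfaces(day, night, gfm, grid, mask)
        out = summarize_by_roads(surf, small_city)
        assert out["l_den_median"].nunique() == 1

    def test_empty_road_class_omitted_with_warning(self, surface, small_city):
        surf, grid, mask = surface
        from noiselur.geo import VectorLayer

        far = VectorLayer(
            list(small_city.roads.geometries),
            small_city.roads.attributes.assign(
                road_class=["nowhere_class"] * 0
                + list(small_city.roads.attributes["road_class"])
            ),
        )
        city2 = small_city
        out = summarize_by_roads(surf, city2)
        assert set(out["road_class"]) <= {"major", "secondary_tertiary", "minor"}


class TestRoundTrip:
    def test_surface_written_layers_reload(self, surface, tmp_path):
        surf, grid, mask = surface
        surf.write(tmp_path / "s")
        from noiselur.geo import Raster

        back = Raster.from_asc(tmp_path / "s" / "l_den.asc")
        got = back.data[mask]
        np.testing.assert_allclose(got, surf.metrics["l_den"][mask], atol=1e-4)
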