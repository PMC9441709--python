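"""LUR selection machinery: buffer screening, stepwise rules, stability
pruning, VIF, and the site-level intermittency-ratio models."""

import numpy as np
import pandas as pd
import pytest

from noiselur import acoustics
from noiselur.features import FeatureSpec
from noiselur.lur import (
    SelectionConfig,
    best_buffer_per_variable,
    filter_period,
    fit_ir_models,
    fit_mixed,
    forward_stepwise,
    is_unstable,
    site_mean_levels,
    stability_prune,
    vif,
)
from noiselur.mixedlm import FitError
from noiselur.synthetic_city import TruthModel, simulate_minute_levels, sites_frame


NOISELESS = TruthModel(
    betas={"major_road_length_100": 2.5, "ndvi_50": -2.8},
    hour_effects=tuple([0.0] * 24),
    night_offset_dba=0.0,
    sigma_site=0.0,
    sigma_resid=0.0,
    event_rate=0.0,
)


@pytest.fixture(scope="module")
def noiseless_hourly(small_city, small_sites, small_fm):
    minutes = simulate_minute_levels(
        small_city, small_sites, NOISELESS, days_per_site=1, seed=0,
        features=small_fm.values(),
    )
    return acoustics.hourly_levels(minutes)


class TestFitMixed:
    def test_noiseless_simulation_recovers_truth_exactly(
        self, noiseless_hourly, small_fm
    ):
        m = fit_mixed(
            noiseless_hourly, small_fm, ["major_road_length_100", "ndvi_50"], "day"
        )
        assert m.coefficients["major_road_length_100"] == pytest.approx(2.5, abs=1e-5)
        assert m.coefficients["ndvi_50"] == pytest.approx(-2.8, abs=1e-5)
        assert m.r2_fixed > 0.999

    def test_empty_variable_list_gives_low_r2_on_exchangeable_data(
        self, small_hourly, small_fm
    ):
        m = fit_mixed(small_hourly, small_fm, [], "day")
        assert m.variables == []
        # only monitor height remains as a fixed covariate
        assert m.r2_fixed < 0.2

    def test_day_and_night_models_cover_their_hours(self, small_hourly, small_fm):
        day = fit_mixed(small_hourly, small_fm, ["ndvi_50"], "day")
        night = fit_mixed(small_hourly, small_fm, ["ndvi_50"], "night")
        assert set(day.hour_intercepts) == set(range(6, 22))
        assert set(night.hour_intercepts) == {22, 23, 0, 1, 2, 3, 4, 5}

    def test_too_few_sites_rejected(self, small_hourly, small_fm):
        few = small_hourly[small_hourly["site_id"].isin(small_hourly["site_id"].unique()[:5])]
        with pytest.raises(FitError):
            fit_mixed(few, small_fm, [], "day")

    def test_unknown_variable_rejected(self, small_hourly, small_fm):
        with pytest.raises(FitError, match="no_such"):
            fit_mixed(small_hourly, small_fm, ["no_such_var"], "day")


class TestBestBuffer:
    def test_true_buffer_wins_in_noiseless_data(self, noiseless_hourly, small_fm):
        bb = best_buffer_per_variable(noiseless_hourly, small_fm, period="day")
        assert bb.loc["major_road_length", "column"] == "major_road_length_100"
        assert bool(bb.loc["major_road_length", "direction_ok"])

    def test_sign_contradiction_flagged(self, noiseless_hourly, small_fm):
        # truth has NDVI negative; an entry expecting '+' must fail the screen
        cat = [FeatureSpec("ndvi", "ndvi", "raster_mean", "+")]
        bb = best_buffer_per_variable(noiseless_hourly, small_fm, cat, "day")
        assert not bool(bb.loc["ndvi", "direction_ok"])
        assert bb.loc["ndvi", "r"] < 0

    def test_uncorrelated_variable_has_small_r(self, noiseless_hourly, small_fm):
        bb = best_buffer_per_variable(noiseless_hourly, small_fm, period="day")
        # dem never enters the truth; |r| should be modest relative to active vars
        assert abs(bb.loc["dem", "r"]) < abs(bb.loc["major_road_length", "r"])


class TestForwardStepwise:
    def test_noiseless_truth_selected_exactly(self, noiseless_hourly, small_fm):
        model = forward_stepwise(noiseless_hourly, small_fm, period="day")
        assert set(model.variables) == {"major_road_length_100", "ndvi_50"}
        assert any("add" in line for line in model.selection_trace)

    def test_inert_candidates_give_intercept_only_model(
        self, small_city, small_sites, small_fm
    ):
        flat = TruthModel(
            betas={}, sigma_site=0.0, sigma_resid=0.0, event_rate=0.0
        )
        minutes = simulate_minute_levels(
            small_city, small_sites, flat, days_per_site=1, seed=5,
            features=small_fm.values(),
        )
        hourly = acoustics.hourly_levels(minutes)
        model = forward_stepwise(hourly, small_fm, period="day")
        assert model.variables == []

    def test_duplicated_columns_only_one_enters(self, noiseless_hourly, small_fm):
        fm = small_fm
        dup = fm.table.copy()
        dup["major_road_length_dup_100"] = dup["major_road_length_100"]
        cat = list(fm.catalogue) + [
            FeatureSpec("major_road_length_dup", "roads", "length_sum", "+", "major")
        ]
        fm2 = type(fm)(dup, cat, fm.buffers, fm.params, fm.raw_columns, fm.dropped_columns)
        model = forward_stepwise(noiseless_hourly, fm2, cat, period="day")
        sel = set(model.variables)
        assert not {"major_road_length_100", "major_road_length_dup_100"} <= sel
        assert any("collinearity" in line for line in model.selection_trace)

    def test_r2_never_decreases_along_accepted_adds(self, small_hourly, small_fm):
        model = forward_stepwise(small_hourly, small_fm, period="day")
        gains = [
            line for line in model.selection_trace if line.startswith("add ")
        ]
        r2s = [float(line.rsplit("-> ", 1)[1]) for line in gains]
        assert all(b >= a for a, b in zip(r2s, r2s[1:]))

    def test_selection_deterministic(self, small_hourly, small_fm):
        m1 = forward_stepwise(small_hourly, small_fm, period="day")
        m2 = forward_stepwise(small_hourly, small_fm, period="day")
        assert m1.variables == m2.variables
        assert m1.coefficients == m2.coefficients


class TestStabilityRule:
    @pytest.mark.parametrize(
        "coef, ci, dropped",
        [
            (0.8, (-0.4, 2.0), False),  # wide but |t| >= 1: retained
            (0.1, (-2.0, 2.2), True),  # tiny effect, huge CI: dropped
            (2.5, (1.2, 3.7), False),  # CI clear of zero: retained
            (-0.9, (-2.1, 0.3), False),  # crosses zero, |t| ~ 1.5: retained
        ],
    )
    def test_rule_applications(self, coef, ci, dropped):
        assert is_unstable(coef, ci) is dropped

    def test_prune_refits_after_dropping(self, small_hourly, small_fm):
        model = fit_mixed(
            small_hourly, small_fm,
            ["major_road_length_100", "ndvi_50", "dem_500"], "day",
        )
        pruned = stability_prune(model, small_hourly, small_fm)
        assert set(pruned.variables) <= set(model.variables)
        for var in pruned.variables:
            assert not is_unstable(pruned.coefficients[var], pruned.conf_ints[var])


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self, small_fm):
        fm = small_fm
        tbl = fm.table.copy()
        rng = np.random.default_rng(0)
        n = len(tbl)
        tbl["ortho_a"] = np.tile([1.0, -1.0], n // 2 + 1)[:n]
        tbl["ortho_b"] = np.repeat([1.0, -1.0], n // 2 + 1)[:n]
        fm2 = type(fm)(tbl, fm.catalogue, fm.buffers, fm.params, fm.raw_columns)
        out = vif(fm2, ["ortho_a", "ortho_b"])
        for v in out.values():
            assert v == pytest.approx(1.0, abs=0.1)

    def test_near_duplicate_blows_up(self, small_fm):
        fm = small_fm
        tbl = fm.table.copy()
        rng = np.random.default_rng(1)
        tbl["near_copy"] = tbl["ndvi_50"] + rng.normal(0, 1e-4, len(tbl))
        fm2 = type(fm)(tbl, fm.catalogue, fm.buffers, fm.params, fm.raw_columns)
        out = vif(fm2, ["ndvi_50", "near_copy"])
        assert out["near_copy"] > 10

    def test_selected_set_vifs_finite(self, small_hourly, small_fm):
        model = forward_stepwise(small_hourly, small_fm, period="day")
        if len(model.variables) >= 2:
            out = vif(small_fm, model.variables)
            assert all(np.isfinite(v) for v in out.values())


class TestIrModels:
    def test_constant_ir_gives_intercept_only(self, small_fm, small_sites):
        frame = sites_frame(small_sites)
        tab = pd.DataFrame(
            {
                "site_id": frame["site_id"],
                "ir_day": 40.0,
                "ir_night": 40.0,
                "l_day": 60.0,
                "l_night": 55.0,
            }
        )
        models = fit_ir_models(tab, small_fm)
        assert models["day"].variables == []

    def test_event_rate_gradient_signs_recovered(
        self, small_city, small_sites, small_fm
    ):
        """Sites with more events show higher IR; road length lowers IR by
        raising the steady background. Both signs must be recovered."""
        import pandas as pd

        frames = []
        rng = np.random.default_rng(12)
        rates = {}
        for i, site in enumerate(small_sites):
            rate = 0.5 + 5.0 * rng.random()
            rates[site.id] = rate
            truth = TruthModel(
                betas={"major_road_length_100": 3.0},
                sigma_site=0.0,
                sigma_resid=1.0,
                event_rate=rate,
                event_gain_dba=12.0,
            )
            frames.append(
                simulate_minute_levels(
                    small_city, [site], truth, days_per_site=2, seed=300 + i,
                    features=small_fm.values(),
                )
            )
        minutes = pd.concat(frames, ignore_index=True)
        table = acoustics.site_metrics_table(minutes)
        # IR must increase with the underlying event rate...
        merged = table.assign(rate=table["site_id"].map(rates))
        assert np.corrcoef(merged["rate"], merged["ir_day"])[0, 1] > 0.5
        # ...and decrease with steady-traffic road length
        road = small_fm.table.loc[table["site_id"], "major_road_length_100"]
        assert np.corrcoef(road, table["ir_day"])[0, 1] < 0

    def test_single_class_interaction_dropped_with_warning(self, small_fm, small_sites):
        frame = sites_frame(small_sites)
        rng = np.random.default_rng(3)
        l_day = rng.uniform(55, 70, len(frame))
        tab = pd.DataFrame(
            {
                "site_id": frame["site_id"],
                "ir_day": 10 + 2.0 * (l_day - 60) + rng.normal(0, 1, len(frame)),
                "ir_night": rng.uniform(20, 60, len(frame)),
                "l_day": l_day,
                "l_night": rng.uniform(45, 60, len(frame)),
            }
        )
        one_class = pd.Series("other", index=frame["site_id"])
        with pytest.warns(UserWarning, match="single land-use class"):
            models = fit_ir_models(tab, small_fm, land_use_class=one_class)
        assert models["day"].interaction_terms == []


class TestSiteMeans:
    def test_site_mean_levels_are_energetic(self, small_hourly):
        means = site_mean_levels(small_hourly, "day")
        site = small_hourly["site_id"].iloc[0]
        sub = filter_period(small_hourly[small_hourly["site_id"] == site], "day")
        expect = 10 * np.log10(np.mean(10 ** (sub["laeq_1hr_dba"] / 10)))
        assert means[site] == pytest.approx(expect, abs=1e-9)
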