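"""EA overlay, exposure binning conservation, and SES inequality statistics."""

import numpy as np
import pandas as pd
import pytest
import shapely

from noiselur.exposure import (
    assign_quintiles,
    ea_average,
    exposure_distribution,
    fisher_ci,
    ses_inequality,
)
from noiselur.geo import GridSpec, VectorLayer
from noiselur.surfaces import METRIC_NAMES, NoiseSurface


def flat_surface(value=60.0, n=6, cell=100.0):
    grid = GridSpec((0.0, 0.0), cell, n, n)
    mask = np.ones((n, n), dtype=bool)
    hourly = np.full((24, n, n), value)
    metrics = {name: np.full((n, n), value) for name in METRIC_NAMES}
    return NoiseSurface(grid, mask, hourly, metrics)


def ea_layer(boxes, populations, ses=None):
    n = len(boxes)
    ses = ses if ses is not None else np.linspace(7.0, 9.0, n)
    return VectorLayer(
        [shapely.box(*b) for b in boxes],
        pd.DataFrame(
            {
                "ea_id": [f"EA{i:03d}" for i in range(n)],
                "population": populations,
                "ses_consumption": ses,
                "ses_education": (np.asarray(populations) * 0.2).astype(int),
                "ses_unemployed": (np.asarray(populations) * 0.1).astype(int),
            }
        ),
    )


class TestEaAverage:
    def test_constant_surface_gives_constant_means(self):
        surf = flat_surface(60.0)
        eas = ea_layer([(0, 0, 300, 600), (300, 0, 600, 600)], [100, 200])
        out = ea_average(surf, eas)
        assert np.allclose(out["l_den"], 60.0)
        assert (out["n_cells"] > 0).all()

    def test_two_cell_hand_mean(self):
        surf = flat_surface(60.0, n=2, cell=100.0)
        for name in METRIC_NAMES:
            surf.metrics[name] = np.array([[58.0, 62.0], [58.0, 62.0]])
        eas = ea_layer([(0, 0, 200, 200)], [100])
        out = ea_average(surf, eas)
        assert out.loc[0, "l_den"] == pytest.approx(60.0, abs=1e-12)

    def test_checkerboard_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        n = 8
        surf = flat_surface(0.0, n=n, cell=50.0)
        vals = np.where(np.indices((n, n)).sum(axis=0) % 2 == 0, 55.0, 65.0)
        for name in METRIC_NAMES:
            surf.metrics[name] = vals.astype(float)
        boxes = [(0, 0, 200, 400), (200, 0, 400, 400)]
        eas = ea_layer(boxes, [10, 20])
        out = ea_average(surf, eas).set_index("ea_id")

        gx, gy = surf.grid.cell_centers()
        for i, b in enumerate(boxes):
            inside = (gx >= b[0]) & (gx <= b[2]) & (gy >= b[1]) & (gy <= b[3])
            expect = vals[inside].mean()
            assert out.loc[f"EA{i:03d}", "l_den"] == pytest.approx(expect, abs=1e-9)

    def test_uncovered_ea_flagged_missing(self):
        surf = flat_surface(60.0, n=2, cell=100.0)
        eas = ea_layer([(0, 0, 200, 200), (5000, 5000, 5100, 5100)], [50, 60])
        out = ea_average(surf, eas)
        assert out.loc[1, "n_cells"] == 0
        assert np.isnan(out.loc[1, "l_den"])

    def test_energetic_variant_dominates_arithmetic(self):
        surf = flat_surface(60.0, n=2, cell=100.0)
        for name in METRIC_NAMES:
            surf.metrics[name] = np.array([[50.0, 70.0], [50.0, 70.0]])
        eas = ea_layer([(0, 0, 200, 200)], [100])
        arith = ea_average(surf, eas).loc[0, "l_den"]
        energ = ea_average(surf, eas, energetic=True).loc[0, "l_den"]
        assert energ > arith  # Jensen


class TestExposureDistribution:
    def test_hand_binning_example(self):
        # pop 100 at 61 dBA -> bin 60-64; pop 300 at 66 -> bin 65-69
        ea_levels = pd.DataFrame(
            {"ea_id": ["EA000", "EA001"], "l_den": [61.0, 66.0], "n_cells": [1, 1]}
        )
        eas = ea_layer([(0, 0, 1, 1), (1, 0, 2, 1)], [100, 300])
        out = exposure_distribution(ea_levels, eas, "l_den")
        bins = out.bins.set_index("bin_low")
        assert bins.loc[60.0, "population"] == 100
        assert bins.loc[65.0, "population"] == 300
        assert out.percent_above == 100.0
        assert out.total_population == 400

    def test_population_conserved_across_bins(self, small_city):
        rng = np.random.default_rng(1)
        eas = small_city.eas
        ea_levels = pd.DataFrame(
            {
                "ea_id": eas.attributes["ea_id"],
                "l_den": rng.uniform(50, 75, len(eas)),
                "n_cells": 1,
            }
        )
        out = exposure_distribution(ea_levels, eas, "l_den")
        assert out.bins["population"].sum() == eas.attributes["population"].sum()
        assert (np.diff(out.cumulative["cum_share"]) >= -1e-12).all()

    def test_all_below_threshold_gives_zero_exceedance(self):
        ea_levels = pd.DataFrame(
            {"ea_id": ["EA000", "EA001"], "l_den": [40.0, 45.0], "n_cells": [1, 1]}
        )
        eas = ea_layer([(0, 0, 1, 1), (1, 0, 2, 1)], [10, 20])
        out = exposure_distribution(ea_levels, eas, "l_den")
        assert out.percent_above == 0.0

    def test_missing_level_ea_excluded(self):
        ea_levels = pd.DataFrame(
            {"ea_id": ["EA000", "EA001"], "l_den": [61.0, np.nan], "n_cells": [1, 0]}
        )
        eas = ea_layer([(0, 0, 1, 1), (1, 0, 2, 1)], [100, 300])
        out = exposure_distribution(ea_levels, eas, "l_den")
        assert out.total_population == 100


class TestQuintiles:
    def test_sizes_differ_by_at_most_one(self):
        for n in (10, 12, 23, 100):
            q = assign_quintiles(pd.Series(np.arange(n, dtype=float)))
            counts = q.value_counts()
            assert counts.max() - counts.min() <= 1
            assert set(q) == {1, 2, 3, 4, 5}

    def test_monotone_relabeling_keeps_assignment(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=37))
        a = assign_quintiles(x)
        b = assign_quintiles(np.exp(3 * x) + 5)  # strictly increasing transform
        pd.testing.assert_series_equal(a, b)

    def test_constant_measure_rejected(self):
        with pytest.raises(ValueError):
            assign_quintiles(pd.Series([1.0] * 20))


class TestFisherCi:
    def test_closed_form_reproduced(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            r = float(rng.uniform(-0.95, 0.95))
            lo, hi = fisher_ci(r, n)
            half = 1.959963984540054 / np.sqrt(n - 3)
            assert lo == pytest.approx(np.tanh(np.arctanh(r) - half), abs=1e-9)
            assert hi == pytest.approx(np.tanh(np.arctanh(r) + half), abs=1e-9)
            assert lo <= r <= hi

    def test_hand_dataset_matches_textbook_formula(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(0, 0.8, 12)
        r = float(np.corrcoef(x, y)[0, 1])
        lo, hi = fisher_ci(r, 12)
        assert lo == pytest.approx(np.tanh(np.arctanh(r) - 1.96 / 3), abs=1e-3)
        assert hi == pytest.approx(np.tanh(np.arctanh(r) + 1.96 / 3), abs=1e-3)


class TestSesInequality:
    def _levels(self, eas, noise_sd=0.0, slope=-3.0, seed=0):
        rng = np.random.default_rng(seed)
        ses = eas.attributes["ses_consumption"].to_numpy()
        lden = 65.0 + slope * (ses - ses.mean()) + rng.normal(0, noise_sd, len(ses))
        return pd.DataFrame(
            {
                "ea_id": eas.attributes["ea_id"],
                "l_den": lden,
                "l_night": lden - 7.0,
                "n_cells": 1,
            }
        )

    def _eas(self, n=25, seed=3):
        rng = np.random.default_rng(seed)
        boxes = [(i * 10, 0, i * 10 + 10, 10) for i in range(n)]
        return ea_layer(boxes, rng.integers(500, 1000, n), ses=rng.normal(8, 0.5, n))

    def test_negative_dependence_detected(self):
        eas = self._eas()
        res = ses_inequality(self._levels(eas, noise_sd=0.5), eas, "consumption")
        r = res.correlations.set_index("metric").loc["l_den", "r"]
        assert r < -0.8
        qs = res.quintile_summary.set_index("quintile")
        assert qs.loc[1, "l_den_median"] > qs.loc[5, "l_den_median"]
        assert res.welch.set_index("metric").loc["l_den", "p"] < 0.05

    def test_independent_ses_covers_zero(self):
        cover = 0
        n_rep = 40
        for rep in range(n_rep):
            eas = self._eas(seed=100 + rep)
            levels = self._levels(eas, noise_sd=3.0, slope=0.0, seed=200 + rep)
            res = ses_inequality(levels, eas, "consumption")
            row = res.correlations.set_index("metric").loc["l_den"]
            cover += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert cover >= int(0.85 * n_rep)

    def test_too_few_eas_rejected(self):
        eas = self._eas(n=5)
        with pytest.raises(ValueError):
            ses_inequality(self._levels(eas), eas, "consumption")

    def test_unknown_measure_rejected(self):
        eas = self._eas()
        with pytest.raises(ValueError):
            ses_inequality(self._levels(eas), eas, "wealth")


class TestPlots:
    def test_figures_written_to_disk(self, tmp_path):
        from noiselur.exposure import (
            plot_cumulative_exposure,
            plot_quintile_distributions,
        )

        rng = np.random.default_rng(0)
        n = 25
        boxes = [(i * 10, 0, i * 10 + 10, 10) for i in range(n)]
        eas = ea_layer(boxes, rng.integers(500, 1000, n), ses=rng.normal(8, 0.5, n))
        lden = rng.uniform(55, 75, n)
        levels = pd.DataFrame(
            {
                "ea_id": eas.attributes["ea_id"],
                "l_den": lden,
                "l_night": lden - 7,
                "n_cells": 1,
            }
        )
        summaries = [
            exposure_distribution(levels, eas, m) for m in ("l_den", "l_night")
        ]
        ineq = ses_inequality(levels, eas, "consumption")
        p1, p2 = tmp_path / "cum.png", tmp_path / "quint.png"
        plot_cumulative_exposure(summaries, p1)
        plot_quintile_distributions(ineq, levels, p2)
        assert p1.stat().st_size > 0 and p2.stat().st_size > 0
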