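"""Rainfall fields, zone classification, density grids and zonal summaries."""

import numpy as np
import pandas as pd
import pytest

from sahelcarbon import geo
from sahelcarbon.geo import (
    NODATA,
    OUT_OF_DOMAIN,
    RainfallField,
    ZoneDefinition,
    carbon_density_grid,
    classify_zone,
    classify_zones,
    extract_rainfall,
    mean_annual_rainfall,
    zonal_summary,
    zone_land_areas,
)


def field(grid, cell=100.0, x0=0.0, y0=None):
    grid = np.asarray(grid, dtype=float)
    y0 = y0 if y0 is not None else grid.shape[0] * cell
    return RainfallField(grid=grid, x_origin=x0, y_origin=y0, cell_size=cell)


class TestMeanAnnualRainfall:
    def test_constant_years(self):
        stack = np.full((3, 4, 5), 300.0)
        np.testing.assert_allclose(mean_annual_rainfall(stack), 300.0)

    def test_two_annual_grids(self):
        stack = np.stack([np.full((2, 2), 100.0), np.full((2, 2), 300.0)])
        np.testing.assert_allclose(mean_annual_rainfall(stack), 200.0)

    def test_monthly_sum_then_mean(self):
        stack = np.full((12, 2, 2), 10.0)
        np.testing.assert_allclose(mean_annual_rainfall(stack, monthly=True), 120.0)

    def test_incomplete_year_names_missing_months(self):
        with pytest.raises(ValueError, match="5 missing"):
            mean_annual_rainfall(np.full((7, 2, 2), 1.0), monthly=True)

    def test_nodata_propagates(self):
        stack = np.full((2, 2, 2), 100.0)
        stack[1, 0, 0] = NODATA
        out = mean_annual_rainfall(stack)
        assert out[0, 0] == NODATA and out[1, 1] == 100.0


class TestExtractRainfall:
    def test_cell_centre_identity(self):
        f = field([[100.0, 300.0], [500.0, 700.0]])
        # centre of top-left cell: (50, 150) with y_origin=200
        assert extract_rainfall(f, [(50.0, 150.0)])[0] == pytest.approx(100.0)

    def test_linear_midpoint(self):
        f = field([[100.0, 300.0]])
        assert extract_rainfall(f, [(100.0, 50.0)])[0] == pytest.approx(200.0)

    def test_outside_bounds_is_nodata(self):
        f = field([[100.0, 300.0]])
        assert extract_rainfall(f, [(-10.0, 50.0)])[0] == NODATA

    def test_nodata_neighbour_is_nodata(self):
        f = field([[100.0, NODATA]])
        assert extract_rainfall(f, [(100.0, 50.0)])[0] == NODATA

    def test_translation_by_whole_cells_is_invariant(self):
        grid = np.linspace(0, 999, 50).reshape(5, 10)
        f1 = field(grid)
        f2 = RainfallField(grid=grid, x_origin=300.0, y_origin=f1.y_origin + 200.0,
                           cell_size=100.0)
        pts = np.array([[123.0, 77.0], [456.0, 321.0]])
        shifted = pts + np.array([300.0, 200.0])
        v1 = extract_rainfall(f1, pts)
        v2 = extract_rainfall(f2, shifted)
        np.testing.assert_allclose(v1, v2)
        assert list(classify_zones(v1)) == list(classify_zones(v2))


class TestClassifyZone:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.0, "hyper-arid"),
            (100.0, "hyper-arid"),
            (149.999, "hyper-arid"),
            (150.0, "arid"),
            (299.999, "arid"),
            (300.0, "semi-arid"),
            (600.0, "sub-humid"),
            (1000.0, "sub-humid"),
            (1000.001, OUT_OF_DOMAIN),
            (1200.0, OUT_OF_DOMAIN),
        ],
    )
    def test_boundaries(self, p, expected):
        assert classify_zone(p) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_zone(-1.0)

    def test_vectorised_agrees_with_scalar(self):
        ps = np.array([0.0, 149.999, 150.0, 599.0, 1000.0, 1500.0])
        assert list(classify_zones(ps)) == [classify_zone(p) for p in ps]

    def test_bad_zone_definition_rejected(self):
        with pytest.raises(ValueError):
            ZoneDefinition(names=("a", "b"), bounds=(0.0, 100.0))
        with pytest.raises(ValueError):
            ZoneDefinition(names=("a", "b"), bounds=(0.0, 100.0, 50.0))


class TestDensityGrid:
    def test_single_tree_unit_conversion(self):
        crowns = pd.DataFrame({"id": [0], "x": [50.0], "y": [50.0],
                               "carbon_kg": [47.0]})
        grid, _, _ = carbon_density_grid(crowns, (0, 0, 100, 100), cell_size=100.0)
        assert grid.shape == (1, 1)
        assert grid[0, 0] == pytest.approx(0.047)

    def test_empty_landscape_all_zero(self):
        grid, _, _ = carbon_density_grid(pd.DataFrame(), (0, 0, 300, 200))
        assert grid.shape == (2, 3) and not grid.any()

    def test_conservation(self):
        rng = np.random.default_rng(1)
        crowns = pd.DataFrame({
            "id": range(500),
            "x": rng.uniform(0, 1000, 500),
            "y": rng.uniform(0, 500, 500),
            "carbon_kg": rng.uniform(1, 100, 500),
        })
        grid, _, _ = carbon_density_grid(crowns, (0, 0, 1000, 500), cell_size=100.0)
        cell_ha = 1.0
        assert grid.sum() * cell_ha * 1000.0 == pytest.approx(
            crowns.carbon_kg.sum(), rel=1e-9
        )

    def test_split_across_cells_reaggregates(self):
        """Moving a tree within the pair of cells conserves the 2-cell total."""
        base = {"id": [0, 1], "y": [50.0, 50.0], "carbon_kg": [40.0, 60.0]}
        together = pd.DataFrame({**base, "x": [40.0, 60.0]})
        split = pd.DataFrame({**base, "x": [40.0, 160.0]})
        g1, _, _ = carbon_density_grid(together, (0, 0, 200, 100))
        g2, _, _ = carbon_density_grid(split, (0, 0, 200, 100))
        assert g1.sum() == pytest.approx(g2.sum(), rel=1e-12)

    def test_missing_estimates_named(self):
        crowns = pd.DataFrame({"id": [3], "x": [1.0], "y": [1.0],
                               "carbon_kg": [np.nan]})
        with pytest.raises(ValueError, match="3"):
            carbon_density_grid(crowns, (0, 0, 100, 100))


class TestZonalSummary:
    @staticmethod
    def crowns_in_zone(carbons, zone="arid"):
        n = len(carbons)
        return pd.DataFrame({
            "id": range(n), "x": np.zeros(n), "y": np.zeros(n),
            "crown_area_m2": np.full(n, 10.0), "zone": zone,
            "carbon_kg": np.asarray(carbons, dtype=float),
        })

    def test_single_zone_mean(self):
        s = zonal_summary(self.crowns_in_zone([10.0, 30.0]))
        by = {z.zone: z for z in s}
        assert by["arid"].mean_carbon_kg == pytest.approx(20.0)
        assert by["arid"].carbon_share_pct == pytest.approx(100.0)
        assert by["hyper-arid"].n_trees == 0

    def test_percentile_definition(self):
        # linear interpolation between order statistics of {1..100}
        s = zonal_summary(self.crowns_in_zone(np.arange(1.0, 101.0)),
                          percentiles=(25,))
        by = {z.zone: z for z in s}
        assert by["arid"].carbon_percentiles_kg[25] == pytest.approx(25.75)

    def test_shares_sum_to_100(self, small_landscape):
        from sahelcarbon.allometry import add_carbon_estimates
        _, rainfall, crowns = small_landscape
        crowns = add_carbon_estimates(crowns)
        s = zonal_summary(crowns, zone_land_area_ha=zone_land_areas(rainfall))
        assert sum(z.carbon_share_pct for z in s) == pytest.approx(100.0, abs=0.01)

    def test_zone_means_increase_along_gradient(self, small_landscape):
        from sahelcarbon.allometry import add_carbon_estimates
        _, rainfall, crowns = small_landscape
        crowns = add_carbon_estimates(crowns)
        s = zonal_summary(crowns)
        means = [z.mean_carbon_kg for z in s if z.n_trees > 50]
        assert means == sorted(means)

    def test_requires_zone_column(self):
        with pytest.raises(ValueError):
            zonal_summary(pd.DataFrame({"carbon_kg": [1.0]}))


class TestConservationAcrossAggregations:
    def test_per_tree_per_cell_per_zone_agree(self, small_landscape):
        from sahelcarbon.allometry import add_carbon_estimates
        _, rainfall, crowns = small_landscape
        crowns = add_carbon_estimates(crowns)
        per_tree = crowns["carbon_kg"].sum()
        grid, _, _ = carbon_density_grid(crowns, rainfall.bounds, cell_size=100.0)
        per_cell = grid.sum() * 1.0 * 1000.0  # 1 ha cells, Mg -> kg
        per_zone = sum(z.total_carbon_kg for z in zonal_summary(crowns))
        assert per_cell == pytest.approx(per_tree, rel=1e-9)
        assert per_zone == pytest.approx(per_tree, rel=1e-9)
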