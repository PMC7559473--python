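import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from thermalsteps.covariates import (collinearity_screen, distance_to_water,
                                     solar_radiation_index, standardize,
                                     terrain_derivatives, validate_temperature,
                                     StandardizationRecord, annotate)
from thermalsteps.errors import ConfigurationError, DataError, DomainError, \
    SpecificationError
from thermalsteps.raster import RasterLayer


def layer(vals, cell=30.0):
    vals = np.asarray(vals, dtype=float)
    return RasterLayer(vals, origin_x=0, origin_y=vals.shape[0] * cell, cell_size=cell)


class TestDistanceToWater:
    def test_water_cells_have_zero_distance(self, rng):
        mask = (rng.uniform(size=(15, 15)) < 0.2).astype(float)
        mask[0, 0] = 1.0
        d = distance_to_water(layer(mask))
        assert (d.values[mask == 1] == 0).all()

    def test_corner_to_corner_diagonal(self):
        mask = np.zeros((3, 3))
        mask[0, 0] = 1.0
        d = distance_to_water(layer(mask))
        assert d.values[2, 2] == pytest.approx(2 * np.sqrt(2) * 30)

    def test_matches_brute_force_on_random_masks(self, rng):
        """Exhaustive all-pairs minimum distance is the oracle."""
        for _ in range(25):
            mask = (rng.uniform(size=(20, 20)) < 0.08).astype(float)
            if mask.sum() == 0:
                mask[int(rng.integers(20)), int(rng.integers(20))] = 1.0
            d = distance_to_water(layer(mask)).values
            rows, cols = np.indices(mask.shape)
            wr, wc = np.nonzero(mask)
            brute = np.sqrt(
                (rows[..., None] - wr) ** 2 + (cols[..., None] - wc) ** 2
            ).min(axis=-1) * 30.0
            np.testing.assert_allclose(d, brute, atol=1e-9)

    def test_no_water_raises(self):
        with pytest.raises(DomainError):
            distance_to_water(layer(np.zeros((5, 5))))


class TestTerrain:
    def test_flat_dem_has_zero_slope_everywhere(self):
        slope, aspect = terrain_derivatives(layer(np.full((6, 6), 250.0)))
        np.testing.assert_array_equal(slope, 0.0)
        assert np.isnan(aspect).all()

    def test_plane_slope_matches_analytic_gradient(self):
        cell = 30.0
        cols = np.arange(8) * cell
        dem = layer(np.tile(0.1 * cols, (8, 1)), cell)
        slope, _ = terrain_derivatives(dem)
        np.testing.assert_allclose(slope[2:-2, 2:-2], np.arctan(0.1), rtol=1e-9)

    def test_south_dipping_plane_has_south_aspect(self):
        cell = 30.0
        northing = np.arange(8)[::-1] * cell  # row 0 is northernmost
        dem = layer(np.tile(0.05 * northing[:, None], (1, 8)), cell)
        _, aspect = terrain_derivatives(dem)
        np.testing.assert_allclose(aspect[2:-2, 2:-2], np.pi, rtol=1e-9)

    def test_nodata_propagates_to_window(self):
        vals = np.full((5, 5), 100.0)
        vals[2, 2] = -9999.0
        slope, _ = terrain_derivatives(layer(vals))
        assert np.isnan(slope[1:4, 1:4]).all()
        assert np.isfinite(slope[0, 0])


def sri_quadrature(lat, slope, aspect):
    """Quadrature oracle from first principles of solar geometry: integrate
    the incidence cosine n . s over the hour angle at equinox, with the sun
    above the flat horizon and in front of the surface."""
    normal = np.array([
        np.sin(slope) * np.sin(aspect),     # east
        np.sin(slope) * np.cos(aspect),     # north
        np.cos(slope),                      # up
    ])

    def raw(h):
        sin_alpha = np.cos(lat) * np.cos(h)             # declination 0
        east = -np.sin(h)
        north = -np.sin(lat) * np.cos(h)
        return float(normal @ np.array([east, north, sin_alpha]))

    # locate sign changes of the (kinked) integrand so quad sees smooth pieces
    from scipy.optimize import brentq
    grid = np.linspace(-np.pi / 2, np.pi / 2, 2001)
    vals = np.array([raw(h) for h in grid])
    breaks = [-np.pi / 2]
    for i in np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:])):
        breaks.append(brentq(raw, grid[i], grid[i + 1], xtol=1e-14))
    breaks.append(np.pi / 2)

    total = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        piece, _ = quad(lambda h: max(0.0, raw(h)), a, b, limit=200)
        total += piece
    return total / (2 * np.pi)


class TestSolarRadiationIndex:
    def test_flat_surface_ignores_aspect(self):
        lat = np.deg2rad(65)
        vals = [solar_radiation_index(lat, 0.0, a) for a in np.linspace(0, 2 * np.pi, 7)]
        np.testing.assert_allclose(vals, vals[0])
        assert vals[0] == pytest.approx(np.cos(lat) / np.pi)

    def test_east_west_symmetry(self):
        lat, slope = np.deg2rad(55), np.deg2rad(25)
        east = solar_radiation_index(lat, slope, np.pi / 2)
        west = solar_radiation_index(lat, slope, 3 * np.pi / 2)
        assert east == pytest.approx(west, rel=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(100):
            lat = rng.uniform(-np.pi / 2, np.pi / 2)
            slope = rng.uniform(0, np.pi / 2)
            aspect = rng.uniform(0, 2 * np.pi)
            ours = solar_radiation_index(lat, slope, aspect)
            oracle = sri_quadrature(lat, slope, aspect)
            assert ours == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            solar_radiation_index(2.0, 0.1, 0.0)
        with pytest.raises(DomainError):
            solar_radiation_index(0.5, np.array([1.8]), np.array([0.0]))


class TestStandardize:
    def table(self, rng, n=400):
        return pd.DataFrame({
            "canopy_pct": rng.uniform(0, 100, n),
            "dist_water_m": rng.gamma(2, 200, n),
            "elevation_m": rng.normal(300, 120, n),
            "sri": rng.uniform(0, 0.5, n),
        })

    def test_standardized_sd_is_half(self, rng):
        out, record = standardize(self.table(rng))
        for col in out.columns:
            assert np.std(out[col], ddof=1) == pytest.approx(0.5, abs=1e-9)
            assert record.divisor(col) > 0

    def test_constant_column_raises_with_name(self, rng):
        t = self.table(rng)
        t["sri"] = 0.31
        with pytest.raises(ConfigurationError, match="sri"):
            standardize(t)

    def test_round_trip_via_stored_divisor(self, rng):
        t = self.table(rng)
        out, record = standardize(t)
        for col in t.columns:
            np.testing.assert_allclose(out[col] * record.divisor(col), t[col],
                                       atol=1e-12)

    def test_correlations_unchanged(self, rng):
        t = self.table(rng)
        t["elevation_m"] += 0.5 * t["canopy_pct"]
        out, _ = standardize(t)
        pd.testing.assert_frame_equal(out.corr(), t.corr(), atol=1e-12)

    def test_record_reuse_applies_training_scale(self, rng):
        train, test = self.table(rng), self.table(rng, n=100)
        _, record = standardize(train)
        out, _ = standardize(test, record=record)
        np.testing.assert_allclose(out["canopy_pct"] * record.divisor("canopy_pct"),
                                   test["canopy_pct"])


class TestCollinearityScreen:
    def test_duplicate_column_drops_lower_priority(self, rng):
        t = pd.DataFrame({"canopy_pct": rng.normal(size=300)})
        t["elevation_m"] = t["canopy_pct"] * 2.0
        retained, report = collinearity_screen(t, columns=["canopy_pct", "elevation_m"])
        assert retained == ["canopy_pct"]
        assert report.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert bool(report.loc[0, "dropped"])

    def test_water_retained_over_collinear_elevation(self, rng):
        dist = rng.gamma(2, 100, 500)
        t = pd.DataFrame({
            "dist_water_m": dist,
            "elevation_m": dist * 0.9 + rng.normal(0, 10, 500),
            "canopy_pct": rng.uniform(0, 100, 500),
        })
        retained, _ = collinearity_screen(t)
        assert "dist_water_m" in retained
        assert "elevation_m" not in retained

    def test_independent_covariates_all_retained(self, rng):
        t = pd.DataFrame(rng.normal(size=(10000, 4)),
                         columns=["canopy_pct", "dist_water_m", "elevation_m", "sri"])
        retained, report = collinearity_screen(t)
        assert len(retained) == 4
        assert (report["pearson_r"].abs() < 0.70).all()

    def test_unranked_conflict_demands_a_rule(self, rng):
        x = rng.normal(size=300)
        t = pd.DataFrame({"canopy_pct": x, "mystery": x * 1.0})
        with pytest.raises(SpecificationError):
            collinearity_screen(t, columns=["canopy_pct", "mystery"])


class TestValidateTemperature:
    def test_identical_series(self):
        x = np.linspace(5, 25, 50)
        r2, rmse = validate_temperature(x, x)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0)

    def test_constant_offset(self):
        x = np.linspace(5, 25, 50)
        r2, rmse = validate_temperature(x + 3.0, x)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(3.0)

    def test_noise_sets_rmse(self, rng):
        gridded = rng.uniform(5, 25, 5000)
        collar = gridded + rng.normal(0, 4.0, 5000)
        _, rmse = validate_temperature(collar, gridded)
        assert 3.8 <= rmse <= 4.2

    def test_zero_variance_gridded_rejected(self):
        with pytest.raises(DataError):
            validate_temperature(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))


class TestAnnotate:
    def test_exact_cell_center_identity_and_case_conservation(self):
        canopy = np.array([[10.0, 37.6, 20.0], [55.0, 90.0, 30.0], [5.0, 15.0, 25.0]])
        water = np.zeros((3, 3))
        water[2, 0] = 1.0
        dem = np.linspace(100, 180, 9).reshape(3, 3)
        from thermalsteps.raster import CovariateStack
        stack = CovariateStack(canopy=layer(canopy), water=layer(water),
                               elevation=layer(dem))
        strata = pd.DataFrame({
            "stratum_id": ["s0"] * 3,
            "animal_id": "m1", "animal_year": "m1-2015",
            "case": [1, 0, 0],
            "x": [45.0, 15.0, 45.0],
            "y": [75.0, 15.0, 15.0],
            "t": pd.Timestamp("2015-06-01"),
            "temperature_c": 12.0,
        })
        out = annotate(strata, stack)
        assert out.loc[out.case == 1, "canopy_pct"].iloc[0] == 37.6
        assert (out.groupby("stratum_id")["case"].sum() == 1).all()

    def test_stratum_with_offraster_member_dropped_whole(self, landscape):
        xmin, xmax, ymin, ymax = landscape.canopy.extent
        good = {"x": (xmin + xmax) / 2, "y": (ymin + ymax) / 2}
        strata = pd.DataFrame({
            "stratum_id": ["a", "a", "b", "b"],
            "animal_id": "m1", "animal_year": "m1-2015",
            "case": [1, 0, 1, 0],
            "x": [good["x"], xmax + 100, good["x"], good["x"] + 30],
            "y": [good["y"], good["y"], good["y"], good["y"]],
            "t": pd.Timestamp("2015-06-01"),
            "temperature_c": 12.0,
        })
        out = annotate(strata, landscape)
        assert set(out["stratum_id"]) == {"b"}
        assert out.attrs["n_dropped_strata"] == 1
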