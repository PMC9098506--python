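"""Habitat models, habitat-area metric, calibration, distribution area."""

import numpy as np
import pytest

from habcast import (
    BLUE_WHITING,
    BLUEFIN_TUNA,
    EARTH_RADIUS_KM,
    GridError,
    GridField,
    GridSpec,
    MACKEREL,
    RegionPolygon,
    SalinityWindowHabitatModel,
    calibrate_probability_threshold,
    cell_areas,
    core_distribution_area,
    habitat_area,
    larvae_probability,
    probability_area_curve,
    register_probability_model,
    salinity_window_suitability,
    solar_elevation,
    threshold_suitability,
)


class TestThresholdSuitability:
    @pytest.mark.parametrize("value,expected", [(9.0, 1.0), (8.5, 1.0), (8.49, 0.0)])
    def test_uniform_fields_with_inclusive_boundary(self, toy_grid, value, expected):
        f = GridField(toy_grid, "sst", np.full(toy_grid.shape, value))
        out = threshold_suitability(f, MACKEREL)
        assert np.all(out.values == expected)

    def test_random_field_matches_elementwise_comparison(self, toy_grid, rng):
        vals = rng.uniform(5, 15, toy_grid.shape)
        out = threshold_suitability(GridField(toy_grid, "sst", vals), BLUEFIN_TUNA)
        assert np.array_equal(out.values, (vals >= 11.0).astype(float))

    def test_mask_preserved(self, toy_grid):
        vals = np.full(toy_grid.shape, 12.0)
        vals[0, 0] = np.nan
        out = threshold_suitability(GridField(toy_grid, "sst", vals), MACKEREL)
        assert out.mask[0, 0]

    def test_variable_mismatch_rejected(self, toy_grid):
        f = GridField(toy_grid, "salinity", np.full(toy_grid.shape, 35.0))
        with pytest.raises(GridError, match="sst"):
            threshold_suitability(f, MACKEREL)


class TestSalinityWindow:
    @pytest.mark.parametrize("value,expected",
                             [(35.4, 1.0), (35.3, 1.0), (35.5, 1.0), (35.25, 0.0)])
    def test_closed_window(self, toy_grid, value, expected):
        f = GridField(toy_grid, "salinity", np.full(toy_grid.shape, value))
        assert np.all(salinity_window_suitability(f, BLUE_WHITING).values == expected)

    def test_linear_ramp_band_width_analytic(self):
        # salinity linear in longitude: S = 35.6 - 0.01 * (lon - lon0)
        grid = GridSpec.regular(50.0, 52.0, 0.0, 40.0, step=0.5)
        lon = grid.lon_centers[None, :] * np.ones((grid.shape[0], 1))
        sal = 35.6 - 0.01 * lon
        out = salinity_window_suitability(GridField(grid, "salinity", sal), BLUE_WHITING)
        # 35.3 <= S <= 35.5  <=>  10 <= lon <= 30: centres 10.25..29.75 = 40 columns
        per_row = out.values.sum(axis=1)
        assert np.all(per_row == 40)


class TestLarvaeProbability:
    def test_dome_maximal_at_window_centre(self):
        s = np.linspace(35.0, 35.8, 161)
        p = larvae_probability(55.0, 71, 1500.0, s, 10.0)
        assert s[np.argmax(p)] == pytest.approx(35.4, abs=1e-9)

    def test_dome_symmetric_about_centre(self):
        d = np.linspace(0, 0.2, 21)
        p_up = larvae_probability(55.0, 71, 1500.0, 35.4 + d, 10.0)
        p_dn = larvae_probability(55.0, 71, 1500.0, 35.4 - d, 10.0)
        assert np.allclose(p_up, p_dn, atol=1e-12)

    def test_shallow_bathymetry_excluded(self):
        assert larvae_probability(55.0, 71, 300.0, 35.4, 10.0) == 0.0
        assert larvae_probability(55.0, 71, 500.0, 35.4, 10.0) > 0.5

    def test_registered_model_clipped_to_unit_interval(self, rng):
        register_probability_model("wild", lambda la, d, b, s, e: 3.0 * np.sin(10 * s))
        model = SalinityWindowHabitatModel(probability_model="wild")
        s = rng.uniform(34, 36, 200)
        p = larvae_probability(rng.uniform(45, 65, 200), 71, 1500.0, s, 10.0, model)
        assert np.all((p >= 0) & (p <= 1))

    def test_unregistered_model_rejected(self):
        model = SalinityWindowHabitatModel(probability_model="nope")
        with pytest.raises(GridError, match="not registered"):
            larvae_probability(55.0, 71, 1500.0, 35.4, 10.0, model)


class TestSolarElevation:
    def test_equator_equinox_noon_near_zenith(self):
        # day 80 ~ March equinox; solar noon at lon 0
        assert solar_elevation(0.0, 80, hour_utc=12.0, lon=0.0) > 88.0

    def test_polar_night_negative_elevation(self):
        assert solar_elevation(80.0, 355, hour_utc=12.0, lon=0.0) < 0.0

    def test_against_independent_noaa_style_oracle(self, rng):
        def noaa_elevation(lat, doy, hour, lon):
            # NOAA general solar position algorithm (fractional-year form)
            g = 2 * np.pi / 365 * (doy - 1 + (hour - 12) / 24)
            decl = (
                0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
                - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
                - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g)
            )
            eqtime = 229.18 * (
                0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g)
            )
            tst = hour * 60 + eqtime + 4 * lon
            ha = np.radians(tst / 4 - 180)
            phi = np.radians(lat)
            cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
            return 90 - np.degrees(np.arccos(np.clip(cos_zen, -1, 1)))

        for _ in range(50):
            lat = rng.uniform(-80, 80)
            doy = rng.integers(1, 366)
            hour = rng.uniform(0, 24)
            lon = rng.uniform(-180, 180)
            ours = solar_elevation(lat, doy, hour_utc=hour, lon=lon)
            assert ours == pytest.approx(noaa_elevation(lat, doy, hour, lon), abs=0.5)


class TestHabitatArea:
    def test_all_suitable_whole_grid(self, toy_grid):
        ind = GridField(toy_grid, "indicator", np.ones(toy_grid.shape))
        region = RegionPolygon.from_vertices(
            "all", [(-30, 44), (-6, 44), (-6, 64), (-30, 64)]
        )
        areas = cell_areas(toy_grid)
        assert habitat_area(ind, region, areas) == pytest.approx(areas.sum())

    def test_none_suitable_is_zero(self, toy_grid):
        ind = GridField(toy_grid, "indicator", np.zeros(toy_grid.shape))
        region = RegionPolygon.from_vertices(
            "all", [(-30, 44), (-6, 44), (-6, 64), (-30, 64)]
        )
        assert habitat_area(ind, region) == 0.0

    def test_additive_over_disjoint_regions_and_bounded(self, toy_grid, rng):
        ind = GridField(toy_grid, "indicator",
                        (rng.uniform(size=toy_grid.shape) > 0.5).astype(float))
        south = RegionPolygon.from_vertices("s", [(-30, 44), (-6, 44), (-6, 54), (-30, 54)])
        north = RegionPolygon.from_vertices("n", [(-30, 54), (-6, 54), (-6, 64), (-30, 64)])
        both = RegionPolygon.from_vertices("b", [(-30, 44), (-6, 44), (-6, 64), (-30, 64)])
        areas = cell_areas(toy_grid)
        a_s = habitat_area(ind, south, areas)
        # the 54N edge: centres at 53/55 so no double counting occurs
        a_n = habitat_area(ind, north, areas)
        a_b = habitat_area(ind, both, areas)
        assert a_s + a_n == pytest.approx(a_b, rel=1e-12)
        assert a_b <= areas.sum() + 1e-9

    def test_isotherm_crossing_matches_spherical_zone(self):
        # SST linear in latitude, crossing 8.5 degC at exactly 55N; suitable
        # habitat is the zone south of 55N
        grid = GridSpec.regular(45.0, 65.0, -30.0, 0.0, step=0.5)
        lat = grid.lat_centers[:, None] * np.ones((1, grid.shape[1]))
        sst = 8.5 - 0.5 * (lat - 55.0)
        ind = threshold_suitability(GridField(grid, "sst", sst), MACKEREL)
        region = RegionPolygon.from_vertices(
            "all", [(-31, 44), (1, 44), (1, 66), (-31, 66)]
        )
        areas = cell_areas(grid)
        got = habitat_area(ind, region, areas)
        lam = np.radians(30.0)
        zone = EARTH_RADIUS_KM**2 * lam * (np.sin(np.radians(55.0)) - np.sin(np.radians(45.0)))
        one_row = areas[areas.shape[0] // 2, :].sum()
        assert abs(got - zone) <= one_row

    def test_monotone_under_warming(self, toy_grid, rng):
        region = RegionPolygon.from_vertices(
            "all", [(-30, 44), (-6, 44), (-6, 64), (-30, 64)]
        )
        areas = cell_areas(toy_grid)
        sst = rng.uniform(5, 12, toy_grid.shape)
        a0 = habitat_area(threshold_suitability(GridField(toy_grid, "sst", sst), MACKEREL),
                          region, areas)
        a1 = habitat_area(
            threshold_suitability(GridField(toy_grid, "sst", sst + 1.0), MACKEREL),
            region, areas,
        )
        assert a1 >= a0


class TestCalibration:
    def _curve_from_areas(self, habitat_areas_by_year):
        """Synthetic monotone curve: areas scale as (1 - t)."""
        def curve(t):
            return {y: a * (1.0 - t) for y, a in habitat_areas_by_year.items()}
        return curve

    def test_recovers_exact_match_threshold(self):
        base = {y: 1000.0 + 10 * (y % 7) for y in range(2000, 2012)}
        curve = self._curve_from_areas(base)
        observed = curve(0.5)
        assert calibrate_probability_threshold(curve, observed) == pytest.approx(0.5, abs=1e-9)

    def test_unattainable_observed_returns_boundary_with_warning(self):
        base = {y: 100.0 for y in range(2000, 2012)}
        curve = self._curve_from_areas(base)
        observed = {y: 1e6 for y in range(2000, 2012)}
        with pytest.warns(UserWarning, match="boundary"):
            assert calibrate_probability_threshold(curve, observed) == 0.0

    def test_monotone_in_observed_scale(self):
        base = {y: 1000.0 + 25 * (y % 5) for y in range(2000, 2015)}
        curve = self._curve_from_areas(base)
        t_small = calibrate_probability_threshold(curve, curve(0.7))
        t_large = calibrate_probability_threshold(
            curve, {y: 1.4 * v for y, v in curve(0.7).items()}
        )
        assert t_large <= t_small

    def test_no_overlapping_years_rejected(self):
        curve = self._curve_from_areas({2000: 10.0})
        with pytest.raises(GridError, match="overlap"):
            calibrate_probability_threshold(curve, {1990: 5.0})

    def test_roundtrip_recovery_from_probability_fields(self, rng):
        # probability fields with a known generative cutoff: observed areas are
        # the habitat areas at that cutoff; recovery within the grid step.
        # the field must sample probabilities finely enough that distinct
        # thresholds give distinct areas, hence the 40 x 40 grid
        grid = GridSpec.regular(50.0, 60.0, -20.0, -10.0, step=0.25)
        areas = cell_areas(grid)
        rmask = np.ones(grid.shape, dtype=bool)
        fields = {
            y: GridField(grid, "probability", rng.uniform(0, 1, grid.shape))
            for y in range(2000, 2015)
        }
        curve = probability_area_curve(fields, rmask, areas)
        true_cut = 0.37
        observed = curve(true_cut)
        got = calibrate_probability_threshold(curve, observed)
        assert got == pytest.approx(true_cut, abs=0.001 + 1e-9)


class TestCoreDistributionArea:
    def test_single_occupied_cell(self):
        ab = np.zeros((4, 5))
        ab[2, 3] = 7.0
        areas = np.full((4, 5), 100.0)
        assert core_distribution_area({2001: ab}, areas)[2001] == pytest.approx(100.0)

    def test_hundred_equal_cells_fraction_99(self):
        ab = np.ones((10, 10))
        areas = np.full((10, 10), 50.0)
        out = core_distribution_area({2001: ab}, areas, fraction=0.99)
        assert out[2001] == pytest.approx(99 * 50.0)

    def test_matches_brute_force_sort_and_accumulate(self, rng):
        areas = rng.uniform(50, 150, size=(6, 8))
        survey = {y: rng.gamma(0.6, 2.0, size=(6, 8)) for y in range(2000, 2006)}
        got = core_distribution_area(survey, areas, fraction=0.99)
        for y, ab in survey.items():
            pairs = sorted(zip(ab.ravel(), areas.ravel()), key=lambda p: -p[0])
            total = ab.sum()
            acc = area = 0.0
            for v, a in pairs:
                acc += v
                area += a
                if acc >= 0.99 * total - 1e-9 * total:
                    break
            assert got[y] == pytest.approx(area, rel=1e-12)

    def test_invariant_to_uniform_rescaling(self, rng):
        areas = rng.uniform(50, 150, size=(5, 5))
        ab = rng.gamma(1.0, 1.0, size=(5, 5))
        a1 = core_distribution_area({1: ab}, areas)[1]
        a2 = core_distribution_area({1: 123.4 * ab}, areas)[1]
        assert a1 == pytest.approx(a2)

    def test_all_zero_year_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero total"):
            out = core_distribution_area({1999: np.zeros((3, 3))}, np.ones((3, 3)))
        assert out[1999] == 0.0

    def test_negative_abundance_rejected(self):
        with pytest.raises(GridError, match="negative"):
            core_distribution_area({1: -np.ones((2, 2))}, np.ones((2, 2)))
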