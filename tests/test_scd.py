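"""Measurement grid, exclusion rule, SCD maps and manual-site analogs."""

import dataclasses

import numpy as np
import pytest

from varusscd import (MeasurementDomainError, TransepicondylarResult,
                      apply_lateral_exclusion, build_frame, build_grid,
                      compute_scd_map, extract_surfaces, generate_knee_like,
                      generate_wedge, manual_site_scd, manual_sites,
                      nearest_grid_to_sites, scd_compmean)
from varusscd.scd import REASON_INVALID, REASON_LATERAL, MeasurementGrid, SCDMap

from conftest import SMALL, SMALL_KNEE, measure_volume


def synthetic_surface(extent_x, extent_y, gap=8.0, cell=0.5):
    """Fully valid flat SurfaceField with exact footprint extents."""
    from varusscd.surfaces import SurfaceField
    nx = int(round(extent_x / cell)) + 1
    ny = int(round(extent_y / cell)) + 1
    xs = np.arange(nx) * cell
    ys = np.arange(ny) * cell
    t = np.zeros((nx, ny))
    f = np.full((nx, ny), gap)
    valid = np.ones((nx, ny), dtype=bool)
    return SurfaceField(xs=xs, ys=ys, tibia_height=t, femur_height=f,
                        valid=valid, interpolated=np.zeros_like(valid),
                        cell_mm=(cell, cell))


def simple_grid(xs, ys):
    shape = (len(xs), len(ys))
    return MeasurementGrid(np.asarray(xs, float), np.asarray(ys, float),
                           3.5, 3.3, np.ones(shape, dtype=bool),
                           np.full(shape, "", dtype=object),
                           (min(xs), max(xs), min(ys), max(ys)))


class TestBuildGrid:
    def test_point_counts_follow_floor_arithmetic(self):
        grid = build_grid(synthetic_surface(35.0, 33.0))
        assert (grid.xs.size, grid.ys.size) == (11, 11)
        grid = build_grid(synthetic_surface(34.9, 32.9, cell=0.1))
        assert (grid.xs.size, grid.ys.size) == (10, 10)

    def test_spacing_and_symmetric_margins(self):
        grid = build_grid(synthetic_surface(35.0, 33.0))
        np.testing.assert_allclose(np.diff(grid.xs), 3.5)
        np.testing.assert_allclose(np.diff(grid.ys), 3.3)
        x0, x1, *_ = grid.anchor_box
        assert grid.xs[0] - x0 == pytest.approx(x1 - grid.xs[-1])

    def test_rebuild_is_identical(self, knee_volume):
        fr = build_frame(knee_volume)
        surf = extract_surfaces(knee_volume, fr)
        a, b = build_grid(surf), build_grid(surf)
        np.testing.assert_array_equal(a.xs, b.xs)
        np.testing.assert_array_equal(a.ys, b.ys)

    def test_tiny_footprint_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="single"):
            grid = build_grid(synthetic_surface(2.0, 2.0))
        assert grid.n_points == 1


class TestLateralExclusion:
    def te(self, diameter, lateral_extreme):
        return TransepicondylarResult(np.array([1.0, 0, 0]), diameter,
                                      lateral_extreme,
                                      lateral_extreme - diameter)

    def test_rule_arithmetic(self):
        grid = simple_grid(np.linspace(0, 40, 21), [0.0])
        out = apply_lateral_exclusion(grid, self.te(80.0, 40.0))
        cut = 40.0 - 8.0
        for i, x in enumerate(out.xs):
            assert out.retained[i, 0] == (x <= cut)
            if not out.retained[i, 0]:
                assert out.reasons[i, 0] == REASON_LATERAL

    def test_entirely_medial_grid_untouched(self):
        grid = simple_grid([0.0, 5.0, 10.0], [0.0])
        out = apply_lateral_exclusion(grid, self.te(80.0, 100.0))
        assert out.n_retained == 3

    def test_matches_brute_force_filter_on_random_configurations(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            xs = np.sort(rng.uniform(-40, 40, size=rng.integers(2, 12)))
            ys = np.sort(rng.uniform(-30, 30, size=rng.integers(2, 10)))
            diameter = rng.uniform(20, 90)
            extreme = rng.uniform(-10, 50)
            frac = rng.uniform(0.0, 0.5)
            out = apply_lateral_exclusion(simple_grid(xs, ys),
                                          self.te(diameter, extreme), frac)
            cut = extreme - frac * diameter
            for i, x in enumerate(xs):
                for j in range(len(ys)):
                    assert out.retained[i, j] == (x <= cut)


class TestSCDMap:
    def test_flat_plate_map_is_constant(self, flat_volume, small_spec):
        smap, grid, fr, _ = measure_volume(flat_volume)
        np.testing.assert_allclose(smap.values[smap.retained],
                                   small_spec.gap_mm, atol=1e-9)
        assert scd_compmean(smap) == pytest.approx(small_spec.gap_mm)

    def test_wedge_map_matches_linear_profile(self):
        vol = generate_wedge(SMALL, gap_lateral_mm=10.0, gap_medial_mm=4.0)
        smap, grid, fr, _ = measure_volume(vol)
        w = vol.meta["wedge"]
        gx, _ = grid.points()
        true = w["intercept_mm"] + w["slope"] * (gx + fr.origin_mm[0])
        err = np.abs(smap.values - true)[smap.retained]
        assert err.max() <= SMALL.spacing_mm[2]

    def test_invalid_columns_masked_with_reason(self, flat_volume):
        fr = build_frame(flat_volume)
        surf = extract_surfaces(flat_volume, fr)
        grid = build_grid(surf)  # no exclusion: lateral rim points lack femur
        smap = compute_scd_map(surf, grid)
        masked = grid.retained & ~smap.retained
        assert masked.any()
        assert (smap.reasons[masked] == REASON_INVALID).all()

    def test_compmean_of_hand_built_map(self):
        grid = simple_grid([0.0, 3.5, 7.0], [0.0])
        values = np.array([[6.0], [8.0], [10.0]])
        smap = SCDMap(grid, values, grid.retained.copy(),
                      grid.reasons.copy())
        assert scd_compmean(smap) == pytest.approx(8.0)

    def test_all_points_invalid_raises(self):
        surf = synthetic_surface(20.0, 20.0)
        surf.valid[:] = False
        surf.femur_height[:] = np.nan
        grid = build_grid(synthetic_surface(20.0, 20.0))
        with pytest.raises(MeasurementDomainError):
            compute_scd_map(surf, grid)


class TestManualSites:
    def test_flat_plate_all_sites_equal_gap(self, flat_volume, small_spec):
        fr = build_frame(flat_volume)
        surf = extract_surfaces(flat_volume, fr)
        vals, mean, _ = manual_site_scd(surf)
        for name in ("ml1", "ml2", "ml3", "ap1", "ap2", "ap3"):
            assert vals[name] == pytest.approx(small_spec.gap_mm)
        assert mean == pytest.approx(small_spec.gap_mm)

    def test_wedge_orders_ml_sites_lateral_to_medial(self):
        vol = generate_wedge(SMALL, gap_lateral_mm=10.0, gap_medial_mm=4.0)
        fr = build_frame(vol)
        surf = extract_surfaces(vol, fr)
        vals, _, sites = manual_site_scd(surf)
        assert vals["ml1"] > vals["ml2"] > vals["ml3"]
        # ml1 is the most lateral site (+x)
        assert sites.coords["ml1"][0] > sites.coords["ml2"][0] \
            > sites.coords["ml3"][0]

    def test_site_geometry_conventions(self):
        sites = manual_sites(synthetic_surface(20.0, 10.0))
        ml_y = {sites.coords[n][1] for n in ("ml1", "ml2", "ml3")}
        ap_x = {sites.coords[n][0] for n in ("ap1", "ap2", "ap3")}
        assert len(ml_y) == 1 and len(ap_x) == 1
        assert sites.coords["ml2"][0] == pytest.approx(10.0)
        assert sites.coords["ap2"][1] == pytest.approx(5.0)


class TestNearestGrid:
    def test_exact_hit_and_tie_break(self):
        grid = simple_grid([0.0, 2.0], [0.0])
        from varusscd.scd import ManualSites
        hit = nearest_grid_to_sites(grid, ManualSites({"s": (2.0, 0.0)}))
        assert hit["s"]["x"] == 2.0 and hit["s"]["distance_mm"] == 0.0
        tie = nearest_grid_to_sites(grid, ManualSites({"s": (1.0, 0.0)}))
        assert tie["s"]["x"] == 0.0  # equidistant: smaller x wins

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            xs = np.sort(rng.uniform(-20, 20, size=rng.integers(2, 8)))
            ys = np.sort(rng.uniform(-20, 20, size=rng.integers(2, 8)))
            grid = simple_grid(xs, ys)
            drop = rng.random(grid.retained.shape) < 0.3
            grid.retained[drop] = False
            if not grid.retained.any():
                continue
            from varusscd.scd import ManualSites
            site = (rng.uniform(-25, 25), rng.uniform(-25, 25))
            got = nearest_grid_to_sites(grid, ManualSites({"s": site}))["s"]
            best = None
            for i, x in enumerate(xs):
                for j, y in enumerate(ys):
                    if not grid.retained[i, j]:
                        continue
                    d = (x - site[0]) ** 2 + (y - site[1]) ** 2
                    key = (round(d, 12), x, y)
                    if best is None or key < best:
                        best = key
            assert (got["x"], got["y"]) == (best[1], best[2])


class TestBaselineReferencing:
    def test_same_grid_reused_across_conditions(self):
        base = generate_knee_like(SMALL_KNEE)
        loaded = generate_knee_like(dataclasses.replace(SMALL_KNEE,
                                                        varus_angle_deg=2.0))
        m_ul, grid, fr, _ = measure_volume(base)
        m_lo = compute_scd_map(extract_surfaces(loaded, fr), grid)
        np.testing.assert_array_equal(m_ul.grid.xs, m_lo.grid.xs)
        np.testing.assert_array_equal(m_ul.grid.retained, m_lo.grid.retained)
        assert m_lo.n_retained > 0
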