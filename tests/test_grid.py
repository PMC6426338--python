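"""Grid container, block upscaling, bilinear resampling, QC and temporal means."""

import numpy as np
import pytest

from forestclim import (
    GeoGrid,
    QCRule,
    apply_qc,
    grid_to_table,
    read_netcdf,
    resample_bilinear,
    temporal_average,
    upscale_mean,
    write_netcdf,
)
from conftest import make_grid


class TestGeoGrid:
    def test_centers_follow_northwest_origin(self):
        g = make_grid(np.zeros((2, 3)), origin_lon=-60.0, origin_lat=0.0, res=0.5)
        assert g.lon_center(0) == pytest.approx(-59.75)
        assert g.lat_center(0) == pytest.approx(-0.25)
        assert g.lat_center(1) == pytest.approx(-0.75)  # rows run south

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GeoGrid(np.zeros((2, 2)), np.ones((2, 3), dtype=bool), 0, 0, 0.05)

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ValueError):
            GeoGrid(np.zeros((2, 2)), np.ones((2, 2), dtype=bool), 0, 0, 0.0)


class TestUpscaleMean:
    def test_single_block_mean(self):
        g = make_grid([[10, 20], [30, 40]])
        out = upscale_mean(g, 2)
        assert out.shape == (1, 1)
        assert out.values[0, 0] == pytest.approx(25.0)
        assert out.res == pytest.approx(0.1)

    @pytest.mark.parametrize("factor", [1, 2, 4])
    def test_constant_field_invariant(self, factor):
        g = make_grid(np.full((4, 4), 7.25))
        out = upscale_mean(g, factor)
        assert np.allclose(out.values, 7.25)

    def test_masked_cells_excluded_matches_block_enumeration(self, rng):
        vals = rng.normal(size=(4, 4))
        mask = np.ones((4, 4), dtype=bool)
        for i, j in [(0, 1), (2, 2), (3, 0)]:
            mask[i, j] = False
        g = make_grid(vals, mask)
        out = upscale_mean(g, 2)
        for bi in range(2):
            for bj in range(2):
                bv = vals[2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2]
                bm = mask[2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2]
                assert out.values[bi, bj] == pytest.approx(bv[bm].mean())

    def test_fully_masked_block_is_masked(self):
        mask = np.ones((2, 4), dtype=bool)
        mask[:, :2] = False
        out = upscale_mean(make_grid(np.ones((2, 4)), mask), 2)
        assert not out.mask[0, 0]
        assert out.mask[0, 1]

    def test_mean_conserved_without_masking(self, rng):
        vals = rng.normal(size=(6, 6))
        out = upscale_mean(make_grid(vals), 3)
        assert out.values.mean() == pytest.approx(vals.mean())

    def test_bad_factor_rejected(self):
        g = make_grid(np.ones((4, 4)))
        with pytest.raises(ValueError):
            upscale_mean(g, 0)
        with pytest.raises(ValueError):
            upscale_mean(g, 3)  # does not divide 4


class TestResampleBilinear:
    def test_constant_field_preserved(self):
        src = make_grid(np.full((5, 5), 3.5), res=0.1)
        target = make_grid(np.zeros((8, 8)), origin_lon=-59.9, origin_lat=-0.1, res=0.05)
        out = resample_bilinear(src, target)
        assert np.allclose(out.values[out.mask], 3.5)
        assert out.mask.any()

    def test_planar_field_reproduced_exactly(self):
        src = make_grid(np.zeros((6, 6)), res=0.1)
        lon, lat = np.meshgrid(src.lons, src.lats)
        src.values[:] = 2.0 * lon - 3.0 * lat + 1.0
        target = make_grid(np.zeros((10, 10)), origin_lon=-59.9, origin_lat=-0.1, res=0.04)
        out = resample_bilinear(src, target)
        tlon, tlat = np.meshgrid(target.lons, target.lats)
        expected = 2.0 * tlon - 3.0 * tlat + 1.0
        assert np.allclose(out.values[out.mask], expected[out.mask])

    def test_matches_textbook_formula(self, rng):
        """Interior target centers agree with the direct four-point formula."""
        src = make_grid(rng.normal(size=(5, 5)), res=0.2)
        target = make_grid(np.zeros((9, 9)), origin_lon=-59.95, origin_lat=-0.05, res=0.1)
        out = resample_bilinear(src, target)
        src_lons, src_lats = src.lons, src.lats
        for ti in range(9):
            for tj in range(9):
                if not out.mask[ti, tj]:
                    continue
                lon, lat = target.lon_center(tj), target.lat_center(ti)
                j0 = int(np.clip(np.searchsorted(src_lons, lon) - 1, 0, 3))
                # lats descend; use ascending copy for bracketing
                asc = src_lats[::-1]
                i0a = int(np.clip(np.searchsorted(asc, lat) - 1, 0, 3))
                la0, la1 = asc[i0a], asc[i0a + 1]
                lo0, lo1 = src_lons[j0], src_lons[j0 + 1]
                fy = (lat - la0) / (la1 - la0)
                fx = (lon - lo0) / (lo1 - lo0)
                v = src.values[::-1, :]
                expect = (
                    v[i0a, j0] * (1 - fx) * (1 - fy)
                    + v[i0a, j0 + 1] * fx * (1 - fy)
                    + v[i0a + 1, j0] * (1 - fx) * fy
                    + v[i0a + 1, j0 + 1] * fx * fy
                )
                assert out.values[ti, tj] == pytest.approx(expect, abs=1e-10)

    def test_output_within_local_bounds(self, rng):
        src = make_grid(rng.normal(size=(6, 6)), res=0.1)
        target = make_grid(np.zeros((11, 11)), origin_lon=-59.95, origin_lat=-0.05, res=0.05)
        out = resample_bilinear(src, target)
        assert out.values[out.mask].min() >= src.values.min() - 1e-12
        assert out.values[out.mask].max() <= src.values.max() + 1e-12

    def test_masked_neighbor_propagates_conservatively(self, rng):
        vals = rng.normal(size=(5, 5))
        mask = np.ones((5, 5), dtype=bool)
        mask[2, 2] = False
        src = make_grid(vals, mask, res=0.2)
        target = make_grid(np.zeros((9, 9)), origin_lon=-59.95, origin_lat=-0.05, res=0.1)
        out = resample_bilinear(src, target)
        # every target giving nonzero bilinear weight to (2,2) must be masked
        bad_lon = src.lon_center(2)
        bad_lat = src.lat_center(2)
        for ti in range(9):
            for tj in range(9):
                dlon = abs(target.lon_center(tj) - bad_lon)
                dlat = abs(target.lat_center(ti) - bad_lat)
                wlon = max(1.0 - dlon / src.res, 0.0)
                wlat = max(1.0 - dlat / src.res, 0.0)
                if wlon * wlat > 1e-9:
                    assert not out.mask[ti, tj]

    def test_degenerate_source_axis_rejected(self):
        src = make_grid(np.ones((1, 5)))
        with pytest.raises(ValueError):
            resample_bilinear(src, make_grid(np.zeros((3, 3))))


class TestApplyQC:
    def test_lst_error_above_threshold_masks_cell(self):
        vals = make_grid(np.full((2, 2), 20.0))
        emis = make_grid(np.full((2, 2), 0.01))
        err = make_grid([[1.0, 3.0], [1.0, 1.0]])
        out = apply_qc(vals, {"emissivity_error": emis, "lst_error": err}, QCRule("LST"))
        assert not out.mask[0, 1]
        assert out.mask[0, 0] and out.mask[1, 0] and out.mask[1, 1]
        assert np.allclose(out.values[out.mask], 20.0)  # values untouched

    def test_good_albedo_flags_leave_mask_unchanged(self):
        vals = make_grid(np.full((3, 3), 15.0))
        flags = make_grid(np.zeros((3, 3)))
        out = apply_qc(vals, {"flag": flags}, QCRule("albedo"))
        assert np.array_equal(out.mask, vals.mask)

    def test_albedo_flag_three_masked(self):
        vals = make_grid(np.full((2, 2), 15.0))
        flags = make_grid([[0, 1], [2, 3]])
        out = apply_qc(vals, {"flag": flags}, QCRule("albedo"))
        assert out.mask.sum() == 3 and not out.mask[1, 1]

    def test_incomplete_et_subpixels_masked(self):
        vals = make_grid(np.full((1, 2), 50.0))
        count = make_grid([[36.0, 35.0]])
        out = apply_qc(vals, {"valid_subpixels": count}, QCRule("ET"))
        assert out.mask[0, 0] and not out.mask[0, 1]

    def test_idempotent_and_mask_only_grows(self, rng):
        vals = make_grid(rng.normal(size=(4, 4)))
        err = make_grid(rng.uniform(0, 4, (4, 4)))
        emis = make_grid(np.full((4, 4), 0.01))
        layers = {"emissivity_error": emis, "lst_error": err}
        once = apply_qc(vals, layers, QCRule("LST"))
        twice = apply_qc(once, layers, QCRule("LST"))
        assert np.array_equal(once.mask, twice.mask)
        assert np.all(once.mask <= vals.mask)

    def test_missing_layer_rejected(self):
        vals = make_grid(np.ones((2, 2)))
        with pytest.raises(ValueError):
            apply_qc(vals, {}, QCRule("LST"))


class TestTemporalAverage:
    def test_identical_months_preserved(self):
        months = [make_grid(np.full((2, 2), 4.5)) for _ in range(12)]
        out = temporal_average(months, "monthly_to_annual")
        assert np.allclose(out.values, 4.5)

    def test_day_night_two_value_mean(self):
        day = make_grid(np.full((2, 2), 30.0))
        night = make_grid(np.full((2, 2), 20.0))
        out = temporal_average([(day, night)], "day_night_then_annual")
        assert np.allclose(out.values, 25.0)

    def test_hierarchical_differs_from_pooled_with_unequal_counts(self, rng):
        """Mean of monthly means, not mean over all composites."""
        jan = [make_grid(rng.normal(size=(2, 2))) for _ in range(4)]
        feb = [make_grid(rng.normal(size=(2, 2)))]
        stack = [("01", g) for g in jan] + [("02", g) for g in feb]
        out = temporal_average(stack, "eightday_to_monthly_to_annual")
        jan_mean = np.mean([g.values for g in jan], axis=0)
        expect = (jan_mean + feb[0].values) / 2.0
        pooled = np.mean([g.values for g in jan + feb], axis=0)
        assert np.allclose(out.values, expect)
        assert not np.allclose(out.values, pooled)

    def test_commutes_with_scalar_multiplication(self, rng):
        months = [make_grid(rng.normal(size=(3, 3))) for _ in range(5)]
        base = temporal_average(months, "monthly_to_annual")
        scaled = [make_grid(3.0 * g.values) for g in months]
        out = temporal_average(scaled, "monthly_to_annual")
        assert np.allclose(out.values, 3.0 * base.values)

    def test_any_valid_versus_require_all(self):
        a = make_grid([[1.0, 1.0]])
        b = make_grid([[3.0, 3.0]], mask=np.array([[True, False]]))
        any_valid = temporal_average([a, b], "monthly_to_annual")
        strict = temporal_average([a, b], "monthly_to_annual", require_all=True)
        assert any_valid.values[0, 1] == pytest.approx(1.0)
        assert any_valid.mask[0, 1]
        assert not strict.mask[0, 1]

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            temporal_average([], "monthly_to_annual")


class TestIO:
    def test_netcdf_roundtrip(self, tmp_path, rng):
        vals = rng.normal(size=(4, 6))
        mask = rng.random((4, 6)) > 0.2
        g = make_grid(vals, mask)
        path = tmp_path / "grids.nc"
        write_netcdf({"dF": g}, path)
        back = read_netcdf(path)["dF"]
        assert back.same_geometry(g)
        assert np.array_equal(back.mask, g.mask)
        assert np.allclose(back.values[back.mask], g.values[g.mask])

    def test_table_export_lists_valid_cells_only(self):
        mask = np.array([[True, False], [True, True]])
        g = make_grid([[1.0, 2.0], [3.0, 4.0]], mask)
        table = grid_to_table(g)
        assert len(table) == 3
        assert set(table.columns) == {"lon", "lat", "value"}
        assert 2.0 not in table["value"].values
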