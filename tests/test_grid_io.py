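"""Grid containers, area weights, unit conversion, regridding, integrals."""
import numpy as np
import pytest
import xarray as xr

import gppattrib as ga
from gppattrib.grid_io import DAYS_IN_MONTH, EARTH_RADIUS_M

from conftest import make_flux


class TestAreaWeights:
    def test_half_degree_equator_cell_closed_form(self):
        grid = ga.GridSpec(np.array([-0.25, 0.25]), np.array([0.0, 0.5]))
        w = ga.area_weights(grid)
        expect = (EARTH_RADIUS_M ** 2 * np.radians(0.5) *
                  2 * np.sin(np.radians(0.25)))
        assert w.shape == (1, 1)
        assert w[0, 0] == pytest.approx(expect, rel=1e-12)
        assert w[0, 0] == pytest.approx(3.091e9, rel=1e-3)

    def test_global_grid_sums_to_sphere_area(self):
        w = ga.area_weights(ga.GridSpec.regular(24, 48))
        assert w.sum() == pytest.approx(4 * np.pi * EARTH_RADIUS_M ** 2,
                                        rel=1e-6)

    def test_hemispheric_symmetry(self):
        w = ga.area_weights(ga.GridSpec.regular(10, 4))
        np.testing.assert_allclose(w, w[::-1, :])

    def test_monotone_edges_enforced(self):
        with pytest.raises(ValueError):
            ga.GridSpec(np.array([0.0, -1.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            ga.GridSpec(np.array([-91.0, 0.0]), np.array([0.0, 1.0]))


class TestUnitConversion:
    def _write(self, tmp_path, vals, units):
        grid = ga.GridSpec.regular(2, 3)
        da = ga.make_data_array(vals, grid, 1901)
        ds = xr.Dataset({"GPP": da})
        ds["GPP"].attrs["units"] = units
        ds.attrs.update(model_id="M0", experiment_id="SG1")
        path = str(tmp_path / "M0_SG1.nc")
        ds.to_netcdf(path)
        return path

    def test_kg_per_second_to_g_per_month(self, tmp_path):
        vals = np.ones((12, 2, 3))
        f = ga.read_flux(self._write(tmp_path, vals, "kg C m-2 s-1"))
        # January: 31 days -> 31*86400*1000 g C m-2 month-1
        assert f.values[0, 0, 0] == pytest.approx(2_678_400_000.0)
        expected = 1000.0 * 86400.0 * DAYS_IN_MONTH
        np.testing.assert_allclose(f.values[:, 1, 2], expected)

    def test_canonical_units_identity(self, tmp_path):
        vals = np.random.default_rng(0).uniform(0, 300, (12, 2, 3))
        f = ga.read_flux(self._write(tmp_path, vals, "g C m-2 month-1"))
        np.testing.assert_allclose(f.values, vals)

    def test_missing_units_is_hard_error(self, tmp_path):
        grid = ga.GridSpec.regular(2, 3)
        ds = xr.Dataset({"GPP": ga.make_data_array(np.ones((12, 2, 3)),
                                                   grid, 1901)})
        path = str(tmp_path / "x.nc")
        ds.to_netcdf(path)
        with pytest.raises(ValueError, match="GPP"):
            ga.read_flux(path)

    def test_write_read_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(1)
        f = make_flux(rng.uniform(0, 250, (24, 3, 4)), model_id="PM00",
                      experiment_id="SG3")
        path = str(tmp_path / "PM00_SG3.nc")
        ga.write_flux(f, path)
        g = ga.read_flux(path)
        np.testing.assert_array_equal(g.values, f.values)
        assert (g.model_id, g.experiment_id) == ("PM00", "SG3")


class TestRegrid:
    def test_constant_field_maps_to_constant(self):
        src = ga.GridSpec.regular(4, 8)
        tgt = ga.GridSpec.regular(8, 16)
        f = make_flux(np.full((12, 4, 8), 7.5), grid=src)
        out = ga.regrid(f, tgt, src)
        np.testing.assert_allclose(out.values, 7.5)

    def test_conserves_global_integral(self):
        src = ga.GridSpec.regular(6, 12)
        tgt = ga.GridSpec.regular(9, 20)   # non-nested refinement
        rng = np.random.default_rng(2)
        f = make_flux(rng.uniform(0, 100, (12, 6, 12)), grid=src)
        all_veg = ga.LandMask(np.ones((6, 12), bool), np.zeros((6, 12), bool),
                              np.zeros((6, 12), bool))
        tgt_veg = ga.LandMask(np.ones((9, 20), bool), np.zeros((9, 20), bool),
                              np.zeros((9, 20), bool))
        before = ga.global_integral(f, ga.area_weights(src), all_veg)
        after = ga.global_integral(ga.regrid(f, tgt, src),
                                   ga.area_weights(tgt), tgt_veg)
        np.testing.assert_allclose(after.values, before.values, rtol=1e-3)

    def test_identity_on_own_grid(self):
        src = ga.GridSpec.regular(4, 6)
        f = make_flux(np.random.default_rng(3).uniform(0, 50, (12, 4, 6)),
                      grid=src)
        out = ga.regrid(f, src, src)
        np.testing.assert_allclose(out.values, f.values, atol=1e-10)

    def test_disjoint_grids_error(self):
        src = ga.GridSpec(np.array([0.0, 10.0]), np.array([0.0, 10.0]))
        tgt = ga.GridSpec(np.array([40.0, 50.0]), np.array([90.0, 100.0]))
        f = make_flux(np.ones((12, 1, 1)), grid=src)
        with pytest.raises(ValueError):
            ga.regrid(f, tgt, src)


class TestGlobalIntegral:
    def _uniform_world(self, monthly_value):
        grid = ga.GridSpec.regular(12, 24)
        f = make_flux(np.full((12, 12, 24), monthly_value), grid=grid)
        mask = ga.LandMask(np.ones((12, 24), bool), np.zeros((12, 24), bool),
                           np.zeros((12, 24), bool))
        return f, ga.area_weights(grid), mask

    def test_uniform_field_closed_form(self):
        # 1000 g C m-2 a-1 over the whole sphere -> area * 1e3 * 1e-15 Pg C
        f, w, mask = self._uniform_world(1000.0 / 12.0)
        expect = 4 * np.pi * EARTH_RADIUS_M ** 2 * 1000.0 * 1e-15
        assert ga.global_integral(f, w, mask).values[0] == \
            pytest.approx(expect, rel=1e-9)

    def test_zero_field_and_linearity(self):
        f, w, mask = self._uniform_world(10.0)
        zero = make_flux(np.zeros_like(f.values), grid=ga.GridSpec.regular(12, 24))
        assert ga.global_integral(zero, w, mask).values[0] == 0.0
        doubled = make_flux(2 * f.values, grid=ga.GridSpec.regular(12, 24))
        np.testing.assert_allclose(ga.global_integral(doubled, w, mask).values,
                                   2 * ga.global_integral(f, w, mask).values)

    def test_all_masked_is_hard_error(self):
        f, w, _ = self._uniform_world(10.0)
        water = ga.LandMask(np.zeros((12, 24), bool), np.zeros((12, 24), bool),
                            np.ones((12, 24), bool))
        with pytest.raises(ValueError):
            ga.global_integral(f, w, water)

    def test_adding_vegetated_cells_is_monotone(self):
        f, w, mask = self._uniform_world(10.0)
        partial = mask.vegetated.copy()
        partial[: 6] = False
        m1 = ga.LandMask(partial, ~partial, np.zeros_like(partial))
        total_partial = ga.global_integral(f, w, m1).values[0]
        total_full = ga.global_integral(f, w, mask).values[0]
        assert total_full > total_partial


class TestFluxFieldInvariants:
    def test_small_negative_values_clipped(self):
        vals = np.zeros((12, 2, 2))
        vals[0, 0, 0] = -1e-10
        f = make_flux(vals)
        assert f.values[0, 0, 0] == 0.0

    def test_large_negative_values_rejected(self):
        vals = np.zeros((12, 2, 2))
        vals[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            make_flux(vals)

    def test_non_monthly_axis_rejected(self):
        grid = ga.GridSpec.regular(2, 2)
        da = ga.make_data_array(np.zeros((12, 2, 2)), grid, 1901)
        da = da.isel(time=[0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 1])
        with pytest.raises(ValueError):
            ga.FluxField(da)
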