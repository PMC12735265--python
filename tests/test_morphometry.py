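"""Isotherm extraction, caliper axes, warm zones, merge tracking."""

import numpy as np
import pytest

import cryosim as cs
from cryosim.morphometry import surface_volume


@pytest.fixture
def grid():
    return cs.SimulationGrid(spacing=1e-3, shape=(31, 31, 31),
                             origin=(-0.0155, -0.0155, -0.0155))


def radial_field(grid, scale=1e4, offset=-50.0):
    """T(r) = scale*r + offset: the 0 degC level set is a sphere."""
    c = grid.cell_centers()
    r = np.linalg.norm(c, axis=-1)
    return r * scale + offset


def ellipsoid_field(grid, a, b):
    """Negative inside an ellipsoid with semi-axes (b, b, a) along z."""
    c = grid.cell_centers()
    val = (c[..., 0] / b) ** 2 + (c[..., 1] / b) ** 2 + (c[..., 2] / a) ** 2
    return (val - 1.0) * 100.0


class TestExtractIsotherm:
    def test_synthetic_sphere_radius(self, grid):
        T = radial_field(grid)  # zero level at r = 5 mm
        region = cs.extract_isotherm_region(T, 0.0, grid)
        assert region.mask.sum() > 0
        r_verts = np.linalg.norm(region.verts, axis=1)
        assert abs(r_verts.mean() - 0.005) < grid.spacing
        # voxel and surface volumes agree near the analytic value
        vol_ref = 4.0 / 3.0 * np.pi * 0.005**3
        assert region.voxel_volume() == pytest.approx(vol_ref, rel=0.1)
        assert surface_volume(region) == pytest.approx(vol_ref, rel=0.05)

    def test_all_warm_empty(self, grid):
        region = cs.extract_isotherm_region(np.full(grid.shape, 37.0), 0.0, grid)
        assert region.is_empty
        assert region.voxel_volume() == 0.0

    def test_all_cold_whole_domain(self, grid):
        region = cs.extract_isotherm_region(np.full(grid.shape, -50.0), 0.0, grid)
        assert region.mask.all()
        assert region.voxel_volume() == pytest.approx(
            grid.n_cells * grid.spacing**3
        )

    def test_nonfinite_rejected(self, grid):
        T = np.full(grid.shape, 10.0)
        T[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            cs.extract_isotherm_region(T, 0.0, grid)


class TestMeasureAxes:
    def test_ellipsoid_caliper(self, grid):
        T = ellipsoid_field(grid, a=0.0125, b=0.006)
        region = cs.extract_isotherm_region(T, 0.0, grid)
        lon, tra = cs.measure_axes(region, probe_axis=(0, 0, -1))
        assert lon == pytest.approx(0.025, abs=1.5 * grid.spacing)
        assert tra == pytest.approx(0.012, abs=1.5 * grid.spacing)

    def test_sphere_isotropic(self, grid):
        T = radial_field(grid)
        region = cs.extract_isotherm_region(T, 0.0, grid)
        lon, tra = cs.measure_axes(region)
        assert lon == pytest.approx(0.010, abs=1.5 * grid.spacing)
        assert tra == pytest.approx(0.010, abs=1.5 * grid.spacing)

    def test_two_balls_largest_only(self, grid):
        c = grid.cell_centers()
        r1 = np.linalg.norm(c - np.array([0.0, 0.0, 0.008]), axis=-1)
        r2 = np.linalg.norm(c + np.array([0.0, 0.0, 0.010]), axis=-1)
        T = np.minimum(r1 - 0.006, r2 - 0.003) * 1e4  # big and small ball
        region = cs.extract_isotherm_region(T, 0.0, grid)
        assert region.component_count() == 2
        lon, tra = cs.measure_axes(region)
        assert lon == pytest.approx(0.012, abs=1.5 * grid.spacing)

    def test_rotated_field_same_axes(self, grid):
        T = ellipsoid_field(grid, a=0.0125, b=0.006)
        Trot = np.rot90(T, k=1, axes=(0, 1))
        r1 = cs.extract_isotherm_region(T, 0.0, grid)
        r2 = cs.extract_isotherm_region(Trot, 0.0, grid)
        a1 = cs.measure_axes(r1)
        a2 = cs.measure_axes(r2)
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_empty_region_signalled(self, grid):
        region = cs.extract_isotherm_region(np.full(grid.shape, 37.0), 0.0, grid)
        with pytest.raises(cs.EmptyRegionError):
            cs.measure_axes(region)


class TestWarmZone:
    def test_uniform_cold_no_warm_zone(self, grid):
        assert cs.warm_zone_volume(np.full(grid.shape, -50.0), 0.0, -40.0, grid) == 0.0

    def test_cold_sphere_below_lethal(self, grid):
        T = radial_field(grid, scale=1e4, offset=-90.0)  # sphere colder than -40
        T = np.where(T > -41.0, 37.0, T)
        assert cs.warm_zone_volume(T, 0.0, -40.0, grid) == 0.0

    def test_central_pocket_counted(self, grid):
        """A warm pocket inside a frozen shell is measured by voxel count."""
        c = grid.cell_centers()
        r = np.linalg.norm(c, axis=-1)
        T = np.full(grid.shape, 37.0)
        shell = (r >= 0.006) & (r <= 0.012)
        core = r < 0.006
        T[shell] = -60.0
        T[core] = -30.0  # pocket above the -40 lethal level
        expected = float(np.sum(core) * grid.spacing**3)
        got = cs.warm_zone_volume(T, 0.0, -40.0, grid)
        assert got == pytest.approx(expected, rel=0.05)

    def test_monotone_in_lethal_level(self, grid):
        c = grid.cell_centers()
        r = np.linalg.norm(c, axis=-1)
        T = np.where(r < 0.010, -55.0 + r * 4e3, 37.0)
        vols = [cs.warm_zone_volume(T, 0.0, lv, grid) for lv in (-50.0, -40.0, -30.0)]
        assert vols[0] >= vols[1] >= vols[2]

    def test_level_ordering_enforced(self, grid):
        with pytest.raises(ValueError):
            cs.warm_zone_volume(np.zeros(grid.shape), -40.0, 0.0, grid)


class TestMergeTracking:
    def _result_from_fields(self, grid, fields):
        snaps = [
            cs.ThermalState(T=f, alpha=np.zeros(grid.shape),
                            theta_d=np.zeros(grid.shape), t=float(i))
            for i, f in enumerate(fields)
        ]
        import pandas as pd
        return cs.SimulationResult(
            grid=grid, layout=None, config=cs.SolverConfig(dt=1.0, end_time=1.0),
            tissue=cs.LIVER, damage=cs.DamageParams(), load_curve=cs.LoadCurve(),
            snapshot_times=list(range(len(fields))), snapshots=snaps,
            monitors=(), traces=pd.DataFrame(), step_records=[],
        )

    def test_two_balls_merge(self, grid):
        c = grid.cell_centers()
        p = np.array([0.0, 0.0, 0.006])
        warm = np.full(grid.shape, 37.0)
        def balls(rad):
            d1 = np.linalg.norm(c - p, axis=-1)
            d2 = np.linalg.norm(c + p, axis=-1)
            return np.where(np.minimum(d1, d2) < rad, -10.0, 37.0)
        res = self._result_from_fields(grid, [warm, balls(0.003), balls(0.007)])
        df = cs.track_merge_events(res)
        assert list(df["n_components"]) == [0, 2, 1]
        assert list(df["merge_event"]) == [False, False, True]

    def test_separated_balls_never_merge(self, grid):
        c = grid.cell_centers()
        p = np.array([0.0, 0.0, 0.010])
        d1 = np.linalg.norm(c - p, axis=-1)
        d2 = np.linalg.norm(c + p, axis=-1)
        f = np.where(np.minimum(d1, d2) < 0.004, -10.0, 37.0)
        res = self._result_from_fields(grid, [f, f])
        df = cs.track_merge_events(res)
        assert list(df["n_components"]) == [2, 2]
        assert not df["merge_event"].any()


class TestDimensionalError:
    def test_exact_match(self):
        assert cs.dimensional_error((2.5, 1.2), (2.5, 1.2)) == 0.0

    def test_mean_of_axis_errors(self):
        err = cs.dimensional_error((2.5, 1.2), (2.6, 1.25))
        expected = 0.5 * (abs(2.5 - 2.6) / 2.6 + abs(1.2 - 1.25) / 1.25) * 100
        assert err == pytest.approx(expected)

    def test_single_axis_relative_error(self):
        assert cs.dimensional_error(2.0, 2.5) == pytest.approx(20.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            cs.dimensional_error((1.0,), (0.0,))


class TestThermocouples:
    def test_cell_center_exact_and_midpoint_mean(self, small_grid):
        cfg = cs.SolverConfig(dt=1.0, end_time=2.0, output_cadence=1.0)
        res = cs.simulate(cfg, small_grid, None, cs.TissueParams(w_b=0.0, Q_m=0.0))
        snap = res.final
        snap.T[...] = np.arange(snap.T.size, dtype=float).reshape(snap.T.shape)
        x = small_grid.axis_coords()
        center = (x[0][3], x[1][3], x[2][3])
        midpoint = (0.5 * (x[0][3] + x[0][4]), x[1][3], x[2][3])
        df = cs.sample_thermocouples(res, [center, midpoint])
        assert df.iloc[-1]["T_p0_C"] == pytest.approx(snap.T[3, 3, 3])
        assert df.iloc[-1]["T_p1_C"] == pytest.approx(
            0.5 * (snap.T[3, 3, 3] + snap.T[4, 3, 3])
        )

    def test_point_outside_named(self, small_grid):
        cfg = cs.SolverConfig(dt=1.0, end_time=1.0)
        res = cs.simulate(cfg, small_grid, None, cs.TissueParams(w_b=0.0, Q_m=0.0))
        with pytest.raises(ValueError, match=r"\[1.0, 1.0, 1.0\]"):
            cs.sample_thermocouples(res, [(1.0, 1.0, 1.0)])


class TestAxisymmetricExtents:
    def test_rectangle_region(self):
        grid = cs.AxisymmetricGrid(spacing=1e-3, shape=(20, 30), z_top=0.0)
        r, z = grid.axis_coords()
        T = np.full(grid.shape, 37.0)
        T[(r < 0.0052)[:, None] & ((z > -0.0202) & (z < -0.0048))[None, :]] = -20.0
        lon, tra = cs.axisymmetric_extents(T, 0.0, grid)
        assert lon == pytest.approx(0.015, abs=1.5e-3)
        assert tra == pytest.approx(0.010, abs=2e-3)

    def test_empty_region(self):
        grid = cs.AxisymmetricGrid(spacing=1e-3, shape=(10, 10), z_top=0.0)
        with pytest.raises(cs.EmptyRegionError):
            cs.axisymmetric_extents(np.full(grid.shape, 37.0), 0.0, grid)
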