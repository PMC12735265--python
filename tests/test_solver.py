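"""Time stepping: equilibria, conservation, damage kinetics, stability."""

import numpy as np
import pytest

import cryosim as cs
from cryosim.solver import Discretization


def _steps(state, disc, tissue, cfg, n, damage=None):
    recs = []
    for _ in range(n):
        state, diag = cs.step(state, disc, tissue=tissue,
                              damage=damage or cs.DamageParams(), cfg=cfg)
        recs.append(diag)
    return state, recs


class TestThermalStep:
    def test_uniform_equilibrium_without_sources(self, small_grid):
        tis = cs.TissueParams(w_b=0.0, Q_m=0.0)
        cfg = cs.SolverConfig(dt=1.0, end_time=10.0, frozen_shutdown=False)
        disc = Discretization(small_grid, None)
        state = cs.ThermalState.uniform(small_grid, 37.0)
        state, _ = _steps(state, disc, tis, cfg, 5)
        np.testing.assert_allclose(state.T, 37.0, atol=1e-10)

    def test_insulated_enthalpy_conservation(self, small_grid):
        """Source-free insulated slab: per-step balance at machine level even
        while cells cross the mushy interval."""
        tis = cs.TissueParams(w_b=0.0, Q_m=0.0)
        cfg = cs.SolverConfig(dt=1.0, end_time=10.0, frozen_shutdown=False)
        disc = Discretization(small_grid, None)
        state = cs.ThermalState.uniform(small_grid, 20.0)
        state.T += np.linspace(-50.0, 10.0, 8)[None, None, :]
        _, recs = _steps(state, disc, tis, cfg, 10)
        assert max(r["residual_rel"] for r in recs) < 1e-8

    def test_conduction_free_matches_closed_form(self):
        """k -> 0 run follows the exact perfusion relaxation of every cell."""
        tis = cs.TissueParams(k_u=1e-12, k_f=1e-12)
        grid = cs.Grid1D(spacing=1e-3, n=4)
        cfg = cs.SolverConfig(dt=0.5, end_time=300.0, initial_temperature=30.0,
                              frozen_shutdown=False, output_cadence=300.0,
                              trace_interval=300.0)
        res = cs.simulate(cfg, grid, None, tis)
        ref = cs.lumped_perfusion_temperature(300.0, tis, 30.0)
        np.testing.assert_allclose(res.final.T, ref, atol=0.05)

    def test_comparison_principle(self, centered_grid):
        """With a cold probe, the coldest temperature anywhere never falls
        below the load-curve minimum."""
        layout = cs.make_layout("single", depth=0.02)
        lc = cs.LoadCurve(plateau_temperature=-100.0)
        cfg = cs.SolverConfig(dt=2.0, end_time=60.0, output_cadence=20.0)
        res = cs.simulate(cfg, centered_grid, layout, cs.LIVER, load_curve=lc)
        for snap in res.snapshots:
            assert snap.T.min() >= -100.0 - 1e-9
            assert np.all(np.isfinite(snap.T))

    def test_nan_rejected(self, small_grid):
        cfg = cs.SolverConfig(dt=1.0, end_time=10.0)
        disc = Discretization(small_grid, None)
        state = cs.ThermalState.uniform(small_grid, 37.0)
        state.T[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            cs.step(state, disc, cfg=cfg)


class TestExplicitMode:
    def test_stable_step_agrees_with_implicit(self, small_grid):
        tis = cs.TissueParams(w_b=0.0, Q_m=0.0)
        disc = Discretization(small_grid, None)
        state = cs.ThermalState.uniform(small_grid, 20.0)
        state.T += np.linspace(0.0, 5.0, 8)[None, None, :]
        dt_small = 1e-3
        exp_cfg = cs.SolverConfig(dt=dt_small, end_time=1.0, method="explicit",
                                  frozen_shutdown=False)
        imp_cfg = cs.SolverConfig(dt=dt_small, end_time=1.0, method="implicit",
                                  frozen_shutdown=False)
        se, _ = cs.step(state.copy(), disc, tissue=tis, cfg=exp_cfg)
        si, _ = cs.step(state.copy(), disc, tissue=tis, cfg=imp_cfg)
        np.testing.assert_allclose(se.T, si.T, atol=1e-4)

    def test_unstable_step_flagged(self, small_grid):
        disc = Discretization(small_grid, None)
        state = cs.ThermalState.uniform(small_grid, 20.0)
        cfg = cs.SolverConfig(dt=10.0, end_time=100.0, method="explicit")
        with pytest.raises(cs.StabilityError, match="stability limit"):
            cs.step(state, disc, cfg=cfg)


class TestDamageKinetics:
    def _cell_state(self, T):
        state = cs.ThermalState(
            T=np.array([T]), alpha=np.zeros(1), theta_d=np.zeros(1), t=0.0
        )
        return state

    def test_accumulation_rate(self, damage):
        """30 s below threshold at t_dc = 60 s gives alpha = theta = 0.5."""
        state = self._cell_state(-30.0)
        for _ in range(30):
            state = cs.update_damage(state, damage, 1.0)
        assert state.alpha[0] == pytest.approx(0.5)
        assert state.theta_d[0] == pytest.approx(0.5)

    def test_above_threshold_no_accumulation(self, damage):
        state = self._cell_state(-10.0)
        state = cs.update_damage(state, damage, 1000.0)
        assert state.alpha[0] == 0.0

    def test_cap_at_one(self, damage):
        state = self._cell_state(-30.0)
        state = cs.update_damage(state, damage, 90.0)
        assert state.alpha[0] == pytest.approx(1.5)
        assert state.theta_d[0] == 1.0

    def test_alpha_monotone_through_simulation(self, centered_grid):
        layout = cs.make_layout("single", depth=0.02)
        cfg = cs.SolverConfig(dt=2.0, end_time=60.0, output_cadence=10.0)
        res = cs.simulate(cfg, centered_grid, layout, cs.LIVER)
        prev = None
        for snap in res.snapshots:
            assert np.all(snap.theta_d == np.minimum(snap.alpha, 1.0))
            if prev is not None:
                assert np.all(snap.alpha >= prev - 1e-15)
            prev = snap.alpha

    def test_damage_enthalpy_registered(self, damage):
        dmg = cs.DamageParams(apply_damage_enthalpy=True)
        state = self._cell_state(-30.0)
        state = cs.update_damage(state, dmg, 30.0, tissue=cs.LIVER)
        # rho_f * L_dc * dtheta/dt = 998 * 250e3 * (0.5/30)
        assert state.damage_heat[0] == pytest.approx(998 * 250e3 * 0.5 / 30.0)


class TestSimulateOutputs:
    def test_zero_end_time_single_snapshot(self, small_grid):
        cfg = cs.SolverConfig(dt=1.0, end_time=0.0, initial_temperature=25.0)
        res = cs.simulate(cfg, small_grid, None)
        assert len(res.snapshots) == 1
        np.testing.assert_allclose(res.final.T, 25.0)

    def test_snapshot_cadence(self, small_grid):
        cfg = cs.SolverConfig(dt=1.0, end_time=10.0, output_cadence=2.0,
                              trace_interval=1.0)
        res = cs.simulate(cfg, small_grid, None, cs.TissueParams(w_b=0.0, Q_m=0.0))
        assert res.snapshot_times == [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]

    def test_traces_sampled_at_one_hertz(self, small_grid):
        cfg = cs.SolverConfig(dt=2.0, end_time=10.0, output_cadence=10.0,
                              trace_interval=1.0)
        x = small_grid.axis_coords()
        pt = (x[0][2], x[1][2], x[2][2])
        res = cs.simulate(cfg, small_grid, None, monitors=(pt,))
        assert list(res.traces["t_s"]) == [0.0, 1.0, 2.0, 3.0, 4.0, 5.0,
                                           6.0, 7.0, 8.0, 9.0, 10.0]
        assert "T_p0_C" in res.traces and "theta_p0" in res.traces

    def test_monitor_outside_domain_rejected(self, small_grid):
        cfg = cs.SolverConfig(dt=1.0, end_time=1.0)
        with pytest.raises(ValueError, match="outside"):
            cs.simulate(cfg, small_grid, None, monitors=((1.0, 1.0, 1.0),))

    def test_energy_balance_report_shape(self, small_grid):
        cfg = cs.SolverConfig(dt=1.0, end_time=5.0)
        res = cs.simulate(cfg, small_grid, None, cs.TissueParams(w_b=0.0, Q_m=0.0))
        df = cs.energy_balance_report(res)
        assert len(df) == 5
        assert {"t_s", "residual_rel", "probe_sink_J"} <= set(df.columns)


class TestProbeRunBalance:
    def test_probe_clamp_accounted_in_balance(self, centered_grid):
        """With the clamped-cell sink included, probe steps balance to <=1%."""
        layout = cs.make_layout("single", depth=0.02)
        cfg = cs.SolverConfig(dt=1.0, end_time=120.0, initial_temperature=25.0,
                              output_cadence=120.0)
        res = cs.simulate(cfg, centered_grid, layout, cs.LIVER)
        df = cs.energy_balance_report(res)
        assert df["residual_rel"].max() < 0.01
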