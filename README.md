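# cryosim

Planning-grade simulation of **multi-probe cryoablation**: the freezing of
soft tissue (liver is the packaged default) around one or several needle-like
cryoprobes, for researchers and engineers studying probe-layout design,
ice-ball growth, and lethal-zone coverage.

The thermal core is the transient Pennes bioheat equation with solid–liquid
phase change handled by the effective heat capacity method,

    (ρC)_eff ∂T/∂t = ∇·(k(T)∇T) + w_b ρ_b c_b (T_b − T) + Q_m ,

with three-branch piecewise properties (liquid above T_mu = −1 °C, frozen
below T_ml = −8 °C, mushy mixture in between) and the latent heat
Q_lf = 250 MJ/m³ smeared across the mushy interval. Cell injury follows a
threshold/time clock: below T_dc = −20 °C the damage fraction θ_d grows at
rate 1/t_dc (t_dc = 60 s) and saturates at 1.

On top of the solver the package provides:

* probe-layout geometry (single / five / seven / nine-probe patterns, shared
  piecewise-linear load curve, grid rasterization);
* a conservative backward-Euler finite-volume solver (3-D Cartesian,
  axisymmetric (r,z), and 1-D) with per-step enthalpy balance reporting;
* ice-ball morphometrics: isotherm surfaces (marching cubes), caliper-style
  longitudinal/transverse extents, warm-zone volumes, merge-event tracking;
* closed-form verification oracles (two-phase Neumann/Stefan front, lumped
  perfusion relaxation, mesh-convergence harness);
* a YAML config dialect with explicit unit suffixes, scenario presets, VTK
  and CSV outputs, a reproducibility manifest, and a `cryosim` CLI.

## Worked example

A single probe inserted 2 cm into 25 °C tissue, frozen for 5 minutes on a
1 mm axisymmetric grid, with a thermocouple 5 mm from the probe axis at tip
depth:

```python
import cryosim as cs

grid = cs.AxisymmetricGrid(spacing=1e-3, shape=(30, 40), z_top=0.0)
layout = cs.make_layout("single", depth=0.02)
cfg = cs.SolverConfig(dt=1.0, end_time=300.0, initial_temperature=25.0,
                      output_cadence=300.0, trace_interval=60.0)
res = cs.simulate(cfg, grid, layout, cs.LIVER, monitors=((0.005, -0.02),))

lon, tra = cs.axisymmetric_extents(res.final.T, 0.0, grid)
print(f"0 C ice ball after {cfg.end_time:.0f} s: "
      f"longitudinal {lon*100:.2f} cm, transverse {tra*100:.2f} cm")
print(res.traces.tail(3).to_string(index=False))
df = cs.energy_balance_report(res)
print(f"worst per-step energy residual: {df['residual_rel'].max():.2e}")
```

prints

```
0 C ice ball after 300 s: longitudinal 2.69 cm, transverse 2.35 cm
  t_s     T_p0_C  theta_p0
180.0 -16.754320  0.112500
240.0 -20.360071  0.370833
300.0 -22.752954  0.629167
worst per-step energy residual: 3.23e-03
```

The ice ball (0 °C isotherm) already spans the whole 2 cm insertion and has
grown ~1.2 cm radially; the monitored point crosses the −20 °C damage
threshold shortly after t = 180 s, after which its damage fraction climbs at
1/60 s⁻¹ toward certain death; and every backward-Euler step balances
enthalpy against boundary and source fluxes to better than 0.4%.

The same run from the shell:

```
cryosim simulate --preset phantom-single --out out/
cryosim layouts --pattern nine --spacing-cm 1
cryosim morphometry out/run_t0009.vtk --level -40
cryosim convergence --preset phantom-single --spacings-mm 2.4 1.2 0.6
cryosim validate
```

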