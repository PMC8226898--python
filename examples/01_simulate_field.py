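"""Simulate one focused-ultrasound exposure and inspect the field volumes.

Loads the packaged fast-profile pancreas scenario, runs the full chain
(source plane -> angular-spectrum propagation -> intensity -> power
deposition -> steady temperature) for a 44 x 40-element array focused at
46 mm, and prints the focal-zone scalars plus an axial profile.

Run:  python examples/01_simulate_field.py
"""

import numpy as np

import focusurf as fu

cfg = fu.load_packaged("pancreas_sweep_fast")
print(f"scenario: {cfg.name}  ({len(cfg.stack.layers)} layers, "
      f"{cfg.frequency / 1e6:.1f} MHz)")

res = fu.simulate(cfg, nx=44, ny=40, focus_mm_z=46.0)

print("\nfocal-zone scalars (maxima over the target layer):")
for key in ("max_pressure_pa", "max_power_w_m3", "max_temperature_c"):
    print(f"  {key:20s} {res.scalars[key]:.6g}")
print(f"  peak voxel (mm)      {res.scalars['peak_voxel_xyz_mm']}")
print(f"  runtime (s)          {res.scalars['runtime_s']:.2f}")

# axial pressure profile through the lateral centre
grid = cfg.grid
axial = np.abs(res.pressure.values[grid.nx // 2, grid.ny // 2, :])
print("\naxial |p| profile (depth mm : MPa):")
for iz in range(0, grid.nz, 6):
    bar = "#" * int(40 * axial[iz] / axial.max())
    print(f"  {grid.z[iz] * 1e3:5.1f} : {axial[iz] / 1e6:7.3f}  {bar}")
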