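"""Shared fixtures: small media, one ASM-vs-oracle field, one Green's-function
solve and one fast-profile sweep dataset, each computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import focusurf as fu


@pytest.fixture(scope="session")
def water() -> fu.Medium:
    """Degassed water (couplant) with its published property set."""
    return fu.Medium(name="water", density=1000, sound_speed=1480,
                     attenuation_coeff=0.00025, power_law_exponent=2,
                     specific_heat=4180, thermal_conductivity=0.615,
                     blood_perfusion=0, blood_specific_heat=3480)


@pytest.fixture(scope="session")
def lossless_water() -> fu.Medium:
    return fu.Medium(name="water0", density=1000, sound_speed=1480,
                     attenuation_coeff=0.0, power_law_exponent=2)


@pytest.fixture(scope="session")
def prostate() -> fu.Medium:
    """Prostate tissue with its published property set."""
    return fu.Medium(name="prostate", density=1060, sound_speed=1500,
                     attenuation_coeff=0.504, power_law_exponent=1,
                     specific_heat=3600, thermal_conductivity=0.50,
                     blood_perfusion=2.5, blood_specific_heat=3720)


@pytest.fixture(scope="session")
def rectal_wall() -> fu.Medium:
    return fu.Medium(name="rectal_wall", density=1060, sound_speed=1500,
                     attenuation_coeff=0.5211, power_law_exponent=1,
                     specific_heat=3500, thermal_conductivity=0.56,
                     blood_perfusion=4, blood_specific_heat=3720)


@pytest.fixture(scope="session")
def asm_vs_oracle(lossless_water):
    """16x4-element array at 1 MHz in lossless water: spectral march vs the
    brute-force Rayleigh-Sommerfeld sum on a 64x64 plane at 30 mm depth."""
    arr = fu.build_array(16, 4, (20.0, 5.0), 1.0)
    exc = fu.make_excitation(arr, 1e6, (0.0, 0.0, 0.030),
                             lossless_water.sound_speed, v0=1.0)
    grid = fu.Grid3D(nx=64, ny=64, nz=60, dx=0.7e-3, dy=0.7e-3, dz=0.5e-3)
    stack = fu.LayeredStack(layers=[(lossless_water, 0.2)])
    src = fu.rayleigh_plane(arr, exc, lossless_water, grid)
    field = fu.propagate_stack(src, stack, grid, exc)
    iz = int(np.argmin(abs(grid.z - 0.030)))
    gx, gy = np.meshgrid(grid.x, grid.y, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, grid.z[iz])])
    oracle = fu.direct_field_oracle(arr, exc, lossless_water, pts).reshape(64, 64)
    return {"array": arr, "exc": exc, "grid": grid, "stack": stack,
            "source": src, "field": field, "iz": iz, "oracle": oracle,
            "medium": lossless_water}


@pytest.fixture(scope="session")
def greens_solution(prostate):
    """Steady bio-heat response to a 1 W point source in homogeneous
    prostate-like tissue, plus the perfusion Green's function."""
    kt = prostate.thermal_conductivity
    wbcb = prostate.blood_perfusion * prostate.blood_specific_heat
    length = np.sqrt(kt / wbcb)  # 7.33 mm perfusion length
    n, h = 51, 1.4e-3
    grid = fu.Grid3D(nx=n, ny=n, nz=n, dx=h, dy=h, dz=h)
    stack = fu.LayeredStack(layers=[(prostate, 1.0)])
    solver = fu.BioheatSolver(stack, grid)
    q = np.zeros(grid.shape)
    c = n // 2
    watts = 1.0
    q[c, c, c] = watts / h ** 3
    rise = solver.solve_rise(q)
    xg, yg, zg = np.meshgrid(grid.x, grid.y, grid.z - grid.z[c], indexing="ij")
    r = np.sqrt(xg ** 2 + yg ** 2 + zg ** 2)
    analytic = np.where(r > 0, watts * np.exp(-r / length)
                        / (4 * np.pi * kt * np.maximum(r, 1e-12)), 0.0)
    return {"grid": grid, "stack": stack, "solver": solver, "q": q,
            "rise": rise, "analytic": analytic, "r": r, "h": h,
            "length": length, "wbcb": wbcb}


@pytest.fixture(scope="session")
def fast_sweep_dataset(tmp_path_factory):
    """The packaged 120-combination fast-profile sweep, run once."""
    cfg = fu.load_packaged("pancreas_sweep_fast")
    out = tmp_path_factory.mktemp("sweep") / "fast.csv"
    df = fu.run_sweep(cfg, out, resume=False)
    return {"config": cfg, "dataset": df, "path": out}
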