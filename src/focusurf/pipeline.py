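"""End-to-end single simulation: source plane -> 3D pressure -> Q -> T."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .asm import PressureField3D, propagate_stack
from .config import ScenarioConfig
from .rayleigh import rayleigh_plane
from .thermal import BioheatSolver, ScalarField3D, intensity, power_deposition, steady_bioheat

log = logging.getLogger(__name__)


@dataclass
class SimulationResult:
    """All fields plus the scalar summary of one continuous-wave run."""

    pressure: PressureField3D
    intensity: ScalarField3D | None
    power: ScalarField3D | None
    temperature: ScalarField3D | None
    scalars: dict


def focal_metrics(pressure: PressureField3D, q: ScalarField3D | None,
                  temperature: ScalarField3D | None,
                  target_layer: str) -> tuple[float, float, float]:
    """(max |p|, max Q, max T) over the voxels of the target tissue layer.

    The focus zone is taken to be the whole target layer: maxima are
    restricted to z-planes whose medium label matches ``target_layer``,
    so hot spots in intervening layers (e.g. skin) are excluded.
    """
    names = np.array([m.name for m in pressure.stack.media])
    mask = names[pressure.layer_index] == target_layer
    if not mask.any():
        raise ValueError(f"target layer {target_layer!r} absent from the grid")
    max_p = float(np.abs(pressure.values[:, :, mask]).max())
    max_q = float(q.values[:, :, mask].max()) if q is not None else float("nan")
    max_t = (float(temperature.values[:, :, mask].max())
             if temperature is not None else float("nan"))
    return max_p, max_q, max_t


def simulate(config: ScenarioConfig, nx: int | None = None, ny: int | None = None,
             focus_mm_z: float | None = None, thermal: bool = True,
             solver: BioheatSolver | None = None) -> SimulationResult:
    """Run the full chain for one (element-count, focus) combination.

    ``solver`` may carry a pre-factorised bio-heat operator for the
    scenario's stack/grid; passing it avoids re-assembly inside sweeps.
    """
    t0 = time.perf_counter()
    array, exc = config.excitation(nx=nx, ny=ny, focus_mm_z=focus_mm_z)
    couplant = config.stack.media[0]
    src = rayleigh_plane(array, exc, couplant, config.grid)
    log.debug("source plane done in %.2fs", time.perf_counter() - t0)

    pressure = propagate_stack(src, config.stack, config.grid, exc)
    ia = intensity(pressure, config.stack)
    q = power_deposition(ia, config.stack, config.frequency / 1e6)
    temp = None
    if thermal:
        temp = steady_bioheat(q, config.stack, config.grid, solver=solver)

    target = config.sweep.target_layer if config.sweep else config.stack.media[-1].name
    max_p, max_q, max_t = focal_metrics(pressure, q, temp, target)
    peak = np.unravel_index(np.argmax(np.abs(pressure.values)), pressure.values.shape)
    scalars = {
        "max_pressure_pa": max_p,
        "max_power_w_m3": max_q,
        "max_temperature_c": max_t,
        "target_layer": target,
        "peak_voxel_xyz_mm": [float(config.grid.x[peak[0]] * 1e3),
                              float(config.grid.y[peak[1]] * 1e3),
                              float(config.grid.z[peak[2]] * 1e3)],
        "runtime_s": time.perf_counter() - t0,
    }
    log.info("simulation %s: nx=%d ny=%d focus=%.1fmm in %.2fs",
             config.name, array.nx_elements, array.ny_elements,
             exc.focus[2] * 1e3, scalars["runtime_s"])
    return SimulationResult(pressure=pressure, intensity=ia, power=q,
                            temperature=temp, scalars=scalars)
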