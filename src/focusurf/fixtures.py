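"""Deterministic small inputs for tests and demos."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .media import Grid3D
from .thermal import ScalarField3D

FIXTURE_KINDS = ("toy_array", "gaussian_temperature", "tiny_sweep")

_WATER = {"density": 1000, "sound_speed": 1480,
          "attenuation_db_cm_mhz": 0.00025, "power_law_exponent": 2,
          "specific_heat": 4180, "thermal_conductivity": 0.615,
          "blood_perfusion": 0, "blood_specific_heat": 3480,
          "nonlinearity": 0}

_TISSUE = {"density": 1050, "sound_speed": 1550,
           "attenuation_db_cm_mhz": 0.5, "power_law_exponent": 1,
           "specific_heat": 3600, "thermal_conductivity": 0.5,
           "blood_perfusion": 2.5, "blood_specific_heat": 3720,
           "nonlinearity": 1}


def toy_array_config(seed: int = 0) -> dict:
    """A 4x2-element water-path scenario small enough for unit tests."""
    rng = np.random.default_rng(seed)
    focus_z = float(rng.choice([18.0, 20.0, 22.0]))
    return {
        "name": f"toy_array_seed{seed}",
        "media": {"water": dict(_WATER), "tissue": dict(_TISSUE)},
        "stack": {"layers": [{"medium": "water", "thickness_mm": 8},
                             {"medium": "tissue", "thickness_mm": 40}],
                  "arterial_temperature_c": 37},
        "grid": {"extent_mm": [24, 12, 32], "spacing_mm": [1.5, 1.5, 2.0]},
        "array": {"aperture_mm": [16, 8], "nx": 4, "ny": 2, "kerf_um": 1,
                  "frequency_mhz": 0.45, "focus_mm": [0, 0, focus_z],
                  "v0_m_per_s": 1.0},
        "sweep": {"x_elements": {"start": 4, "stop": 4, "step": 1},
                  "y_elements": {"start": 2, "stop": 2, "step": 1},
                  "focus_mm": {"start": focus_z, "stop": focus_z, "step": 1},
                  "target_layer": "tissue"},
    }


def tiny_sweep_config(seed: int = 0) -> dict:
    """A 6-combination sweep (2 x-counts, 1 y-count, 3 focal depths)."""
    cfg = toy_array_config(seed)
    cfg["name"] = f"tiny_sweep_seed{seed}"
    cfg["sweep"] = {"x_elements": {"start": 4, "stop": 8, "step": 4},
                    "y_elements": {"start": 2, "stop": 2, "step": 1},
                    "focus_mm": {"start": 16, "stop": 24, "step": 4},
                    "target_layer": "tissue"}
    return cfg


def gaussian_temperature_field(seed: int = 0) -> tuple[ScalarField3D, dict]:
    """Synthetic temperature volume with an exactly known Gaussian rise.

    Returns the field plus its ground truth (peak rise, sigmas in mm):
    the closed-form width of a level-L contour of a Gaussian of lateral
    standard deviation sigma is 2*sigma*sqrt(2*ln(peak/L)).
    """
    rng = np.random.default_rng(seed)
    peak = float(rng.uniform(5.5, 7.5))
    sigma_x_mm = float(rng.uniform(2.0, 3.5))
    sigma_z_mm = 2.5 * sigma_x_mm
    grid = Grid3D(nx=61, ny=21, nz=81, dx=0.5e-3, dy=0.5e-3, dz=0.5e-3)
    x = grid.x[:, None, None]
    y = grid.y[None, :, None]
    z = (grid.z - grid.z[len(grid.z) // 2])[None, None, :]
    rise = peak * np.exp(-(x ** 2 + y ** 2) / (2 * (sigma_x_mm * 1e-3) ** 2)
                         - z ** 2 / (2 * (sigma_z_mm * 1e-3) ** 2))
    field = ScalarField3D(values=37.0 + rise, grid=grid, role="temperature")
    truth = {"peak_rise_c": peak, "sigma_x_mm": sigma_x_mm,
             "sigma_z_mm": sigma_z_mm, "baseline_c": 37.0}
    return field, truth


def make_fixture(kind: str, seed: int, out_dir: str | Path) -> Path:
    """Write one fixture to ``out_dir``; same seed gives identical bytes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "toy_array":
        path = out_dir / f"toy_array_seed{seed}.yaml"
        path.write_text(yaml.safe_dump(toy_array_config(seed), sort_keys=True))
    elif kind == "tiny_sweep":
        path = out_dir / f"tiny_sweep_seed{seed}.yaml"
        path.write_text(yaml.safe_dump(tiny_sweep_config(seed), sort_keys=True))
    elif kind == "gaussian_temperature":
        from .io import save_fields
        field, truth = gaussian_temperature_field(seed)
        path = out_dir / f"gaussian_temperature_seed{seed}.h5"
        save_fields(path, field.grid, scalars={"temperature": field},
                    provenance={"seed": seed, **truth})
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return path
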