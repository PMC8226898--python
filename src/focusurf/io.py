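"""HDF5 serialisation of simulation fields with provenance attributes."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .asm import PressureField3D
from .media import Grid3D
from .thermal import ScalarField3D


def _write_axes(h5: h5py.Group, grid: Grid3D) -> None:
    h5.create_dataset("x", data=grid.x)
    h5.create_dataset("y", data=grid.y)
    h5.create_dataset("z", data=grid.z)
    h5.attrs["spacing_m"] = (grid.dx, grid.dy, grid.dz)


_UNITS = {"pressure": "Pa", "intensity": "W/m^2",
          "power_deposition": "W/m^3", "temperature": "degC"}


def save_fields(path: str | Path, grid: Grid3D,
                pressure: PressureField3D | None = None,
                scalars: dict[str, ScalarField3D] | None = None,
                provenance: dict | None = None) -> None:
    """Write pressure/scalar volumes plus provenance attrs to one HDF5 file."""
    with h5py.File(path, "w") as h5:
        _write_axes(h5, grid)
        if pressure is not None:
            g = h5.create_group("pressure")
            g.create_dataset("real", data=pressure.values.real)
            g.create_dataset("imag", data=pressure.values.imag)
            g.create_dataset("layer_index", data=pressure.layer_index)
            g.attrs["units"] = _UNITS["pressure"]
        for name, fld in (scalars or {}).items():
            g = h5.create_group(name)
            g.create_dataset("values", data=fld.values)
            g.attrs["units"] = _UNITS.get(fld.role, "")
            g.attrs["role"] = fld.role
        for key, val in (provenance or {}).items():
            h5.attrs[key] = json.dumps(val) if isinstance(val, (dict, list)) else val


def load_pressure(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Complex pressure volume and layer index from a saved field file."""
    with h5py.File(path, "r") as h5:
        g = h5["pressure"]
        vals = np.asarray(g["real"]) + 1j * np.asarray(g["imag"])
        return vals, np.asarray(g["layer_index"])


def load_scalar(path: str | Path, name: str) -> np.ndarray:
    with h5py.File(path, "r") as h5:
        return np.asarray(h5[name]["values"])
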