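"""Parameter-sweep enumeration, execution and dataset I/O.

A sweep varies the number of array elements in x and y and the focal depth
over inclusive ranges while the aperture, kerf, frequency, tissue stack and
grid stay fixed; each combination yields one row of three features
(nx, ny, focus_mm) and three targets (max pressure, max power deposition,
max temperature in the target layer). Rows are appended to a CSV as they
complete, so an interrupted sweep can be resumed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import ScenarioConfig, SweepSpec
from .pipeline import simulate
from .thermal import BioheatSolver

log = logging.getLogger(__name__)

DATASET_COLUMNS = ["nx", "ny", "focus_mm", "max_pressure_pa",
                   "max_power_w_m3", "max_temperature_c"]
FEATURES = ["nx", "ny", "focus_mm"]
TARGETS = ["max_pressure_pa", "max_power_w_m3", "max_temperature_c"]

# one factorised bio-heat operator per (config hash) per worker process
_solver_cache: dict[str, BioheatSolver] = {}


def _inclusive_range(start, stop, step):
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return [start + i * step for i in range(n)]


def enumerate_sweep(spec: SweepSpec) -> list[tuple[int, int, float]]:
    """All (nx, ny, focus_mm) combinations, row-major (nx outer, focus inner)."""
    xs = [int(v) for v in _inclusive_range(*spec.x_elements)]
    ys = [int(v) for v in _inclusive_range(*spec.y_elements)]
    fs = [float(v) for v in _inclusive_range(*spec.focus_mm)]
    if not (xs and ys and fs):
        raise ValueError("empty sweep range")
    return [(nx, ny, f) for nx in xs for ny in ys for f in fs]


def _run_one(config: ScenarioConfig, nx: int, ny: int, focus_mm: float) -> dict:
    solver = _solver_cache.get(config.config_hash)
    if solver is None:
        solver = BioheatSolver(config.stack, config.grid)
        _solver_cache[config.config_hash] = solver
    res = simulate(config, nx=nx, ny=ny, focus_mm_z=focus_mm, solver=solver)
    return {"nx": nx, "ny": ny, "focus_mm": focus_mm,
            "max_pressure_pa": res.scalars["max_pressure_pa"],
            "max_power_w_m3": res.scalars["max_power_w_m3"],
            "max_temperature_c": res.scalars["max_temperature_c"]}


def _read_existing(out_path: Path) -> pd.DataFrame:
    """Completed rows of a partial dataset; malformed tail rows are dropped."""
    try:
        df = pd.read_csv(out_path, on_bad_lines="skip")
    except Exception:
        return pd.DataFrame(columns=DATASET_COLUMNS)
    if list(df.columns) != DATASET_COLUMNS:
        return pd.DataFrame(columns=DATASET_COLUMNS)
    return df.dropna()


def run_sweep(config: ScenarioConfig, out_path: str | Path,
              resume: bool = True, workers: int = 1) -> pd.DataFrame:
    """Run every combination of the scenario's sweep spec; write a CSV.

    Deterministic given the config; with ``resume`` the rows already
    present in ``out_path`` are kept and only missing combinations are
    computed. A JSON sidecar records provenance (config hash, grid).
    """
    if config.sweep is None:
        raise ValueError("scenario config has no sweep block")
    out_path = Path(out_path)
    combos = enumerate_sweep(config.sweep)

    done: set[tuple] = set()
    rows: list[dict] = []
    if resume and out_path.exists():
        existing = _read_existing(out_path)
        for _, r in existing.iterrows():
            done.add((int(r.nx), int(r.ny), round(float(r.focus_mm), 6)))
        rows = existing.to_dict("records")
        log.info("resuming sweep: %d/%d rows already done", len(done), len(combos))

    todo = [(nx, ny, f) for nx, ny, f in combos
            if (nx, ny, round(f, 6)) not in done]

    if todo:
        if workers > 1:
            new_rows = Parallel(n_jobs=workers)(
                delayed(_run_one)(config, nx, ny, f) for nx, ny, f in todo)
        else:
            new_rows = []
            for i, (nx, ny, f) in enumerate(todo):
                new_rows.append(_run_one(config, nx, ny, f))
                if (i + 1) % 25 == 0:
                    log.info("sweep progress: %d/%d", i + 1, len(todo))
        rows.extend(new_rows)

    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    df = df.sort_values(FEATURES).reset_index(drop=True)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False)
    sidecar = out_path.with_suffix(out_path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({
        "config_name": config.name, "config_hash": config.config_hash,
        "n_rows": len(df), "grid_shape": list(config.grid.shape),
        "frequency_mhz": config.frequency / 1e6,
        "target_layer": config.sweep.target_layer,
    }, indent=2))
    return df


def load_dataset(path: str | Path) -> pd.DataFrame:
    """Read a sweep dataset CSV, checking the expected column layout."""
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    if df[DATASET_COLUMNS].isna().any().any():
        raise ValueError("dataset contains missing values")
    return df[DATASET_COLUMNS]
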