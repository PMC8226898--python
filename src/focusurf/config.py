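"""Scenario configuration: schema validation and unit normalisation.

Config files are YAML with blocks ``media``, ``stack``, ``grid``, ``array``
and optional ``sweep``, ``surrogate`` and ``validation_scenario``. Keys
carry their units in their names (``thickness_mm``, ``frequency_mhz``,
``kerf_um``); everything is converted to strict SI on load. Unknown keys
are rejected so that typos fail loudly rather than silently falling back
to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .media import Grid3D, LayeredStack, Medium
from .transducer import ArraySpec, Excitation, build_array, focus_phases


class ConfigError(ValueError):
    """Schema violation in a scenario config, reported with the key path."""


_MEDIUM_KEYS = {
    "density": "density",
    "sound_speed": "sound_speed",
    "attenuation_db_cm_mhz": "attenuation_coeff",
    "power_law_exponent": "power_law_exponent",
    "specific_heat": "specific_heat",
    "thermal_conductivity": "thermal_conductivity",
    "blood_perfusion": "blood_perfusion",
    "blood_specific_heat": "blood_specific_heat",
    "nonlinearity": "nonlinearity",
}
_REQUIRED_MEDIUM_KEYS = {"density", "sound_speed"}

_ARRAY_KEYS = {"aperture_mm", "nx", "ny", "kerf_um", "frequency_mhz",
               "focus_mm", "v0_m_per_s"}
_SWEEP_KEYS = {"x_elements", "y_elements", "focus_mm", "target_layer"}
_SURROGATE_KEYS = {"seed", "test_fraction", "cart_max_leaf_nodes",
                   "rf_n_estimators", "svr", "grids"}
_TOP_KEYS = {"name", "media", "stack", "grid", "array", "sweep", "surrogate",
             "validation_scenario", "notes"}


def _require(block: dict, key: str, path: str):
    if key not in block:
        raise ConfigError(f"missing key: {path}.{key}")
    return block[key]


def _reject_unknown(block: dict, allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) at {path}: {sorted(unknown)}")


@dataclass
class SweepSpec:
    """Ranges of the three swept inputs; endpoints inclusive."""

    x_elements: tuple[int, int, int]  # start, stop, step
    y_elements: tuple[int, int, int]
    focus_mm: tuple[float, float, float]
    target_layer: str

    def __post_init__(self) -> None:
        for name, (start, stop, step) in (("x_elements", self.x_elements),
                                          ("y_elements", self.y_elements),
                                          ("focus_mm", self.focus_mm)):
            if step <= 0:
                raise ConfigError(f"sweep.{name}: step must be > 0")
            if stop < start:
                raise ConfigError(f"sweep.{name}: empty range")


@dataclass
class ScenarioConfig:
    """Validated, SI-normalised scenario."""

    name: str
    media: dict[str, Medium]
    stack: LayeredStack
    grid: Grid3D
    array: ArraySpec
    frequency: float               # Hz
    focus: tuple[float, float, float]  # m
    v0: float                      # m/s
    sweep: SweepSpec | None = None
    surrogate: dict = field(default_factory=dict)
    validation_scenario: bool = False
    config_hash: str = ""
    aperture_mm: tuple[float, float] = (0.0, 0.0)
    kerf_um: float = 0.0

    def excitation(self, nx: int | None = None, ny: int | None = None,
                   focus_mm_z: float | None = None) -> tuple[ArraySpec, Excitation]:
        """Array + excitation, optionally overriding element counts / focus depth.

        The phase reference speed is the first (couplant) layer's sound
        speed; the focus override is an on-axis depth in mm.
        """
        array = self.array
        if nx is not None or ny is not None:
            array = build_array(nx or array.nx_elements, ny or array.ny_elements,
                                self.aperture_mm, self.kerf_um)
        focus = self.focus
        if focus_mm_z is not None:
            focus = (0.0, 0.0, focus_mm_z * 1e-3)
        c_ref = self.stack.media[0].sound_speed
        exc = Excitation(frequency=self.frequency, v0=self.v0,
                         phases=focus_phases(array, focus, c_ref, self.frequency),
                         focus=focus)
        return array, exc


def _parse_media(block, path="media") -> dict[str, Medium]:
    if not isinstance(block, dict) or not block:
        raise ConfigError(f"{path}: expected a non-empty mapping")
    media = {}
    for name, props in block.items():
        if not isinstance(props, dict):
            raise ConfigError(f"{path}.{name}: expected a mapping")
        _reject_unknown(props, set(_MEDIUM_KEYS), f"{path}.{name}")
        for req in _REQUIRED_MEDIUM_KEYS:
            _require(props, req, f"{path}.{name}")
        kwargs = {dest: float(props[src]) for src, dest in _MEDIUM_KEYS.items()
                  if src in props}
        try:
            media[name] = Medium(name=name, **kwargs)
        except ValueError as exc:
            raise ConfigError(f"{path}.{name}: {exc}") from exc
    return media


def load_config(source: str | Path | dict) -> ScenarioConfig:
    """Load and validate a scenario config from a YAML file or dict."""
    if isinstance(source, dict):
        raw = source
    else:
        raw = yaml.safe_load(Path(source).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "<root>")

    media = _parse_media(_require(raw, "media", "<root>"))

    stack_block = _require(raw, "stack", "<root>")
    _reject_unknown(stack_block, {"layers", "arterial_temperature_c"}, "stack")
    layers = []
    for i, layer in enumerate(_require(stack_block, "layers", "stack")):
        _reject_unknown(layer, {"medium", "thickness_mm"}, f"stack.layers[{i}]")
        mname = _require(layer, "medium", f"stack.layers[{i}]")
        if mname not in media:
            raise ConfigError(f"stack.layers[{i}].medium: unknown medium {mname!r}")
        layers.append((media[mname],
                       float(_require(layer, "thickness_mm", f"stack.layers[{i}]")) * 1e-3))
    stack = LayeredStack(layers=layers,
                         arterial_temperature_c=float(
                             stack_block.get("arterial_temperature_c", 37.0)))

    grid_block = _require(raw, "grid", "<root>")
    _reject_unknown(grid_block, {"extent_mm", "spacing_mm"}, "grid")
    grid = Grid3D.from_extent_mm(_require(grid_block, "extent_mm", "grid"),
                                 _require(grid_block, "spacing_mm", "grid"))
    if stack.total_thickness + 1e-9 < grid.z[-1]:
        raise ConfigError("stack thinner than grid depth; extend the last layer")

    arr_block = _require(raw, "array", "<root>")
    _reject_unknown(arr_block, _ARRAY_KEYS, "array")
    aperture_mm = tuple(float(v) for v in _require(arr_block, "aperture_mm", "array"))
    kerf_um = float(arr_block.get("kerf_um", 1.0))
    array = build_array(int(_require(arr_block, "nx", "array")),
                        int(_require(arr_block, "ny", "array")),
                        aperture_mm, kerf_um)
    frequency = float(_require(arr_block, "frequency_mhz", "array")) * 1e6
    focus_mm = _require(arr_block, "focus_mm", "array")
    focus = tuple(float(v) * 1e-3 for v in focus_mm)
    v0 = float(arr_block.get("v0_m_per_s", 1.0))

    sweep = None
    if "sweep" in raw:
        sb = raw["sweep"]
        _reject_unknown(sb, _SWEEP_KEYS, "sweep")

        def rng(key, cast):
            r = _require(sb, key, "sweep")
            _reject_unknown(r, {"start", "stop", "step"}, f"sweep.{key}")
            return (cast(r["start"]), cast(r["stop"]), cast(r["step"]))

        target = _require(sb, "target_layer", "sweep")
        if target not in media:
            raise ConfigError(f"sweep.target_layer: unknown medium {target!r}")
        sweep = SweepSpec(x_elements=rng("x_elements", int),
                          y_elements=rng("y_elements", int),
                          focus_mm=rng("focus_mm", float),
                          target_layer=target)

    surrogate = dict(raw.get("surrogate", {}))
    _reject_unknown(surrogate, _SURROGATE_KEYS, "surrogate")

    canon = json.dumps(raw, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(canon.encode()).hexdigest()[:16]

    return ScenarioConfig(
        name=str(raw.get("name", "scenario")), media=media, stack=stack,
        grid=grid, array=array, frequency=frequency, focus=focus, v0=v0,
        sweep=sweep, surrogate=surrogate,
        validation_scenario=bool(raw.get("validation_scenario", False)),
        config_hash=cfg_hash, aperture_mm=aperture_mm, kerf_um=kerf_um)


def packaged_config_path(name: str) -> Path:
    """Path to a config shipped with the package (e.g. ``pancreas_sweep_fast``)."""
    ref = resources.files("focusurf") / "configs" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return Path(p)


def load_packaged(name: str) -> ScenarioConfig:
    return load_config(packaged_config_path(name))
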