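"""Tissue property model, layered-stack geometry and interface physics.

All internal quantities are strict SI (m, s, Pa, W, K). Convenience
constructors accept the mixed clinical units (mm, MHz, °C) that tissue
tables are usually quoted in and convert on entry. Attenuation follows
the acoustic power law alpha(f) = a0 * f**b with a0 in dB/(cm*MHz**b).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: dB per neper: 20/ln(10)
DB_PER_NEPER = 20.0 / math.log(10.0)

#: Sentinel returned by :func:`snell_refraction` when the incident plane
#: wave is beyond the critical angle and no transmitted propagating wave
#: exists.
TOTAL_REFLECTION = "total_reflection"


@dataclass(frozen=True)
class Medium:
    """Acoustic and thermal properties of one tissue type.

    Parameters
    ----------
    name : str
        Human-readable tissue label (e.g. ``"prostate"``).
    density : float
        Mass density rho, kg/m^3.
    sound_speed : float
        Longitudinal sound speed c, m/s.
    attenuation_coeff : float
        Power-law prefactor a0, dB/(cm*MHz^b).
    power_law_exponent : float
        Frequency exponent b (dimensionless).
    specific_heat : float
        Tissue specific heat capacity C, J/(kg*K).
    thermal_conductivity : float
        Thermal conductivity k_t, W/(m*K).
    blood_perfusion : float
        Blood perfusion rate Wb, kg/(m^3*s).
    blood_specific_heat : float
        Specific heat of blood Cb, J/(kg*K).
    nonlinearity : float
        B/A-style nonlinearity parameter. Stored for completeness only;
        the propagation model is linear and never reads it.
    """

    name: str
    density: float
    sound_speed: float
    attenuation_coeff: float = 0.0
    power_law_exponent: float = 1.0
    specific_heat: float = 3600.0
    thermal_conductivity: float = 0.5
    blood_perfusion: float = 0.0
    blood_specific_heat: float = 3720.0
    nonlinearity: float = 0.0

    def __post_init__(self) -> None:
        for key in ("density", "sound_speed", "specific_heat", "thermal_conductivity"):
            if getattr(self, key) <= 0:
                raise ValueError(f"Medium {self.name!r}: {key} must be > 0")
        for key in ("attenuation_coeff", "power_law_exponent", "blood_perfusion",
                    "blood_specific_heat"):
            if getattr(self, key) < 0:
                raise ValueError(f"Medium {self.name!r}: {key} must be >= 0")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance Z = rho*c, Pa*s/m."""
        return acoustic_impedance(self)

    def wavelength(self, frequency_hz: float) -> float:
        """Wavelength c/f in metres at ``frequency_hz``."""
        if frequency_hz <= 0:
            raise ValueError("frequency must be > 0")
        return self.sound_speed / frequency_hz


def attenuation_np_per_m(medium: Medium, frequency_mhz: float) -> float:
    """Attenuation coefficient alpha in Np/m at ``frequency_mhz``.

    Evaluates the power law a0 * f^b (dB/cm) and converts dB/cm -> Np/m
    (factor 100 / 8.685889638).
    """
    if frequency_mhz <= 0:
        raise ValueError("frequency must be > 0")
    db_per_cm = medium.attenuation_coeff * frequency_mhz ** medium.power_law_exponent
    return db_per_cm * 100.0 / DB_PER_NEPER


def acoustic_impedance(medium: Medium) -> float:
    """Characteristic acoustic impedance Z = rho*c in Pa*s/m."""
    return medium.density * medium.sound_speed


def snell_refraction(theta_in: float, c_a: float, c_b: float):
    """Refraction angle of a plane wave crossing a speed discontinuity.

    sin(theta_out) = (c_b / c_a) * sin(theta_in). Returns the refracted
    angle in radians, or :data:`TOTAL_REFLECTION` when the incident angle
    exceeds the critical angle for transmission into the faster medium.
    """
    if not 0 <= theta_in < math.pi / 2:
        raise ValueError("incident angle must lie in [0, pi/2)")
    if c_a <= 0 or c_b <= 0:
        raise ValueError("sound speeds must be > 0")
    s = (c_b / c_a) * math.sin(theta_in)
    if s > 1.0:
        return TOTAL_REFLECTION
    return math.asin(s)


@dataclass(frozen=True)
class Grid3D:
    """Regular simulation lattice.

    x and y are lateral axes centred on the aperture centre; z = 0 is the
    transducer face and z increases into the tissue. Lateral spacings must
    resolve the shortest wavelength in the stack (dx, dy <= lambda_min/2),
    which is enforced by the propagator, not here, because the grid does
    not know the operating frequency.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("grid spacings must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def x(self) -> np.ndarray:
        """Lateral x coordinates (m), centred on the aperture axis."""
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.dx

    @property
    def y(self) -> np.ndarray:
        """Lateral y coordinates (m), centred on the aperture axis."""
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.dy

    @property
    def z(self) -> np.ndarray:
        """Axial plane positions (m); first plane is one dz into the medium."""
        return (np.arange(self.nz) + 1) * self.dz

    @property
    def extent_m(self) -> tuple[float, float, float]:
        return (self.nx * self.dx, self.ny * self.dy, self.nz * self.dz)

    @classmethod
    def from_extent_mm(cls, extent_mm, spacing_mm) -> "Grid3D":
        """Build a grid from physical extents and spacings given in mm."""
        ex, ey, ez = (float(v) * 1e-3 for v in extent_mm)
        dx, dy, dz = (float(v) * 1e-3 for v in spacing_mm)
        return cls(nx=max(1, round(ex / dx)), ny=max(1, round(ey / dy)),
                   nz=max(1, round(ez / dz)), dx=dx, dy=dy, dz=dz)


@dataclass
class LayeredStack:
    """Ordered tissue layers along the propagation (z) axis.

    ``layers`` holds ``(Medium, thickness_m)`` pairs starting at the
    transducer face. ``arterial_temperature_c`` is the perfusing blood
    temperature Ta used by the bio-heat model (°C).
    """

    layers: list[tuple[Medium, float]]
    arterial_temperature_c: float = 37.0
    _snap_warned: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        for medium, thickness in self.layers:
            if thickness <= 0:
                raise ValueError(f"layer {medium.name!r}: thickness must be > 0")

    @property
    def total_thickness(self) -> float:
        return sum(t for _, t in self.layers)

    @property
    def media(self) -> list[Medium]:
        return [m for m, _ in self.layers]

    def interface_depths(self) -> np.ndarray:
        """Cumulative z positions (m) of the interfaces between layers."""
        return np.cumsum([t for _, t in self.layers])[:-1]

    def medium_at(self, z: float) -> Medium:
        """Medium containing depth ``z``; the last layer extends to infinity."""
        depth = 0.0
        for medium, thickness in self.layers:
            depth += thickness
            if z < depth:
                return medium
        return self.layers[-1][0]

    def layer_index_per_plane(self, grid: Grid3D) -> np.ndarray:
        """Layer index for each grid z-plane, with interfaces snapped.

        Each interface is snapped to the nearest plane boundary (midpoint
        between consecutive z-planes). A warning is logged once if a layer
        that starts within the grid depth ends up covering no grid planes
        after snapping (dz coarse relative to a thin layer).
        """
        z = grid.z
        idx = np.zeros(grid.nz, dtype=int)
        for depth in self.interface_depths():
            # plane boundary positions are z - dz/2; planes at z >= snapped
            # depth belong to the next layer
            k = int(np.round((depth - grid.dz / 2) / grid.dz))
            snapped = (k + 0.5) * grid.dz
            idx[z > snapped] += 1
        idx = np.minimum(idx, len(self.layers) - 1)
        if not self._snap_warned:
            counts = np.bincount(idx, minlength=len(self.layers))
            starts = np.concatenate([[0.0], self.interface_depths()])
            for i, count in enumerate(counts):
                if count == 0 and starts[i] < z[-1]:
                    log.warning(
                        "layer %r (%.3f mm thick) covers no grid planes after "
                        "its interfaces were snapped to the %.3f mm plane "
                        "spacing; refine dz or thicken the layer",
                        self.layers[i][0].name, self.layers[i][1] * 1e3,
                        grid.dz * 1e3)
                    self._snap_warned = True
                    break
        return idx

    def min_wavelength(self, frequency_hz: float) -> float:
        """Shortest wavelength across the stack at ``frequency_hz``."""
        return min(m.sound_speed for m in self.media) / frequency_hz
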