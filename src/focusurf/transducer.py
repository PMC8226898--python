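"""Rectangular phased-array geometry and geometric focusing phases.

The array is a rectangular grid of identical rectangular elements tiling
a fixed aperture with a constant kerf (inter-element gap). Elements are
driven at a single continuous-wave frequency with uniform surface normal
velocity; focusing is achieved purely by per-element phase delays chosen
so that contributions from all element centres arrive in phase at the
focal point (straight-ray geometric phasing at a reference sound speed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ArraySpec:
    """Rectangular phased-array geometry (all lengths in metres)."""

    nx_elements: int
    ny_elements: int
    aperture_x: float
    aperture_y: float
    kerf: float

    def __post_init__(self) -> None:
        if self.nx_elements < 1 or self.ny_elements < 1:
            raise ValueError("element counts must be >= 1")
        if self.kerf < 0:
            raise ValueError("kerf must be >= 0")
        if self.element_width <= 0 or self.element_height <= 0:
            raise ValueError("kerf too large: non-positive element dimensions")

    @property
    def element_width(self) -> float:
        """Element size along x: (aperture_x - (nx-1)*kerf) / nx."""
        return (self.aperture_x - (self.nx_elements - 1) * self.kerf) / self.nx_elements

    @property
    def element_height(self) -> float:
        """Element size along y."""
        return (self.aperture_y - (self.ny_elements - 1) * self.kerf) / self.ny_elements

    @property
    def n_elements(self) -> int:
        return self.nx_elements * self.ny_elements

    def element_centers(self) -> np.ndarray:
        """(n_elements, 2) array of element-centre (x, y), symmetric about 0."""
        pitch_x = self.element_width + self.kerf
        pitch_y = self.element_height + self.kerf
        cx = (np.arange(self.nx_elements) - (self.nx_elements - 1) / 2.0) * pitch_x
        cy = (np.arange(self.ny_elements) - (self.ny_elements - 1) / 2.0) * pitch_y
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


def build_array(nx: int, ny: int, aperture_mm: tuple[float, float],
                kerf_um: float) -> ArraySpec:
    """Construct an :class:`ArraySpec` from clinical units (mm aperture, µm kerf)."""
    return ArraySpec(
        nx_elements=nx,
        ny_elements=ny,
        aperture_x=aperture_mm[0] * 1e-3,
        aperture_y=aperture_mm[1] * 1e-3,
        kerf=kerf_um * 1e-6,
    )


@dataclass(frozen=True)
class Excitation:
    """Continuous-wave drive of the array.

    ``frequency`` in Hz, ``v0`` the uniform surface normal velocity (m/s),
    ``phases`` one phase per element (rad, wrapped to [0, 2pi)), ``focus``
    the programmed focal point (x, y, z) in metres.
    """

    frequency: float
    v0: float
    phases: np.ndarray
    focus: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.v0 <= 0:
            raise ValueError("surface velocity must be > 0")
        object.__setattr__(self, "phases", np.mod(np.asarray(self.phases, float), 2 * math.pi))

    @property
    def omega(self) -> float:
        return 2 * math.pi * self.frequency


def focus_phases(array: ArraySpec, focus: tuple[float, float, float],
                 c_ref: float, frequency: float) -> np.ndarray:
    """Per-element phases that align all contributions at ``focus``.

    phi_n = k_ref * d_n (mod 2pi), d_n the distance from element centre n
    to the focal point and k_ref = 2*pi*f/c_ref. The common propagation
    phase e^{-j k d_n} is then cancelled by e^{+j phi_n} so every element
    arrives at the focus with the same phase.

    ``c_ref`` should be the sound speed of the couplant layer; no layered
    refraction correction is applied.
    """
    if focus[2] <= 0:
        raise ValueError("focus must lie at z > 0")
    if c_ref <= 0 or frequency <= 0:
        raise ValueError("c_ref and frequency must be > 0")
    centers = array.element_centers()
    fx, fy, fz = focus
    d = np.sqrt((centers[:, 0] - fx) ** 2 + (centers[:, 1] - fy) ** 2 + fz ** 2)
    k_ref = 2 * math.pi * frequency / c_ref
    return np.mod(k_ref * d, 2 * math.pi)


def make_excitation(array: ArraySpec, frequency: float,
                    focus: tuple[float, float, float], c_ref: float,
                    v0: float = 1.0) -> Excitation:
    """Convenience: geometric focusing phases wrapped into an Excitation."""
    return Excitation(frequency=frequency, v0=v0,
                      phases=focus_phases(array, focus, c_ref, frequency),
                      focus=focus)
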