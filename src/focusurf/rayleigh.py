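"""Rayleigh–Sommerfeld source-plane computation.

The time-harmonic pressure radiated by a baffled planar source into a
half-space is the Rayleigh–Sommerfeld integral

    p(r) = (j rho c k / 2 pi) * Int_S v_n(r') e^{-jkR} / R dS',

discretised by midpoint quadrature over rectangular sub-sources no larger
than lambda/4. The angular-spectrum propagator takes as its input the
complex pressure on a single plane one quarter wavelength in front of the
array (evaluating the integral directly on that plane avoids the
singularity and the worst of the near-field sampling error); the same
summation evaluated at arbitrary 3D points serves as a brute-force
reference field in tests. Phasor convention: e^{+j omega t} time factor
(dropped), spatial factor e^{-jkR}.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .media import Grid3D, Medium
from .transducer import ArraySpec, Excitation

log = logging.getLogger(__name__)

_CHUNK = 2_000_000  # max subsource x field-point products per vectorised block


@dataclass
class ComplexPlane:
    """Complex continuous-wave pressure on one z-plane.

    ``values`` has shape (nx, ny) in Pa (phasor amplitude); ``x``/``y``
    are the lateral coordinates (m); ``z`` the plane position (m).
    """

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, complex)
        if self.values.shape != (len(self.x), len(self.y)):
            raise ValueError("plane shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite pressure values")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if len(self.x) > 1 else 0.0

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if len(self.y) > 1 else 0.0


def subsource_quadrature(array: ArraySpec, exc: Excitation, medium: Medium,
                         max_spacing: float | None = None):
    """Midpoint quadrature nodes over the radiating surface.

    Each element is subdivided into an integer grid of sub-rectangles whose
    pitch does not exceed ``max_spacing`` (default lambda/4 in ``medium``).
    Returns (positions (M, 2) m, complex element drive per node (M,),
    area per node (M,)).
    """
    lam = medium.wavelength(exc.frequency)
    if max_spacing is None:
        max_spacing = lam / 4.0
    ew, eh = array.element_width, array.element_height
    nsx = max(1, math.ceil(ew / max_spacing))
    nsy = max(1, math.ceil(eh / max_spacing))
    if ew / nsx > lam / 2 or eh / nsy > lam / 2:
        log.warning("sub-source spacing exceeds lambda/2; quadrature may be coarse")
    # local offsets of sub-source midpoints within one element
    ox = (np.arange(nsx) + 0.5) * (ew / nsx) - ew / 2
    oy = (np.arange(nsy) + 0.5) * (eh / nsy) - eh / 2
    gx, gy = np.meshgrid(ox, oy, indexing="ij")
    offsets = np.column_stack([gx.ravel(), gy.ravel()])

    centers = array.element_centers()
    pos = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    drive = np.repeat(exc.v0 * np.exp(1j * exc.phases), offsets.shape[0])
    area = np.full(pos.shape[0], (ew / nsx) * (eh / nsy))
    return pos, drive, area


def _rs_sum(points: np.ndarray, pos: np.ndarray, drive: np.ndarray,
            area: np.ndarray, k: float, prefactor: complex) -> np.ndarray:
    """Chunked brute-force Rayleigh–Sommerfeld summation at 3D ``points``."""
    n_pts = points.shape[0]
    out = np.zeros(n_pts, complex)
    step = max(1, _CHUNK // max(1, pos.shape[0]))
    weights = drive * area
    for start in range(0, n_pts, step):
        blk = points[start:start + step]
        dx = blk[:, 0:1] - pos[None, :, 0]
        dy = blk[:, 1:2] - pos[None, :, 1]
        r = np.sqrt(dx * dx + dy * dy + blk[:, 2:3] ** 2)
        out[start:start + step] = (np.exp(-1j * k * r) / r) @ weights
    return prefactor * out


def direct_field_oracle(array: ArraySpec, exc: Excitation, medium: Medium,
                        points: np.ndarray,
                        max_spacing: float | None = None) -> np.ndarray:
    """Brute-force Rayleigh–Sommerfeld field at arbitrary points (z > 0).

    Reference implementation used to validate the spectral propagator; it
    sums every sub-source contribution at every point and scales as
    O(M*N), so keep it to small problems.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if np.any(points[:, 2] <= 0):
        raise ValueError("all field points must lie at z > 0")
    pos, drive, area = subsource_quadrature(array, exc, medium, max_spacing)
    k = exc.omega / medium.sound_speed
    prefactor = 1j * medium.density * medium.sound_speed * k / (2 * math.pi)
    return _rs_sum(points, pos, drive, area, k, prefactor)


def rayleigh_plane(array: ArraySpec, exc: Excitation, medium: Medium,
                   grid: Grid3D, max_spacing: float | None = None) -> ComplexPlane:
    """Source pressure plane at z0 = lambda/4 on the grid's x/y lattice."""
    lam = medium.wavelength(exc.frequency)
    z0 = lam / 4.0
    x, y = grid.x, grid.y
    gx, gy = np.meshgrid(x, y, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z0)])
    vals = direct_field_oracle(array, exc, medium, pts, max_spacing)
    return ComplexPlane(values=vals.reshape(len(x), len(y)), x=x, y=y, z=z0)
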