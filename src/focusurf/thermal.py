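"""Acoustic intensity, power deposition and steady-state bio-heat transfer.

A continuous-wave pressure field deposits heat at a volumetric rate
Q = 2*alpha*I_A with I_A = |p|^2 / (2 rho c) the time-averaged intensity.
The steady temperature follows the Pennes bio-heat balance with the time
derivative set to zero,

    -div(k_t grad T) + Wb*Cb*(T - Ta) = Q,

i.e. conduction against a distributed blood-perfusion sink that pulls the
tissue back toward the arterial temperature Ta. The solver discretises
this on the simulation grid with a 7-point finite-difference stencil,
harmonic-mean conductivity at layer interfaces and Dirichlet T = Ta on all
outer boundaries, and solves the resulting symmetric positive-definite
sparse system (direct LU for small grids, Jacobi-preconditioned conjugate
gradients for large ones). The factorisation depends only on the stack and
grid, so one :class:`BioheatSolver` can be reused across a parameter sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .media import Grid3D, LayeredStack, attenuation_np_per_m
from .asm import PressureField3D

log = logging.getLogger(__name__)

_DIRECT_LIMIT = 60_000  # unknowns above which CG replaces the direct solve


@dataclass
class ScalarField3D:
    """Real-valued field over the grid with a role tag.

    Roles: ``intensity`` (W/m^2), ``power_deposition`` (W/m^3),
    ``temperature`` (°C).
    """

    values: np.ndarray
    grid: Grid3D
    role: str
    layer_index: np.ndarray | None = None

    def max(self) -> float:
        return float(np.max(self.values))


def intensity(pressure: PressureField3D, stack: LayeredStack) -> ScalarField3D:
    """Time-averaged acoustic intensity I_A = |p|^2 / (2 rho0 c), W/m^2.

    rho0 and c are the local layer properties of each z-plane.
    """
    rho_c = np.array([m.density * m.sound_speed
                      for m in stack.media])[pressure.layer_index]
    vals = np.abs(pressure.values) ** 2 / (2.0 * rho_c[None, None, :])
    return ScalarField3D(values=vals, grid=pressure.grid, role="intensity",
                         layer_index=pressure.layer_index)


def power_deposition(ia: ScalarField3D, stack: LayeredStack,
                     frequency_mhz: float) -> ScalarField3D:
    """Volumetric heating rate Q = 2 alpha I_A, W/m^3 (alpha per layer)."""
    if ia.layer_index is None:
        raise ValueError("intensity field lacks layer labels")
    alpha = np.array([attenuation_np_per_m(m, frequency_mhz)
                      for m in stack.media])[ia.layer_index]
    return ScalarField3D(values=2.0 * alpha[None, None, :] * ia.values,
                         grid=ia.grid, role="power_deposition",
                         layer_index=ia.layer_index)


class BioheatSolver:
    """Steady Pennes operator for a fixed stack and grid, reusable across Q.

    Solves (-div k_t grad + Wb*Cb) u = Q for the rise u = T - Ta with
    u = 0 (T = Ta) on all boundaries.
    """

    def __init__(self, stack: LayeredStack, grid: Grid3D):
        self.stack = stack
        self.grid = grid
        self.layer_index = stack.layer_index_per_plane(grid)
        self._matrix = self._assemble()
        self._n = self._matrix.shape[0]
        if self._n <= _DIRECT_LIMIT:
            self._solve = spla.factorized(self._matrix.tocsc())
            self._mode = "direct"
        else:
            self._csr = self._matrix.tocsr()
            self._diag_inv = 1.0 / self._matrix.diagonal()
            self._mode = "cg"

    def _assemble(self) -> sp.spmatrix:
        g = self.grid
        nx, ny, nz = g.nx, g.ny, g.nz
        media = self.stack.media
        kt_z = np.array([m.thermal_conductivity for m in media])[self.layer_index]
        wbcb_z = np.array([m.blood_perfusion * m.blood_specific_heat
                           for m in media])[self.layer_index]

        kt = np.broadcast_to(kt_z[None, None, :], (nx, ny, nz))
        wbcb = np.broadcast_to(wbcb_z[None, None, :], (nx, ny, nz))

        n = nx * ny * nz
        idx = np.arange(n).reshape(nx, ny, nz)
        diag = wbcb.astype(float).copy()
        rows, cols, vals = [], [], []

        def add_faces(axis: int, h: float) -> None:
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(0, -1)
            sl_b[axis] = slice(1, None)
            ka = kt[tuple(sl_a)]
            kb = kt[tuple(sl_b)]
            kf = 2.0 * ka * kb / (ka + kb)  # harmonic mean at the face
            w = kf / h ** 2
            ia = idx[tuple(sl_a)].ravel()
            ib = idx[tuple(sl_b)].ravel()
            wf = w.ravel()
            rows.extend([ia, ib])
            cols.extend([ib, ia])
            vals.extend([-wf, -wf])
            np.add.at(diag, tuple(sl_a), w)
            np.add.at(diag, tuple(sl_b), w)

        def add_boundary(axis: int, h: float) -> None:
            # Dirichlet ghost cells: face coupling stays on the diagonal
            for side in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = side
                diag[tuple(sl)] += kt[tuple(sl)] / h ** 2

        for axis, h in ((0, g.dx), (1, g.dy), (2, g.dz)):
            add_faces(axis, h)
            add_boundary(axis, h)

        rows.append(idx.ravel())
        cols.append(idx.ravel())
        vals.append(diag.ravel())
        a = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        return a.tocsc()

    def solve_rise(self, q: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
        """Temperature rise u = T - Ta (K) for heating rate ``q`` (W/m^3)."""
        q = np.asarray(q, float)
        if q.shape != self.grid.shape:
            raise ValueError("Q shape does not match grid")
        if not np.all(np.isfinite(q)):
            raise ValueError("Q must be finite")
        b = q.ravel()
        if not np.any(b):
            return np.zeros(self.grid.shape)
        if self._mode == "direct":
            u = self._solve(b)
        else:
            m = spla.LinearOperator((self._n, self._n),
                                    matvec=lambda v: self._diag_inv * v)
            u, info = spla.cg(self._csr, b, rtol=rtol, atol=0.0, M=m,
                              maxiter=20_000)
            if info != 0:
                res = np.linalg.norm(self._csr @ u - b) / np.linalg.norm(b)
                raise RuntimeError(
                    f"bio-heat CG did not converge (info={info}, "
                    f"relative residual {res:.3e})")
        return u.reshape(self.grid.shape)


def steady_bioheat(q: ScalarField3D, stack: LayeredStack, grid: Grid3D,
                   solver: BioheatSolver | None = None) -> ScalarField3D:
    """Steady-state temperature field T (°C) for power deposition ``q``."""
    if solver is None:
        solver = BioheatSolver(stack, grid)
    rise = solver.solve_rise(q.values)
    temp = stack.arterial_temperature_c + rise
    return ScalarField3D(values=temp, grid=grid, role="temperature",
                         layer_index=solver.layer_index)


def contour_width(temperature: ScalarField3D, rise_level: float,
                  baseline_c: float | None = None,
                  plane_y_index: int | None = None) -> float:
    """Maximum lateral extent (mm) of the connected iso-rise contour.

    Works on the axial x-z slice through the hottest voxel (or through
    ``plane_y_index``). The contour at ``rise_level`` (K above baseline)
    is the connected region containing the peak; its lateral extent per
    z-row is refined by linear interpolation between grid columns, and the
    maximum over rows is returned in mm. Returns 0.0 (with a warning) when
    the peak rise is below the level.
    """
    vals = temperature.values
    if baseline_c is None:
        baseline_c = float(np.min(vals))
    rise = vals - baseline_c
    pk = np.unravel_index(np.argmax(rise), rise.shape)
    iy = pk[1] if plane_y_index is None else plane_y_index
    sl = rise[:, iy, :]  # (nx, nz)
    peak_xy = np.unravel_index(np.argmax(sl), sl.shape)
    if sl[peak_xy] < rise_level:
        log.warning("contour level %.3g K exceeds peak rise %.3g K",
                    rise_level, sl[peak_xy])
        return 0.0

    labels, _ = ndimage.label(sl >= rise_level)
    blob = labels == labels[peak_xy]
    dx_mm = temperature.grid.dx * 1e3
    width = 0.0
    nx = sl.shape[0]
    for iz in np.flatnonzero(blob.any(axis=0)):
        cols = np.flatnonzero(blob[:, iz])
        lo, hi = cols[0], cols[-1]
        left = float(lo)
        if lo > 0:
            f = (rise_level - sl[lo - 1, iz]) / (sl[lo, iz] - sl[lo - 1, iz])
            left = lo - 1 + f
        right = float(hi)
        if hi < nx - 1 and sl[hi + 1, iz] < rise_level:
            f = (sl[hi, iz] - rise_level) / (sl[hi, iz] - sl[hi + 1, iz])
            right = hi + f
        width = max(width, (right - left) * dx_mm)
    return width
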