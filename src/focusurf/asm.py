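"""Angular-spectrum propagation through layered tissue.

The complex source plane is decomposed into plane waves by a zero-padded
2D FFT; each spectral component (kx, ky) is marched plane-by-plane along z
with the forward transfer function

    H = exp(-j dz sqrt(k^2 - kx^2 - ky^2))        propagating branch
    H = exp(-dz sqrt(kx^2 + ky^2 - Re(k)^2))      evanescent branch,

where attenuation enters through a complex wavenumber k = omega/c - j*alpha.
At every layer interface the spectrum is multiplied by the plane-wave
pressure transmission coefficient evaluated per component from its
incidence angle (Snell refraction of the component's transverse
wavenumber); reflected waves are discarded (forward-only marching). A
smooth angular low-pass taper suppresses components steep enough to wrap
around the padded aperture over the marching distance, the conventional
remedy for FFT aliasing in spectral propagators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .media import Grid3D, LayeredStack, Medium, attenuation_np_per_m
from .rayleigh import ComplexPlane
from .transducer import Excitation

log = logging.getLogger(__name__)


@dataclass
class PressureField3D:
    """Complex continuous-wave pressure over the whole grid.

    ``values`` has shape (nx, ny, nz) in Pa; ``layer_index`` gives the
    tissue-layer index of each z-plane.
    """

    values: np.ndarray
    grid: Grid3D
    layer_index: np.ndarray
    stack: LayeredStack

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def medium_names(self) -> list[str]:
        return [self.stack.media[i].name for i in self.layer_index]


def complex_wavenumber(medium: Medium, frequency: float) -> complex:
    """k = omega/c - j*alpha at ``frequency`` (Hz) in ``medium``."""
    alpha = attenuation_np_per_m(medium, frequency / 1e6)
    return 2 * math.pi * frequency / medium.sound_speed - 1j * alpha


def transfer_function(kx: np.ndarray, ky: np.ndarray, dz: float,
                      k: complex) -> np.ndarray:
    """Spectral forward-propagation factor H(kx, ky) over a step ``dz``.

    ``kx`` and ``ky`` broadcast against each other (pass a column and a row
    for a full 2D transfer matrix). The branch split uses Re(k): components
    inside the radiation circle propagate with phase (and attenuation via
    the imaginary part of ``k``); components outside decay exponentially.
    """
    if dz <= 0:
        raise ValueError("propagation step must be > 0")
    kx = np.asarray(kx, float)
    ky = np.asarray(ky, float)
    kr2 = kx ** 2 + ky ** 2
    k_re = np.real(k)
    propagating = kr2 <= k_re ** 2
    kz = np.sqrt(np.asarray(k ** 2 - kr2, complex))
    # principal sqrt of k^2-kr2 with Im(k)<=0 lands in the fourth quadrant,
    # so exp(-j dz kz) both advances phase and decays
    h_prop = np.exp(-1j * dz * kz)
    h_evan = np.exp(-dz * np.sqrt(np.maximum(kr2 - k_re ** 2, 0.0)))
    return np.where(propagating, h_prop, h_evan)


def transmission_matrix(k_a: float, medium_a: Medium, medium_b: Medium,
                        kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
    """Plane-wave pressure transmission coefficient per spectral component.

    The transverse wavenumber of a component sets its incidence angle on a
    z-normal interface, sin(theta_in) = sqrt(kx^2+ky^2)/Re(k_a); Snell
    refraction in medium B gives theta_out, and the oblique transmission
    coefficient is

        T = 2 * (Z_a cos(theta_out) / (Z_b cos(theta_in)) + 1)^-1
          = 2 Z_b cos(theta_in) / (Z_b cos(theta_in) + Z_a cos(theta_out)).

    Totally reflected components (sin(theta_out) > 1) and evanescent
    components (sin(theta_in) > 1) are assigned T = 0.
    """
    kx = np.asarray(kx, float)
    ky = np.asarray(ky, float)
    k_re = float(np.real(k_a))
    sin_in = np.sqrt(kx ** 2 + ky ** 2) / k_re
    with np.errstate(invalid="ignore"):
        cos_in = np.sqrt(np.maximum(1.0 - sin_in ** 2, 0.0))
        sin_out = (medium_b.sound_speed / medium_a.sound_speed) * sin_in
        cos_out = np.sqrt(np.maximum(1.0 - sin_out ** 2, 0.0))
    z_a = medium_a.impedance
    z_b = medium_b.impedance
    num = 2.0 * z_b * cos_in
    den = z_b * cos_in + z_a * cos_out
    t = np.divide(num, den, out=np.zeros(np.broadcast(kx, ky).shape), where=den > 0)
    t = np.where((sin_in > 1.0) | (sin_out > 1.0), 0.0, t)
    return t


def _angular_taper(kx: np.ndarray, ky: np.ndarray, k_re: float,
                   sin_max_x: float, sin_max_y: float) -> np.ndarray:
    """Smooth separable low-pass over propagation angle.

    Raised-cosine roll-off from 90% to 100% of the cutoff transverse
    wavenumber in each lateral axis; the cutoff angle is the steepest ray
    that stays inside the padded aperture over the marching distance.
    """
    def taper_1d(kt: np.ndarray, kc: float) -> np.ndarray:
        a = np.abs(kt)
        w = np.ones_like(a)
        lo = 0.9 * kc
        band = (a > lo) & (a < kc)
        w[band] = 0.5 * (1 + np.cos(math.pi * (a[band] - lo) / (kc - lo)))
        w[a >= kc] = 0.0
        return w

    return taper_1d(kx, k_re * sin_max_x) * taper_1d(ky, k_re * sin_max_y)


def propagate_stack(source: ComplexPlane, stack: LayeredStack, grid: Grid3D,
                    exc: Excitation, pad_factor: int = 2,
                    angular_filter: bool = True) -> PressureField3D:
    """March the source plane through the stack, producing the 3D field.

    The spectrum is kept in the padded spatial-frequency domain for the
    whole march; each stored plane is an inverse FFT cropped back to the
    grid. A step that crosses a (grid-snapped) layer interface is split at
    the interface: half-step in the incident medium, transmission
    coefficient, half-step in the new medium.
    """
    f = exc.frequency
    lam_min = stack.min_wavelength(f)
    if grid.dx > lam_min / 2 or grid.dy > lam_min / 2:
        raise ValueError(
            f"lateral grid spacing undersamples the field: need dx,dy <= "
            f"{lam_min / 2:.3e} m at {f / 1e6:.3g} MHz")
    if source.z >= grid.z[0]:
        raise ValueError("first grid plane must lie beyond the source plane")

    npx = pad_factor * grid.nx
    npy = pad_factor * grid.ny
    ox = (npx - grid.nx) // 2
    oy = (npy - grid.ny) // 2
    padded = np.zeros((npx, npy), complex)
    padded[ox:ox + grid.nx, oy:oy + grid.ny] = source.values

    kx = 2 * math.pi * np.fft.fftfreq(npx, grid.dx)[:, None]
    ky = 2 * math.pi * np.fft.fftfreq(npy, grid.dy)[None, :]

    layer_idx = stack.layer_index_per_plane(grid)
    media = stack.media
    k_of = {i: complex_wavenumber(m, f) for i, m in enumerate(media)}

    # steepest ray that stays inside the padded aperture over the march
    z_span = float(grid.z[-1])
    half_x = npx * grid.dx / 2
    half_y = npy * grid.dy / 2
    sin_max_x = half_x / math.hypot(half_x, z_span)
    sin_max_y = half_y / math.hypot(half_y, z_span)

    spectrum = np.fft.fft2(padded)
    field = np.empty((grid.nx, grid.ny, grid.nz), complex)

    tapers: dict[int, np.ndarray] = {}
    prev_idx = layer_idx[0]
    z_prev = source.z
    for iz in range(grid.nz):
        cur_idx = int(layer_idx[iz])
        dz_step = float(grid.z[iz]) - z_prev
        if cur_idx == prev_idx:
            spectrum = spectrum * transfer_function(kx, ky, dz_step, k_of[cur_idx])
        else:
            # snapped interface sits midway through this step
            spectrum = spectrum * transfer_function(kx, ky, dz_step / 2, k_of[prev_idx])
            spectrum = spectrum * transmission_matrix(
                np.real(k_of[prev_idx]), media[prev_idx], media[cur_idx], kx, ky)
            spectrum = spectrum * transfer_function(kx, ky, dz_step / 2, k_of[cur_idx])
        if angular_filter:
            if cur_idx not in tapers:
                tapers[cur_idx] = _angular_taper(
                    kx, ky, float(np.real(k_of[cur_idx])), sin_max_x, sin_max_y)
            spectrum = spectrum * tapers[cur_idx]
        plane = np.fft.ifft2(spectrum)
        field[:, :, iz] = plane[ox:ox + grid.nx, oy:oy + grid.ny]
        prev_idx = cur_idx
        z_prev = float(grid.z[iz])

    return PressureField3D(values=field, grid=grid, layer_index=layer_idx,
                           stack=stack)
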