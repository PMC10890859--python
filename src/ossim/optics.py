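"""Optical model: Born-Wolf point spread functions, OTFs and striped illumination.

All physical lengths are in nanometres unless a name says otherwise; spatial
frequencies are in cycles per micrometre, which is the natural unit at the
scale of a high-NA microscope field of view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0


class InvalidOpticsError(ValueError):
    """Raised when optical parameters are physically inconsistent."""


@dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the objective and sampling grid.

    Attributes
    ----------
    numerical_aperture : dimensionless, must satisfy 0 < NA < refractive_index.
    emission_wavelength : nm, fluorescence detection wavelength.
    excitation_wavelength : nm, laser wavelength forming the stripe pattern.
    refractive_index : immersion/sample refractive index.
    voxel_size : (z, y, x) sampling in nm.
    """

    numerical_aperture: float = 1.2
    emission_wavelength: float = 600.0
    excitation_wavelength: float = 488.0
    refractive_index: float = 1.33
    voxel_size: tuple[float, float, float] = (86.0, 86.0, 86.0)

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture:
            raise InvalidOpticsError("numerical aperture must be positive")
        if self.numerical_aperture >= self.refractive_index:
            raise InvalidOpticsError(
                f"NA={self.numerical_aperture} must be smaller than the "
                f"refractive index {self.refractive_index}"
            )
        if self.emission_wavelength <= 0 or self.excitation_wavelength <= 0:
            raise InvalidOpticsError("wavelengths must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidOpticsError("voxel sizes must be positive")

    @property
    def lateral_cutoff(self) -> float:
        """Incoherent lateral cutoff 2 NA / lambda_em, cycles/um."""
        return 2.0 * self.numerical_aperture / (self.emission_wavelength * 1e-3)


@dataclass
class PSF3D:
    """Intensity point spread function sampled on a (z, y, x) grid.

    Normalised so the voxel sum is 1; the focal plane is ``focus_index``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    focus_index: int = 0

    def plane(self, defocus_nm: float = 0.0) -> np.ndarray:
        """Return the 2D PSF slice at the given defocus, renormalised to sum 1.

        Used by the two-plane image-formation model, where the out-of-focus
        contribution is blurred with a defocused slice of the 3D PSF.
        """
        dz = self.voxel_size[0]
        idx = self.focus_index + int(round(defocus_nm / dz))
        idx = int(np.clip(idx, 0, self.data.shape[0] - 1))
        sl = self.data[idx]
        return sl / sl.sum()


@dataclass
class OTF3D:
    """Complex optical transfer function on a (kz, ky, kx) grid.

    ``data`` is the FFT of the (centred) PSF with the DC component at index
    (0, 0, 0) and normalised so OTF(0,0,0) = 1. ``freq_spacing`` is the grid
    spacing in cycles/um along (kz, ky, kx).
    """

    data: np.ndarray
    freq_spacing: tuple[float, float, float]


@dataclass(frozen=True)
class SinusoidalPattern:
    """Striped excitation pattern: (1 + m cos(2 pi nu (x cos t + y sin t) + phi)) / 2.

    The pattern is normalised to mean 1/2 so that averaging the three phase
    images reproduces exactly half the uniformly illuminated image.
    """

    spatial_frequency: float  # cycles/um
    orientation: float = 0.0  # rad
    modulation_depth: float = 1.0
    phase_offsets: tuple[float, ...] = field(
        default=(0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")
        if self.spatial_frequency < 0:
            raise ValueError("spatial frequency must be nonnegative")


def optimal_pattern_frequency(config: OpticalConfig) -> float:
    """Stripe frequency giving the best sectioning: half the detection cutoff.

    The maximum spatial frequency the microscope passes is 2 NA / lambda; the
    sectioning strength of a striped pattern is maximised when the stripe sits
    at half that, i.e. NA / lambda_exc, returned in cycles/um.
    """
    return config.numerical_aperture / (config.excitation_wavelength * 1e-3)


def render_pattern(
    pattern: SinusoidalPattern,
    shape: tuple[int, int],
    phase_index: int,
    pixel_size_nm: float = 86.0,
) -> np.ndarray:
    """Render one phase of the stripe pattern on a (y, x) pixel grid."""
    n_phases = len(pattern.phase_offsets)
    if not 0 <= phase_index < n_phases:
        raise IndexError(
            f"phase_index {phase_index} out of range for {n_phases} phase offsets"
        )
    ny, nx = shape
    px_um = pixel_size_nm * 1e-3
    y = np.arange(ny)[:, None] * px_um
    x = np.arange(nx)[None, :] * px_um
    proj = x * np.cos(pattern.orientation) + y * np.sin(pattern.orientation)
    phase = 2.0 * np.pi * pattern.spatial_frequency * proj
    phase = phase + pattern.phase_offsets[phase_index]
    return 0.5 * (1.0 + pattern.modulation_depth * np.cos(phase))


def _born_wolf_planes(
    config: OpticalConfig,
    radii_nm: np.ndarray,
    z_nm: np.ndarray,
    n_quad: int = 128,
) -> np.ndarray:
    """Evaluate the scalar Born-Wolf defocus integral on (z, r) points.

    h(r, z) = | int_0^1 J0(k NA r rho) exp(-i k z rho^2 NA^2 / (2 n)) rho drho |^2

    with k = 2 pi / lambda_em. Gauss-Legendre quadrature over the normalised
    aperture coordinate rho.
    """
    na = config.numerical_aperture
    k = 2.0 * np.pi / config.emission_wavelength
    nodes, weights = leggauss(n_quad)
    rho = 0.5 * (nodes + 1.0)  # map [-1,1] -> [0,1]
    w = 0.5 * weights * rho  # include the rho Jacobian
    bessel = j0(k * na * radii_nm[:, None] * rho[None, :])  # (nr, nq)
    defocus = np.exp(
        -1j * k * z_nm[:, None] * rho[None, :] ** 2 * na**2 / (2.0 * config.refractive_index)
    )  # (nz, nq)
    # amplitude[z, r] = sum_q w_q * bessel[r, q] * defocus[z, q]
    amp = defocus @ (bessel * w[None, :]).T
    return np.abs(amp) ** 2


def compute_psf(config: OpticalConfig, shape: tuple[int, int, int]) -> PSF3D:
    """Compute the 3D widefield intensity PSF on a (z, y, x) voxel grid.

    The lateral focus sits at the central voxel, so ``shape`` must be odd in
    y and x; an even z count is allowed with the focal plane at z // 2.
    Emits a warning (not an error) when the lateral extent is too small to
    contain the first Airy ring.
    """
    nz, ny, nx = shape
    if ny % 2 == 0 or nx % 2 == 0:
        raise ValueError("PSF shape must be odd in y and x so the focus is a grid point")
    dz, dy, dx = config.voxel_size
    airy_radius = 0.61 * config.emission_wavelength / config.numerical_aperture
    if min((ny // 2) * dy, (nx // 2) * dx) < airy_radius:
        warnings.warn(
            "PSF grid half-extent is smaller than the first Airy ring "
            f"({airy_radius:.0f} nm); the PSF will be truncated",
            stacklevel=2,
        )
    focus = nz // 2
    z = (np.arange(nz) - focus) * dz
    yy = (np.arange(ny) - ny // 2) * dy
    xx = (np.arange(nx) - nx // 2) * dx
    r = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)
    r_unique, inverse = np.unique(np.round(r, 6), return_inverse=True)
    planes = _born_wolf_planes(config, r_unique, z)  # (nz, nr)
    vol = planes[:, inverse].reshape(nz, ny, nx)
    vol /= vol.sum()
    return PSF3D(data=vol, voxel_size=config.voxel_size, focus_index=focus)


def compute_otf(psf: PSF3D) -> OTF3D:
    """Fourier transform of the PSF, DC-normalised.

    The PSF is shifted so its focal voxel sits at the origin before the FFT,
    making the spectrum of the (real, nearly centrosymmetric) PSF close to
    real near DC and Hermitian-symmetric exactly.
    """
    vol = psf.data
    total = vol.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        warnings.warn("PSF is not normalised; rescaling before the OTF", stacklevel=2)
        vol = vol / total
    nz, ny, nx = vol.shape
    centred = np.roll(vol, (-psf.focus_index, -(ny // 2), -(nx // 2)), axis=(0, 1, 2))
    spec = np.fft.fftn(centred)
    spec /= spec[0, 0, 0]
    dz, dy, dx = psf.voxel_size
    spacing = (1e3 / (nz * dz), 1e3 / (ny * dy), 1e3 / (nx * dx))
    return OTF3D(data=spec, freq_spacing=spacing)
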