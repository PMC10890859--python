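"""OS-SIM image formation: patterned excitation, blurring, plane mixing, noise.

The model follows the standard two-plane picture for single-plane data (an
in-focus structure and an out-of-focus background, each excited by the stripe
pattern and blurred by the appropriate PSF slice, then mixed with a weight),
and a full 3D convolution for volumetric scans. Stripe modulation depth decays
axially with a Gaussian envelope m(z) = m0 exp(-(z/z_m)^2), z_m = n lambda_exc
/ NA^2 — the rapid loss of pattern contrast away from focus that makes
optical sectioning possible in the first place.

Noise is Poisson photon statistics plus additive Gaussian read noise: the
noise-free stack is scaled so its maximum equals ``peak_intensity_norm``
(1e-6), each pixel is replaced by a Poisson draw with mean value * eta * 1e12,
and zero-mean Gaussian counts are added. The signal level is controlled by
the Poisson factor eta: peak expected photon counts are eta * 1e6 (100
photons at eta = 1e-4, 20 at 2e-5, 5 at 5e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.signal import fftconvolve

from ossim.optics import (
    OpticalConfig,
    PSF3D,
    SinusoidalPattern,
    compute_psf,
    render_pattern,
)
from ossim.phantom import (
    TEXTURE_KINDS,
    MovingTriplet,
    Phantom3D,
    generate_moving_triplet,
    generate_texture,
)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian + Poisson detection noise.

    ``gaussian_sigma`` is the read-noise standard deviation in photon counts
    and is independent of the signal level, so sweeping ``poisson_factor``
    varies shot noise against a fixed Gaussian floor. ``photon_scale`` is the
    fixed 1e12 conversion between normalised intensity and expected counts;
    ``peak_intensity_norm`` (1e-6) is the value the stack maximum is scaled
    to before Poisson sampling.
    """

    gaussian_sigma: float = 1.0
    poisson_factor: float = 1e-4
    photon_scale: float = 1e12
    peak_intensity_norm: float = 1e-6

    def __post_init__(self) -> None:
        if self.poisson_factor <= 0:
            raise ValueError("poisson factor eta must be positive")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian sigma must be nonnegative")

    @property
    def peak_photons(self) -> float:
        """Expected photon count at the brightest pixel."""
        return self.poisson_factor * self.photon_scale * self.peak_intensity_norm


@dataclass
class OSSimStack:
    """Raw phase-stepped frames with the metadata needed to reconstruct them.

    ``data`` is indexed by ``axes``, which always ends in "pyx" (phase, y, x)
    and may be prefixed by "z" and/or "t". Exactly three phase frames per
    plane/timepoint.
    """

    data: np.ndarray
    axes: str = "pyx"
    pattern: SinusoidalPattern | None = None
    optics: OpticalConfig | None = None
    noise: NoiseModel | None = None
    pixel_size_nm: float = 86.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.axes.endswith("pyx"):
            raise ValueError(f"axes {self.axes!r} must end with 'pyx'")
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dims but axes {self.axes!r} has {len(self.axes)}"
            )
        if self.data.shape[self.axes.index("p")] != 3:
            raise ValueError("exactly 3 phase frames are required")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    def phase_frames(self) -> np.ndarray:
        """The (3, y, x) frames of a single-plane stack."""
        if self.axes != "pyx":
            raise ValueError(f"stack has axes {self.axes!r}; index a plane first")
        return self.data

    def plane(self, index: int) -> "OSSimStack":
        """Extract one leading-axis plane (z or t) as a single-plane stack."""
        if self.axes == "pyx":
            raise ValueError("stack has no leading axis")
        return replace(self, data=self.data[index], axes=self.axes[1:])

    @property
    def n_planes(self) -> int:
        return 1 if self.axes == "pyx" else self.data.shape[0]


def modulation_envelope(z_nm: float | np.ndarray, config: OpticalConfig) -> np.ndarray:
    """Axial decay of stripe modulation: exp(-(z / z_m)^2), z_m = n lambda_exc / NA^2."""
    z_m = config.refractive_index * config.excitation_wavelength / config.numerical_aperture**2
    return np.exp(-((np.asarray(z_nm, dtype=float) / z_m) ** 2))


def _blur2d(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if kernel.shape == (1, 1):  # delta kernel: identity blur, exact
        return image * kernel[0, 0]
    return fftconvolve(image, kernel, mode="same")


def simulate_stack(
    in_focus: np.ndarray,
    out_of_focus: np.ndarray | None,
    psf_in: np.ndarray,
    psf_out: np.ndarray | None,
    pattern: SinusoidalPattern,
    oof_weight: float = 0.5,
    pixel_size_nm: float = 86.0,
    oof_modulation_scale: float = 0.0,
    in_focus_frames: np.ndarray | None = None,
    optics: OpticalConfig | None = None,
) -> OSSimStack:
    """Noise-free two-plane OS-SIM triplet.

    frame_n = blur(in_focus * P_n, psf_in)
              + oof_weight * blur(out_of_focus * P'_n, psf_out)

    where P_n is the n-th phase of the stripe pattern and P'_n the same
    pattern with its modulation depth multiplied by ``oof_modulation_scale``
    (the axial envelope at the background's defocus; out-of-focus structure
    sees almost no stripe contrast).

    ``in_focus_frames`` optionally supplies a distinct in-focus image per
    phase (shape (3, y, x)) to model samples that move between exposures.
    """
    if in_focus_frames is not None:
        frames_in = np.asarray(in_focus_frames, dtype=float)
        if frames_in.shape[0] != 3:
            raise ValueError("in_focus_frames must have shape (3, y, x)")
        in_focus = frames_in[0]
    shape = np.asarray(in_focus).shape
    if out_of_focus is not None and np.asarray(out_of_focus).shape != shape:
        raise ValueError(
            f"in-focus {shape} and out-of-focus {np.asarray(out_of_focus).shape} shapes differ"
        )
    if oof_weight < 0:
        raise ValueError("oof_weight must be nonnegative")
    oof_pattern = replace(
        pattern, modulation_depth=pattern.modulation_depth * oof_modulation_scale
    )
    frames = []
    for n in range(3):
        plane_in = in_focus if in_focus_frames is None else in_focus_frames[n]
        p_n = render_pattern(pattern, shape, n, pixel_size_nm)
        frame = _blur2d(plane_in * p_n, psf_in)
        if out_of_focus is not None and oof_weight > 0:
            p_oof = render_pattern(oof_pattern, shape, n, pixel_size_nm)
            frame = frame + oof_weight * _blur2d(out_of_focus * p_oof, psf_out)
        frames.append(frame)
    data = np.clip(np.stack(frames), 0.0, None)
    return OSSimStack(
        data=data,
        axes="pyx",
        pattern=pattern,
        optics=optics,
        pixel_size_nm=pixel_size_nm,
        meta={"oof_weight": oof_weight, "oof_modulation_scale": oof_modulation_scale},
    )


def default_psf_shape(config: OpticalConfig, z_halfwidth_nm: float = 1600.0) -> tuple[int, int, int]:
    """A PSF grid comfortably containing the main lobe and first rings."""
    dz, dy, dx = config.voxel_size
    hz = int(np.ceil(z_halfwidth_nm / dz))
    r = int(np.ceil(2.5 * 0.61 * config.emission_wavelength / config.numerical_aperture / dx))
    return (2 * hz + 1, 2 * r + 1, 2 * r + 1)


def simulate_volume_scan(
    phantom: Phantom3D,
    config: OpticalConfig,
    pattern: SinusoidalPattern,
    noise: NoiseModel | None = None,
    seed: int = 0,
    psf: PSF3D | None = None,
    focal_indices: np.ndarray | None = None,
) -> OSSimStack:
    """Scan a 3D phantom through focus, three phase frames per focal plane.

    For each focal position the detected plane is the 3D convolution of the
    pattern-excited phantom with the widefield PSF, sampled at that plane;
    the stripe pattern refocuses with the objective, so its modulation depth
    follows the axial envelope centred on the current focal plane. Splitting
    the pattern into its mean and modulated parts turns the whole scan into
    four 3D convolutions (one widefield + one per phase), independent of the
    number of focal planes.
    """
    if tuple(np.round(phantom.voxel_size, 6)) != tuple(np.round(config.voxel_size, 6)):
        raise ValueError("phantom voxel size does not match the optical config")
    vol = phantom.data
    nz, ny, nx = vol.shape
    if psf is None:
        psf = compute_psf(config, default_psf_shape(config))
    h = psf.data
    dz = config.voxel_size[0]
    z_off = (np.arange(h.shape[0]) - psf.focus_index) * dz
    env = modulation_envelope(z_off, config)
    h_env = h * env[:, None, None]

    widefield_term = fftconvolve(vol, h, mode="same")
    carriers = [
        2.0 * render_pattern(
            replace(pattern, modulation_depth=1.0), (ny, nx), n, config.voxel_size[2]
        )
        - 1.0
        for n in range(3)
    ]  # cos(2 pi nu proj + phi_n), unit amplitude
    m0 = pattern.modulation_depth
    frames = np.empty((nz, 3, ny, nx))
    for n in range(3):
        modulated = vol * carriers[n][None, :, :]
        mod_term = fftconvolve(modulated, h_env, mode="same")
        frames[:, n] = 0.5 * widefield_term + 0.5 * m0 * mod_term
    frames = np.clip(frames, 0.0, None)
    if focal_indices is not None:
        frames = frames[np.asarray(focal_indices)]
    stack = OSSimStack(
        data=frames,
        axes="zpyx",
        pattern=pattern,
        optics=config,
        pixel_size_nm=config.voxel_size[2],
        meta={"phantom_kind": phantom.kind, "phantom_seed": phantom.seed},
    )
    if noise is not None:
        stack = add_noise(stack, noise, seed)
    return stack


def sectioned_ground_truth(phantom: Phantom3D, psf: PSF3D) -> np.ndarray:
    """Ideal optically sectioned volume: each plane blurred by the in-focus PSF.

    This is the noise-free, background-free reference all reconstructions are
    scored against (a model "confocal" image of the phantom).
    """
    kernel = psf.plane(0.0)
    return np.stack([fftconvolve(plane, kernel, mode="same") for plane in phantom.data])


def add_noise(stack: OSSimStack, noise: NoiseModel, seed: int = 0) -> OSSimStack:
    """Apply Poisson + Gaussian noise; output is in photon-count units.

    The stack is first normalised so its maximum equals
    ``noise.peak_intensity_norm``; each pixel's expected count is then
    value * eta * 1e12 and the realised count is a Poisson draw plus
    zero-mean Gaussian read noise, clipped at zero. Fully reproducible from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    data = stack.data
    peak = data.max()
    if peak <= 0:
        raise ValueError("cannot add noise to an empty (all-zero) stack")
    lam = data * (noise.peak_intensity_norm / peak) * noise.poisson_factor * noise.photon_scale
    counts = rng.poisson(lam).astype(np.float64)
    if noise.gaussian_sigma > 0:
        counts += rng.normal(0.0, noise.gaussian_sigma, size=counts.shape)
    counts = np.clip(counts, 0.0, None)
    return replace(stack, data=counts, noise=noise, meta={**stack.meta, "noise_seed": seed})


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameter ranges for randomised training-example generation.

    Every optical and pattern parameter is drawn uniformly from its range per
    example, so trained networks generalise across microscopes and imaging
    conditions rather than memorising one configuration. eta is drawn
    log-uniformly (its effect on photon counts is multiplicative).
    """

    shape: tuple[int, int] = (64, 64)
    pixel_size_nm: float = 86.0
    pattern_freq_range: tuple[float, float] = (1.6, 2.9)
    orientation_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    modulation_range: tuple[float, float] = (0.6, 1.0)
    na_range: tuple[float, float] = (1.0, 1.3)
    defocus_range_nm: tuple[float, float] = (1000.0, 3000.0)
    oof_weight_range: tuple[float, float] = (0.2, 1.0)
    eta_log10_range: tuple[float, float] = (-5.3, -3.0)
    gaussian_sigma: float = 1.0
    emission_wavelength: float = 600.0
    excitation_wavelength: float = 488.0
    refractive_index: float = 1.33
    moving: bool = False
    max_displacement: float = 2.0
    texture_kinds: tuple[str, ...] = TEXTURE_KINDS

    def __post_init__(self) -> None:
        for name in (
            "pattern_freq_range",
            "orientation_range",
            "modulation_range",
            "na_range",
            "defocus_range_nm",
            "oof_weight_range",
            "eta_log10_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")
        if not self.texture_kinds:
            raise ValueError("at least one texture kind is required")


@dataclass
class TrainingExample:
    """A noisy raw triplet, its diffraction-limited target and provenance."""

    stack: OSSimStack
    target: np.ndarray
    params: dict[str, Any]
    in_focus: np.ndarray
    psf_in: np.ndarray


def _draw(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def make_training_example(gen: GeneratorConfig, seed: int = 0) -> TrainingExample:
    """Draw one randomised (noisy raw triplet, ground-truth) pair.

    The in-focus scene is a procedural texture (or a moving-object triplet in
    video mode); the out-of-focus background is an independent texture. The
    target is the in-focus plane blurred with the drawn in-focus PSF — for
    moving scenes, the second frame, the timepoint the reconstruction should
    represent.
    """
    rng = np.random.default_rng(seed)
    na = _draw(rng, gen.na_range)
    config = OpticalConfig(
        numerical_aperture=na,
        emission_wavelength=gen.emission_wavelength,
        excitation_wavelength=gen.excitation_wavelength,
        refractive_index=max(gen.refractive_index, na + 0.03),
        voxel_size=(gen.pixel_size_nm, gen.pixel_size_nm, gen.pixel_size_nm),
    )
    freq = _draw(rng, gen.pattern_freq_range)
    pattern = SinusoidalPattern(
        spatial_frequency=freq,
        orientation=_draw(rng, gen.orientation_range),
        modulation_depth=_draw(rng, gen.modulation_range),
    )
    defocus = _draw(rng, gen.defocus_range_nm)
    oof_weight = _draw(rng, gen.oof_weight_range)
    eta = 10.0 ** _draw(rng, gen.eta_log10_range)

    psf3 = compute_psf(config, default_psf_shape(config, z_halfwidth_nm=defocus + 200.0))
    psf_in = psf3.plane(0.0)
    psf_out = psf3.plane(defocus)
    kind = gen.texture_kinds[int(rng.integers(len(gen.texture_kinds)))]
    tex_seed = int(rng.integers(2**31))
    oof_seed = int(rng.integers(2**31))
    out_of_focus = generate_texture(gen.shape, oof_seed, "multiscale-noise")
    frames_in = None
    if gen.moving:
        triplet = generate_moving_triplet(
            gen.shape,
            n_objects=int(rng.integers(3, 9)),
            max_displacement=gen.max_displacement,
            seed=tex_seed,
        )
        frames_in = triplet.frames
        in_focus = triplet.frames[1]
    else:
        in_focus = generate_texture(gen.shape, tex_seed, kind)
    stack = simulate_stack(
        in_focus if frames_in is None else frames_in[0],
        out_of_focus,
        psf_in,
        psf_out,
        pattern,
        oof_weight=oof_weight,
        pixel_size_nm=gen.pixel_size_nm,
        oof_modulation_scale=float(modulation_envelope(defocus, config)),
        in_focus_frames=frames_in,
        optics=config,
    )
    noise = NoiseModel(gaussian_sigma=gen.gaussian_sigma, poisson_factor=eta)
    noisy = add_noise(stack, noise, seed=int(rng.integers(2**31)))
    target = fftconvolve(in_focus, psf_in, mode="same")
    params = {
        "seed": seed,
        "na": na,
        "pattern_frequency": freq,
        "orientation": pattern.orientation,
        "modulation_depth": pattern.modulation_depth,
        "defocus_nm": defocus,
        "oof_weight": oof_weight,
        "eta": eta,
        "texture_kind": kind,
        "texture_seed": tex_seed,
        "oof_seed": oof_seed,
        "moving": gen.moving,
    }
    return TrainingExample(
        stack=noisy, target=target, params=params, in_focus=in_focus, psf_in=psf_in
    )
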