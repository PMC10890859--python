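"""Canonical end-to-end simulation experiments.

These functions bundle the standard study conditions — stated optics
(emission 600 nm, NA 1.2, 86 nm isotropic voxels), the optimal stripe
frequency, the Gaussian + Poisson noise model — into reproducible
experiments used by the benchmarks, the CLI and the test suite.
"""

from __future__ import annotations

import numpy as np

from ossim.evaluate import otf_cone_fill
from ossim.forward import (
    NoiseModel,
    OSSimStack,
    add_noise,
    modulation_envelope,
    simulate_stack,
    simulate_volume_scan,
    default_psf_shape,
)
from ossim.optics import (
    OpticalConfig,
    SinusoidalPattern,
    compute_psf,
    optimal_pattern_frequency,
)
from ossim.phantom import Phantom3D, generate_texture
from ossim.recon import sd_reconstruction, widefield_estimate


def reference_optics() -> OpticalConfig:
    """The stated simulation optics: 600 nm emission, NA 1.2 water immersion,
    86 nm isotropic voxels."""
    return OpticalConfig(
        numerical_aperture=1.2,
        emission_wavelength=600.0,
        excitation_wavelength=488.0,
        refractive_index=1.33,
        voxel_size=(86.0, 86.0, 86.0),
    )


def reference_pattern(config: OpticalConfig | None = None) -> SinusoidalPattern:
    config = config or reference_optics()
    return SinusoidalPattern(spatial_frequency=optimal_pattern_frequency(config))


def point_source_phantom(
    shape: tuple[int, int, int] = (48, 65, 65), n_points: int = 40, seed: int = 0
) -> Phantom3D:
    """Sparse random point emitters for OTF support analysis."""
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape)
    idx = np.stack(
        [rng.integers(4, s - 4, size=n_points) for s in shape], axis=1
    )
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    return Phantom3D(data=vol, kind="point-sources", params={"n_points": n_points}, seed=seed)


def cone_fill_experiment(
    seed: int = 0, shape: tuple[int, int, int] = (48, 65, 65), n_points: int = 40
) -> float:
    """Missing-cone analysis: axial spectral energy of the SD reconstruction
    of a point-source volume relative to its widefield counterpart.

    Widefield imaging transfers essentially no purely axial frequency
    content (the missing cone); sectioned reconstruction restores it, so the
    ratio should be well above 1.
    """
    config = reference_optics()
    pattern = reference_pattern(config)
    phantom = point_source_phantom(shape, n_points, seed)
    phantom.voxel_size = config.voxel_size
    stack = simulate_volume_scan(phantom, config, pattern)
    sd_vol = np.stack([sd_reconstruction(stack.plane(i)) for i in range(stack.n_planes)])
    wf_vol = np.stack([widefield_estimate(stack.plane(i)) for i in range(stack.n_planes)])
    return otf_cone_fill(sd_vol, wf_vol)


def two_plane_scene(
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    defocus_nm: float = 1500.0,
    oof_weight: float = 1.0,
    noise: NoiseModel | None = None,
) -> tuple[OSSimStack, np.ndarray, np.ndarray]:
    """An in-focus texture over a defocused background texture.

    Returns (stack, in-focus scene, out-of-focus scene); the scenes allow
    measuring how much out-of-focus residual each reconstruction retains.
    """
    config = reference_optics()
    pattern = reference_pattern(config)
    psf = compute_psf(config, default_psf_shape(config, z_halfwidth_nm=defocus_nm + 200.0))
    in_focus = generate_texture(shape, seed, "blobs")
    out_of_focus = generate_texture(shape, seed + 1, "blobs")
    stack = simulate_stack(
        in_focus,
        out_of_focus,
        psf.plane(0.0),
        psf.plane(defocus_nm),
        pattern,
        oof_weight=oof_weight,
        pixel_size_nm=config.voxel_size[2],
        oof_modulation_scale=float(modulation_envelope(defocus_nm, config)),
        optics=config,
    )
    if noise is not None:
        stack = add_noise(stack, noise, seed=seed + 13)
    return stack, in_focus, out_of_focus


def out_of_focus_rejection(
    recon: np.ndarray, stack_in_only: np.ndarray, stack_oof_only: np.ndarray
) -> float:
    """Fraction of a reconstruction's energy attributable to the background.

    Uses least-squares projection of the reconstruction onto the separately
    simulated in-focus-only and background-only images (both zero-mean);
    returns |coef_oof| * ||oof|| / (|coef_in| * ||in|| + |coef_oof| * ||oof||).
    """
    r = recon - recon.mean()
    a = stack_in_only - stack_in_only.mean()
    b = stack_oof_only - stack_oof_only.mean()
    basis = np.stack([a.ravel(), b.ravel()], axis=1)
    coef, *_ = np.linalg.lstsq(basis, r.ravel(), rcond=None)
    e_in = abs(coef[0]) * np.linalg.norm(a)
    e_oof = abs(coef[1]) * np.linalg.norm(b)
    return float(e_oof / (e_in + e_oof + 1e-300))
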