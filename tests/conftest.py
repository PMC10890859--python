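"""Shared fixtures: reference optics, PSFs and (session-scoped) trained nets."""

from __future__ import annotations

import numpy as np
import pytest

from ossim.forward import GeneratorConfig
from ossim.optics import OpticalConfig, SinusoidalPattern, compute_psf


@pytest.fixture(scope="session")
def ref_config() -> OpticalConfig:
    return OpticalConfig(
        numerical_aperture=1.2,
        emission_wavelength=600.0,
        excitation_wavelength=488.0,
        refractive_index=1.33,
        voxel_size=(86.0, 86.0, 86.0),
    )


@pytest.fixture(scope="session")
def ref_psf(ref_config):
    return compute_psf(ref_config, (33, 65, 65))


@pytest.fixture(scope="session")
def ref_pattern(ref_config) -> SinusoidalPattern:
    from ossim.optics import optimal_pattern_frequency

    return SinusoidalPattern(spatial_frequency=optimal_pattern_frequency(ref_config))


def _uniform_plane_stack(
    brightness: float = 3.0,
    modulation: float = 0.8,
    shape: tuple[int, int] = (96, 96),
    frequency: float = 2.0,
    orientation: float = 0.3,
    phase_offsets: tuple[float, float, float] | None = None,
):
    """Noise-free triplet of a uniform fluorescent plane under stripes.

    Frame n is B * (1 + m cos(theta(x) + phi_n)): the pattern rendered at
    twice its normalised scale so the analytic constants are simple.
    """
    from ossim.forward import OSSimStack
    from ossim.optics import render_pattern

    kwargs = {} if phase_offsets is None else {"phase_offsets": tuple(phase_offsets)}
    pattern = SinusoidalPattern(frequency, orientation, modulation, **kwargs)
    frames = np.stack(
        [2.0 * brightness * render_pattern(pattern, shape, n) for n in range(3)]
    )
    return OSSimStack(data=frames, pattern=pattern)


@pytest.fixture()
def uniform_plane_stack():
    return _uniform_plane_stack()


@pytest.fixture(scope="session")
def trained_tiny_rcan():
    """A tiny RCAN trained on static simulated scenes (shared across tests)."""
    from ossim.nn import (
        DatasetSpec,
        TrainConfig,
        build_rcan,
        generate_training_set,
        tiny_rcan_config,
        train,
    )

    gen = GeneratorConfig(shape=(48, 48))
    dataset = generate_training_set(DatasetSpec(n_static=150, n_moving=0, static=gen), seed=1)
    model = build_rcan(tiny_rcan_config(), seed=0)
    result = train(
        model, dataset, TrainConfig(epochs=14, batch_size=8, learning_rate=1e-3, seed=0)
    )
    return model, result, gen


@pytest.fixture(scope="session")
def trained_tiny_vsr():
    """A tiny VSR trained on mixed static/moving scenes (shared across tests)."""
    from ossim.nn import (
        DatasetSpec,
        TrainConfig,
        build_vsr,
        generate_training_set,
        tiny_vsr_config,
        train,
    )

    gen = GeneratorConfig(shape=(32, 32))
    gen_moving = GeneratorConfig(shape=(32, 32), moving=True)
    dataset = generate_training_set(
        DatasetSpec(n_static=80, n_moving=120, static=gen, moving=gen_moving), seed=2
    )
    model = build_vsr(tiny_vsr_config(), seed=0)
    result = train(
        model, dataset, TrainConfig(epochs=12, batch_size=8, learning_rate=1e-3, seed=0)
    )
    return model, result
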