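"""Image formation: two-plane model, volume scanning, noise statistics."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from ossim.forward import (
    GeneratorConfig,
    NoiseModel,
    OSSimStack,
    add_noise,
    make_training_example,
    modulation_envelope,
    simulate_stack,
    simulate_volume_scan,
)
from ossim.optics import SinusoidalPattern
from ossim.phantom import generate_texture


@pytest.fixture()
def scene():
    in_focus = generate_texture((64, 64), seed=1, kind="blobs")
    out_of_focus = generate_texture((64, 64), seed=2, kind="multiscale-noise")
    return in_focus, out_of_focus


DELTA = np.array([[1.0]])


def _gauss_kernel(sigma: float, half: int = 8) -> np.ndarray:
    x = np.arange(-half, half + 1)
    k = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / (2 * sigma**2))
    return k / k.sum()


class TestSimulateStack:
    def test_zero_modulation_gives_identical_frames(self, scene):
        in_focus, oof = scene
        pat = SinusoidalPattern(2.0, 0.0, 0.0)
        stack = simulate_stack(in_focus, oof, _gauss_kernel(1.5), _gauss_kernel(4.0), pat)
        assert np.allclose(stack.data[0], stack.data[1])
        assert np.allclose(stack.data[1], stack.data[2])

    def test_delta_psf_identity(self, scene):
        """With a delta kernel and no background, frames are exactly the
        patterned in-focus image."""
        in_focus, _ = scene
        pat = SinusoidalPattern(2.0, 0.4, 0.9)
        stack = simulate_stack(in_focus, None, DELTA, None, pat, oof_weight=0.0)
        from ossim.optics import render_pattern

        for n in range(3):
            expected = in_focus * render_pattern(pat, in_focus.shape, n)
            assert np.allclose(stack.data[n], expected, atol=1e-12)

    def test_three_phase_mean_identity(self, scene):
        """mean of frames = blur(in)/2 + w * blur(oof)/2: uniform average
        illumination carries through blurring and plane mixing."""
        in_focus, oof = scene
        pat = SinusoidalPattern(2.3, 0.7, 0.85)
        k_in, k_out = _gauss_kernel(1.2), _gauss_kernel(3.5)
        w = 0.6
        stack = simulate_stack(in_focus, oof, k_in, k_out, pat, oof_weight=w)
        mean = stack.data.mean(axis=0)
        expected = (
            fftconvolve(in_focus, k_in, mode="same") / 2
            + w * fftconvolve(oof, k_out, mode="same") / 2
        )
        assert np.abs(mean - expected).max() < 1e-6

    def test_widefield_invariant_under_phase_permutation(self, scene):
        in_focus, oof = scene
        pat = SinusoidalPattern(2.0, 0.2, 0.8)
        stack = simulate_stack(in_focus, oof, _gauss_kernel(1.5), _gauss_kernel(4.0), pat)
        mean = stack.data.mean(axis=0)
        perm = stack.data[[2, 0, 1]].mean(axis=0)
        assert np.allclose(mean, perm)

    def test_shape_mismatch_rejected(self, scene):
        in_focus, _ = scene
        with pytest.raises(ValueError, match="shape"):
            simulate_stack(in_focus, np.zeros((32, 32)), DELTA, DELTA, SinusoidalPattern(2.0))


@pytest.fixture(scope="module")
def small_scan(ref_config, ref_pattern):
    from ossim.optics import compute_psf
    from ossim.phantom import generate_filament_mesh

    mesh = generate_filament_mesh((32, 49, 49), n_filaments=8, seed=3)
    mesh.voxel_size = ref_config.voxel_size
    psf = compute_psf(ref_config, (17, 33, 33))
    return mesh, simulate_volume_scan(mesh, ref_config, ref_pattern, psf=psf), psf


class TestVolumeScan:

    def test_shape_contract_and_determinism(self, small_scan, ref_config, ref_pattern):
        mesh, stack, psf = small_scan
        assert stack.axes == "zpyx"
        assert stack.data.shape == (32, 3, 49, 49)
        again = simulate_volume_scan(mesh, ref_config, ref_pattern, psf=psf)
        assert np.array_equal(stack.data, again.data)

    def test_modulation_strongest_in_focus(self, small_scan, ref_config, ref_pattern):
        """Stripe Fourier amplitude at the carrier is higher at the plane of
        best focus than >= 1 um away: the premise of optical sectioning."""
        _, stack, _ = small_scan
        px = ref_config.voxel_size[2] * 1e-3
        ny, nx = stack.data.shape[-2:]
        kx = ref_pattern.spatial_frequency * px  # cycles / pixel along x
        phase_ramp = np.exp(-2j * np.pi * kx * np.arange(nx))

        def stripe_amp(z):
            diffs = stack.data[z] - stack.data[z].mean(axis=0, keepdims=True)
            return np.abs(np.einsum("pyx,x->p", diffs, phase_ramp)).max()

        # brightest plane of the mesh scan
        z_focus = int(np.argmax(stack.data.sum(axis=(1, 2, 3))))
        shift = int(round(1000.0 / ref_config.voxel_size[0]))
        z_far = z_focus + shift if z_focus + shift < 32 else z_focus - shift
        assert stripe_amp(z_focus) > stripe_amp(z_far)

    def test_two_plane_stripe_ratio_exceeds_three(self, ref_config):
        """In-focus vs 1.5-um-defocused stripe amplitude ratio > 3 at NA 1.2."""
        ratio = 1.0 / max(float(modulation_envelope(1500.0, ref_config)), 1e-300)
        # the envelope alone guarantees it; confirm on simulated frames
        assert ratio > 3
        from ossim.optics import compute_psf, render_pattern

        psf = compute_psf(ref_config, (41, 33, 33))
        pat = SinusoidalPattern(2.0, 0.0, 1.0)
        plane = np.ones((64, 64))
        stack_f = simulate_stack(plane, None, psf.plane(0.0), None, pat, oof_weight=0.0)
        scale = float(modulation_envelope(1500.0, ref_config))
        stack_d = simulate_stack(
            plane, plane, np.array([[0.0]]), psf.plane(1500.0), pat,
            oof_weight=1.0, oof_modulation_scale=scale,
        )
        def amp(frames):
            d = frames[0] - frames.mean(axis=0)
            return np.abs(np.fft.fft2(d)).max()

        assert amp(stack_f.data) > 3 * amp(stack_d.data)


class TestNoise:
    def test_eta_must_be_positive(self):
        with pytest.raises(ValueError):
            NoiseModel(poisson_factor=0.0)

    def test_deterministic_from_seed(self, scene):
        in_focus, _ = scene
        stack = OSSimStack(data=np.stack([in_focus] * 3))
        noise = NoiseModel(poisson_factor=2e-5)
        a = add_noise(stack, noise, seed=42)
        b = add_noise(stack, noise, seed=42)
        assert np.array_equal(a.data, b.data)
        c = add_noise(stack, noise, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_high_photon_limit_is_nearly_noiseless(self, scene):
        """Poisson CV = 1/sqrt(lambda): at >= 1e8 expected peak counts the
        relative RMS deviation is below 1e-3 of the peak."""
        in_focus, _ = scene
        stack = OSSimStack(data=np.stack([in_focus] * 3))
        noise = NoiseModel(gaussian_sigma=0.0, poisson_factor=1e2)  # peak 1e8 counts
        noisy = add_noise(stack, noise, seed=0)
        lam = stack.data * (noise.peak_intensity_norm / stack.data.max())
        lam *= noise.poisson_factor * noise.photon_scale
        rel_rms = np.sqrt(np.mean((noisy.data - lam) ** 2)) / lam.max()
        assert rel_rms < 1e-3

    def test_monte_carlo_mean_matches_expectation(self):
        """Across seeds, a pixel's mean count equals its Poisson rate within
        3 standard errors (plus the Gaussian component's zero mean)."""
        data = np.linspace(0.1, 1.0, 12).reshape(1, 3, 4).repeat(3, axis=0)
        stack = OSSimStack(data=data)
        noise = NoiseModel(gaussian_sigma=1.0, poisson_factor=2e-5)
        lam = data * (noise.peak_intensity_norm / data.max()) * noise.poisson_factor * noise.photon_scale
        n_seeds = 600
        draws = np.stack([add_noise(stack, noise, seed=s).data for s in range(n_seeds)])
        mean = draws.mean(axis=0)
        # clipping at zero slightly inflates the mean where sigma ~ lambda;
        # use the brightest pixel where clipping is negligible
        idx = np.unravel_index(np.argmax(lam), lam.shape)
        se = np.sqrt((lam[idx] + noise.gaussian_sigma**2) / n_seeds)
        assert abs(mean[idx] - lam[idx]) < 3 * se

    def test_variance_matches_poisson_plus_gaussian(self):
        data = np.full((3, 2, 2), 1.0)
        stack = OSSimStack(data=data)
        noise = NoiseModel(gaussian_sigma=2.0, poisson_factor=1e-4)
        lam = noise.peak_photons  # all pixels at peak
        draws = np.stack([add_noise(stack, noise, seed=s).data for s in range(600)])
        var = draws.var(axis=0).mean()
        expected = lam + noise.gaussian_sigma**2
        assert abs(var - expected) / expected < 0.15


class TestTrainingExampleGeneration:
    def test_deterministic(self):
        gen = GeneratorConfig(shape=(32, 32))
        a = make_training_example(gen, seed=5)
        b = make_training_example(gen, seed=5)
        assert np.array_equal(a.stack.data, b.stack.data)
        assert np.array_equal(a.target, b.target)
        assert a.params == b.params

    def test_target_is_blurred_in_focus_plane(self):
        gen = GeneratorConfig(shape=(32, 32))
        ex = make_training_example(gen, seed=8)
        recomputed = fftconvolve(ex.in_focus, ex.psf_in, mode="same")
        assert np.array_equal(ex.target, recomputed)

    def test_modulation_draws_cover_configured_range(self):
        gen = GeneratorConfig(shape=(16, 16))
        lo, hi = gen.modulation_range
        draws = np.array(
            [make_training_example(gen, seed=s).params["modulation_depth"] for s in range(200)]
        )
        assert (draws.max() - draws.min()) >= 0.8 * (hi - lo)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            GeneratorConfig(modulation_range=(0.9, 0.3))
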