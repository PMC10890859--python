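"""Classical reconstructions: demodulation identities, pattern estimation,
phase-corrected SD against a brute-force oracle, HiLo filtering."""

import numpy as np
import pytest

from ossim.forward import GeneratorConfig, NoiseModel, OSSimStack, add_noise, make_training_example
from ossim.optics import SinusoidalPattern, render_pattern
from ossim.recon import (
    DegeneratePhaseError,
    HiLoParams,
    PatternEstimate,
    corrected_sd,
    estimate_pattern_parameters,
    hilo_filtered,
    reconstruct,
    sd_reconstruction,
    widefield_estimate,
)
from tests.conftest import _uniform_plane_stack

IDEAL = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


def _stripe_residual(img: np.ndarray, frequency: float, px_nm: float = 86.0) -> float:
    """|spectrum| at the carrier over |spectrum| at DC."""
    spec = np.abs(np.fft.fft2(img))
    px = px_nm * 1e-3
    fy = np.fft.fftfreq(img.shape[0], d=px)[:, None]
    fx = np.fft.fftfreq(img.shape[1], d=px)[None, :]
    ring = np.abs(np.hypot(fy, fx) - frequency) < 0.08 * frequency
    return spec[ring].max() / spec[0, 0]


class TestWidefield:
    def test_identity_and_linearity(self):
        f = np.random.default_rng(0).random((3, 16, 16))
        assert np.allclose(widefield_estimate(np.stack([f[0]] * 3)), f[0])
        lhs = widefield_estimate(2.0 * f)
        assert np.allclose(lhs, 2.0 * widefield_estimate(f))

    def test_three_phase_stripes_cancel(self, uniform_plane_stack):
        """Exact third-turn stepping leaves no carrier in the mean image."""
        wf = widefield_estimate(uniform_plane_stack)
        freq = uniform_plane_stack.pattern.spatial_frequency
        assert _stripe_residual(wf, freq) < 1e-6

    def test_wrong_frame_count_rejected(self):
        with pytest.raises(ValueError):
            widefield_estimate(np.zeros((4, 8, 8)))


class TestSD:
    def test_identical_frames_give_zero(self):
        f = np.random.default_rng(1).random((16, 16))
        assert np.allclose(sd_reconstruction(np.stack([f] * 3)), 0.0)

    def test_uniform_plane_demodulates_to_constant(self):
        """For I_n = B (1 + m cos(theta + phi_n)) with ideal phases the SD
        output is sqrt(4.5) * B * m everywhere, independent of theta."""
        B, m = 3.0, 0.8
        stack = _uniform_plane_stack(brightness=B, modulation=m)
        out = sd_reconstruction(stack)
        expected = np.sqrt(4.5) * B * m
        assert np.allclose(out, expected, rtol=1e-9)

    def test_phase_relabelling_invariance(self, uniform_plane_stack):
        frames = uniform_plane_stack.data
        assert np.allclose(sd_reconstruction(frames), sd_reconstruction(frames[[1, 2, 0]]))

    def test_scaling_equivariance(self, uniform_plane_stack):
        frames = uniform_plane_stack.data
        assert np.allclose(sd_reconstruction(3.7 * frames), 3.7 * sd_reconstruction(frames))


class TestPatternEstimation:
    def test_known_simulated_pattern_recovered(self):
        """Frequency within 0.5% and relative phases within 0.05 rad on a
        noise-free structured scene."""
        gen = GeneratorConfig(shape=(96, 96), eta_log10_range=(2.0, 2.0))  # ~no noise
        ex = make_training_example(gen, seed=4)
        est = estimate_pattern_parameters(ex.stack)
        true_freq = ex.params["pattern_frequency"]
        assert abs(est.spatial_frequency - true_freq) / true_freq < 0.005
        diffs = np.angle(np.exp(1j * np.diff(est.phases)))
        for d in diffs:
            assert min(abs(abs(d) - 2 * np.pi / 3), abs(abs(d) - 4 * np.pi / 3)) < 0.05

    def test_global_phase_offset_leaves_differences_unchanged(self):
        base = _uniform_plane_stack(phase_offsets=IDEAL)
        shifted = _uniform_plane_stack(phase_offsets=tuple(p + 0.37 for p in IDEAL))
        d0 = np.angle(np.exp(1j * np.diff(estimate_pattern_parameters(base).phases)))
        d1 = np.angle(np.exp(1j * np.diff(estimate_pattern_parameters(shifted).phases)))
        assert np.abs(d0 - d1).max() < 1e-6

    def test_phase_error_decreases_with_signal(self):
        """Phase accuracy improves as eta rises over a decade (Monte Carlo).

        The estimated step between consecutive phases is compared against a
        third of a turn in either direction (the carrier's conjugate is an
        equally valid solution and flips the step sign).
        """

        def mean_phase_error(eta):
            errs = []
            for s in range(4):
                ex = make_training_example(
                    GeneratorConfig(
                        shape=(64, 64), eta_log10_range=(np.log10(eta), np.log10(eta))
                    ),
                    seed=100 + s,
                )
                est = estimate_pattern_parameters(ex.stack)
                for d in np.mod(np.diff(est.phases), 2 * np.pi):
                    errs.append(min(abs(d - 2 * np.pi / 3), abs(d - 4 * np.pi / 3)))
            return np.mean(errs)

        assert mean_phase_error(1e-3) < mean_phase_error(1e-5)

    def test_no_stripes_flags_low_confidence_and_falls_back(self):
        pat = SinusoidalPattern(2.0, 0.3, 0.9)
        flat = OSSimStack(
            data=np.random.default_rng(3).poisson(5.0, (3, 64, 64)).astype(float),
            pattern=pat,
        )
        est = estimate_pattern_parameters(flat)
        assert est.low_confidence
        assert est.spatial_frequency == pytest.approx(2.0)


class TestCorrectedSD:
    def _lstsq_oracle(self, frames: np.ndarray, phases) -> np.ndarray:
        """Brute-force per-pixel least squares of I_n = B + p cos(phi_n) - q
        sin(phi_n); the stripe amplitude is hypot(p, q)."""
        phi = np.asarray(phases)
        M = np.stack([np.ones(3), np.cos(phi), -np.sin(phi)], axis=1)
        sol = np.linalg.lstsq(M, frames.reshape(3, -1), rcond=None)[0]
        return np.hypot(sol[1], sol[2]).reshape(frames.shape[1:])

    def test_identical_frames_give_zero(self):
        f = np.random.default_rng(2).random((16, 16))
        out = corrected_sd(np.stack([f] * 3), IDEAL)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_uniform_plane_is_flat(self):
        stack = _uniform_plane_stack(brightness=2.0, modulation=0.7)
        out = corrected_sd(stack, IDEAL)
        assert out.std() / out.mean() < 0.01
        assert out.mean() == pytest.approx(2.0 * 0.7, rel=1e-6)

    def test_matches_brute_force_least_squares(self):
        """The closed pairwise form equals the inverse-matrix solution on an
        arbitrary scene with uneven phase steps."""
        phases = (0.1, 2.31, 4.0)
        pat = SinusoidalPattern(2.2, 0.5, 0.75, phase_offsets=phases)
        rng = np.random.default_rng(5)
        scene = rng.random((48, 48)) + 0.3
        frames = np.stack(
            [2.0 * scene * render_pattern(pat, scene.shape, n) for n in range(3)]
        )
        ours = corrected_sd(frames, phases)
        oracle = self._lstsq_oracle(frames, phases)
        assert np.allclose(ours, oracle, rtol=1e-8, atol=1e-10)

    def test_compensates_phase_step_error(self):
        """With a 0.2 rad phase-step error, using the true phases removes
        >= 50% of the stripe residual the naive SD leaves behind."""
        phases = (0.0, 2 * np.pi / 3 + 0.2, 4 * np.pi / 3)
        stack = _uniform_plane_stack(phase_offsets=phases)
        freq = stack.pattern.spatial_frequency
        naive = _stripe_residual(sd_reconstruction(stack), freq)
        corrected = _stripe_residual(corrected_sd(stack, phases), freq)
        assert corrected < 0.5 * naive

    def test_scaling_equivariance_and_relabelling(self):
        stack = _uniform_plane_stack(phase_offsets=(0.1, 2.31, 4.0))
        frames = stack.data
        base = corrected_sd(frames, (0.1, 2.31, 4.0))
        assert np.allclose(corrected_sd(2.5 * frames, (0.1, 2.31, 4.0)), 2.5 * base)
        permuted = corrected_sd(frames[[2, 0, 1]], (4.0, 0.1, 2.31))
        assert np.allclose(permuted, base, rtol=1e-9)

    def test_degenerate_phases_rejected_with_pair_named(self):
        f = np.random.default_rng(0).random((3, 8, 8))
        with pytest.raises(DegeneratePhaseError, match="1 and 2"):
            corrected_sd(f, (0.5, 0.5005, 3.0))


class TestHiLo:
    @pytest.fixture()
    def striped_estimate(self):
        return PatternEstimate(
            spatial_frequency=2.0,
            orientation=0.0,
            phases=IDEAL,
            modulation_depth_estimate=0.5,
        )

    def test_alpha_endpoints(self, uniform_plane_stack, striped_estimate):
        """alpha = 1 ignores the sectioned image; alpha = 0 ignores the
        widefield high-pass content."""
        a1 = hilo_filtered(uniform_plane_stack, HiLoParams(alpha=1.0), striped_estimate)
        a0 = hilo_filtered(uniform_plane_stack, HiLoParams(alpha=0.0), striped_estimate)
        # a uniform plane: widefield is constant, so HP(widefield) = 0
        assert np.allclose(a1, 0.0, atol=1e-9)
        assert a0.mean() > 0

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            HiLoParams(alpha=1.2)

    def test_notch_suppresses_carrier(self, striped_estimate):
        """A pure carrier-frequency sinusoid loses >= 90% of its stripe
        amplitude through the reconstruction's notch."""
        pat = SinusoidalPattern(2.0, 0.0, 1.0, phase_offsets=(0.0, 0.5, 1.0))
        # deliberately bad phase steps so the demodulated image keeps stripes
        frames = np.stack([2.0 * render_pattern(pat, (96, 96), n) for n in range(3)])
        stack = OSSimStack(data=frames, pattern=pat)
        est = PatternEstimate(2.0, 0.0, (0.0, 0.5, 1.0), 0.5)
        before = _stripe_residual(corrected_sd(stack, (0.0, 0.5, 1.0)) + widefield_estimate(stack), 2.0)
        after = _stripe_residual(hilo_filtered(stack, HiLoParams(alpha=0.5), est), 2.0)
        assert after <= 0.1 * max(before, 1e-12) or after < 1e-6

    def test_volume_reconstruction_wrapper(self, ref_config, ref_pattern):
        from ossim.forward import simulate_volume_scan
        from ossim.optics import compute_psf
        from ossim.phantom import generate_filament_mesh

        mesh = generate_filament_mesh((24, 33, 33), n_filaments=4, seed=1)
        mesh.voxel_size = ref_config.voxel_size
        psf = compute_psf(ref_config, (13, 21, 21))
        stack = simulate_volume_scan(mesh, ref_config, ref_pattern, psf=psf)
        res = reconstruct(stack, method="sd")
        assert res.image.shape == (24, 33, 33)
        assert res.method == "sd"
        with pytest.raises(ValueError, match="unknown method"):
            reconstruct(stack, method="magic")
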