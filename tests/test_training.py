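"""Dataset generation, the two-stage training loop, inference plumbing."""

import numpy as np
import pytest

from ossim.forward import GeneratorConfig
from ossim.nn import (
    DatasetSpec,
    RCANConfig,
    TrainConfig,
    TrainingDiverged,
    TrainingSet,
    build_rcan,
    generate_training_set,
    load_checkpoint,
    load_dataset,
    ml_method,
    reconstruct_ml,
    save_checkpoint,
    save_dataset,
    train,
)


def _micro_rcan(seed=0):
    return build_rcan(
        RCANConfig(n_groups=1, blocks_per_group=1, n_filters=4, reduction=2), seed=seed
    )


@pytest.fixture(scope="module")
def micro_dataset():
    gen = GeneratorConfig(shape=(32, 32))
    return generate_training_set(DatasetSpec(n_static=20, n_moving=0, static=gen), seed=0)


class TestDatasetGeneration:
    def test_counts_and_determinism(self):
        gen = GeneratorConfig(shape=(24, 24))
        spec = DatasetSpec(
            n_static=2, n_moving=3, static=gen, moving=GeneratorConfig(shape=(24, 24), moving=True)
        )
        a = generate_training_set(spec, seed=7)
        b = generate_training_set(spec, seed=7)
        assert len(a) == 5
        assert a.n_static == 2 and a.n_moving == 3
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.targets, b.targets)

    def test_moving_target_is_blurred_middle_frame(self):
        """The moving-example target recomputes bit-exactly as the second
        in-focus frame blurred with the drawn in-focus PSF."""
        from scipy.signal import fftconvolve

        from ossim.phantom import generate_moving_triplet

        spec = DatasetSpec(
            n_static=0, n_moving=2, moving=GeneratorConfig(shape=(24, 24), moving=True)
        )
        _, examples = generate_training_set(spec, seed=3, keep_examples=True)
        for ex in examples:
            assert ex.params["moving"]
            recomputed = fftconvolve(ex.in_focus, ex.psf_in, mode="same")
            assert np.array_equal(ex.target, recomputed)

    def test_hdf5_round_trip(self, micro_dataset, tmp_path):
        path = tmp_path / "ds.h5"
        save_dataset(micro_dataset, str(path))
        loaded = load_dataset(str(path))
        assert np.array_equal(loaded.inputs, micro_dataset.inputs)
        assert np.array_equal(loaded.targets, micro_dataset.targets)
        assert loaded.params == micro_dataset.params

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            DatasetSpec(n_static=0, n_moving=0)


class TestTrainingLoop:
    def test_loss_decreases_and_switches_at_half(self, micro_dataset):
        model = _micro_rcan()
        cfg = TrainConfig(epochs=6, batch_size=4, learning_rate=1e-3, seed=0)
        result = train(model, micro_dataset, cfg)
        names = [h["loss_name"] for h in result.history]
        assert names == ["mse"] * 3 + ["l1"] * 3
        mse_losses = result.losses[:3]
        assert mse_losses[-1] < mse_losses[0]

    def test_identical_seeds_give_identical_trajectories(self, micro_dataset):
        cfg = TrainConfig(epochs=4, batch_size=4, learning_rate=1e-3, seed=5)
        r1 = train(_micro_rcan(seed=2), micro_dataset, cfg)
        r2 = train(_micro_rcan(seed=2), micro_dataset, cfg)
        assert np.array_equal(r1.losses, r2.losses)

    def test_odd_epochs_need_explicit_switch(self):
        with pytest.raises(ValueError, match="even"):
            TrainConfig(epochs=5)
        cfg = TrainConfig(epochs=5, loss_switch_epoch=2)
        assert cfg.switch_epoch == 2

    def test_divergence_aborts_with_last_good_state(self, micro_dataset):
        model = _micro_rcan(seed=1)
        bad = TrainingSet(
            inputs=micro_dataset.inputs[:8],
            targets=np.full_like(micro_dataset.targets[:8], np.nan),
            params=micro_dataset.params[:8],
        )
        before = model.state_dict()
        with pytest.raises(TrainingDiverged):
            train(model, bad, TrainConfig(epochs=2, batch_size=4, seed=0))
        after = model.state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k])

    def test_dataset_smaller_than_batch_rejected(self, micro_dataset):
        small = TrainingSet(
            inputs=micro_dataset.inputs[:2],
            targets=micro_dataset.targets[:2],
            params=micro_dataset.params[:2],
        )
        with pytest.raises(ValueError, match="batch"):
            train(_micro_rcan(), small, TrainConfig(epochs=2, batch_size=4))


class TestCheckpoints:
    def test_round_trip_preserves_weights_and_config(self, tmp_path):
        model = _micro_rcan(seed=9)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, config=TrainConfig(epochs=2, batch_size=1))
        loaded, meta = load_checkpoint(path)
        assert meta["model_class"] == "RCAN"
        assert meta["normalisation"].startswith("percentile")
        for (ka, a), (kb, b) in zip(model.named_parameters(), loaded.named_parameters()):
            assert ka == kb
            assert np.array_equal(a.data, b.data)


class TestInference:
    def test_tiled_matches_full_frame(self):
        """A 128x128 frame fits the default tile, so tiled and full-frame
        inference coincide; forced tiling stays close (channel attention
        pools global statistics, so cut frames can never match exactly) and
        becomes exact when the attention branch — the only global
        operation — is removed."""
        model = _micro_rcan(seed=3)
        frames = np.random.default_rng(0).random((3, 128, 128)).astype(np.float32)
        full = reconstruct_ml(model, frames, tile=128)
        default_path = reconstruct_ml(model, frames)
        assert np.array_equal(full, default_path)
        tiled = reconstruct_ml(model, frames, tile=80, overlap=32)
        rel = np.sqrt(np.mean((full - tiled) ** 2)) / (np.sqrt(np.mean(full**2)) + 1e-12)
        assert rel < 0.05
        for group in model.groups:
            for block in group.blocks:
                block.attention = None
        full_na = reconstruct_ml(model, frames, tile=128)
        tiled_na = reconstruct_ml(model, frames, tile=80, overlap=32)
        rel_na = np.sqrt(np.mean((full_na - tiled_na) ** 2)) / (
            np.sqrt(np.mean(full_na**2)) + 1e-12
        )
        assert rel_na < 1e-4

    def test_all_zero_input_gives_zero_output(self):
        model = _micro_rcan(seed=3)
        out = reconstruct_ml(model, np.zeros((3, 32, 32), dtype=np.float32))
        # percentile normalisation maps a constant stack to zeros; the net's
        # bias response is clipped at zero
        assert out.min() >= 0.0
        assert np.allclose(out, out[0, 0])

    def test_frame_count_mismatch_rejected(self):
        model = _micro_rcan()
        with pytest.raises(ValueError, match="frames"):
            reconstruct_ml(model, np.zeros((5, 32, 32), dtype=np.float32))

    def test_method_wrapper_accepts_pattern_argument(self):
        from ossim.forward import OSSimStack

        model = _micro_rcan()
        stack = OSSimStack(data=np.random.default_rng(1).random((3, 32, 32)))
        fn = ml_method(model)
        out = fn(stack, None)
        assert out.shape == (32, 32)
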