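"""Two-stage training: MSE for the first half of the epochs, L1 for the rest.

The MSE stage settles the network into the right intensity regime quickly;
the L1 stage sharpens structure and is less dominated by the brightest
pixels. Optimisation is Adam throughout. Training is fully deterministic
from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np

from ossim.nn.autodiff import Tensor, l1_loss, mse_loss
from ossim.nn.data import TrainingSet
from ossim.nn.layers import Module


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-4
    seed: int = 0
    loss_switch_epoch: int | None = None  # default: epochs // 2
    n_examples: int | None = None  # optional bookkeeping of the intended dataset size

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.loss_switch_epoch is None and self.epochs % 2 != 0:
            raise ValueError("epochs must be even for the half-way loss switch")

    @property
    def switch_epoch(self) -> int:
        return self.loss_switch_epoch if self.loss_switch_epoch is not None else self.epochs // 2


class Adam:
    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the last good state."""

    def __init__(self, epoch: int, state: dict[str, np.ndarray]):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch
        self.last_good_state = state


@dataclass
class TrainResult:
    model: Module
    history: list[dict[str, Any]]  # per-epoch: epoch, loss, loss_name

    @property
    def losses(self) -> np.ndarray:
        return np.array([h["loss"] for h in self.history])


def train(model: Module, dataset: TrainingSet, config: TrainConfig) -> TrainResult:
    """Optimise the model on the dataset; returns the per-epoch loss history.

    The loss is MSE up to (excluding) ``switch_epoch`` and L1 afterwards.
    A non-finite loss aborts training and restores the last epoch's weights.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("dataset is empty")
    if n < config.batch_size:
        raise ValueError(f"dataset ({n}) is smaller than the batch size ({config.batch_size})")
    rng = np.random.default_rng(config.seed)
    optimiser = Adam(model.parameters(), lr=config.learning_rate)
    history: list[dict[str, Any]] = []
    last_good = model.state_dict()
    for epoch in range(config.epochs):
        loss_name = "mse" if epoch < config.switch_epoch else "l1"
        loss_fn = mse_loss if loss_name == "mse" else l1_loss
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = Tensor(dataset.inputs[idx])
            pred = model(x)
            loss = loss_fn(pred, dataset.targets[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                model.load_state_dict(last_good)
                raise TrainingDiverged(epoch, last_good)
            model.zero_grad()
            loss.backward()
            optimiser.step()
            epoch_losses.append(value)
        history.append(
            {"epoch": epoch, "loss": float(np.mean(epoch_losses)), "loss_name": loss_name}
        )
        last_good = model.state_dict()
    return TrainResult(model=model, history=history)


def save_checkpoint(model: Module, path: str | Path, config: Any = None, extra: dict | None = None) -> None:
    """Weights + full configuration + normalisation convention, reproducibly."""
    path = Path(path)
    state = model.state_dict()
    meta = {
        "model_class": type(model).__name__,
        "config": asdict(model.config) if hasattr(model, "config") else None,
        "train_config": asdict(config) if config is not None else None,
        "normalisation": "percentile (1, 99)",
        "extra": extra or {},
    }
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path: str | Path):
    """Rebuild the model class from a checkpoint and load its weights."""
    from ossim.nn.rcan import RCAN, RCANConfig
    from ossim.nn.vsr import VSR, VSRConfig

    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        state = {k: f[k] for k in f.files if k != "__meta__"}
    cls = {"RCAN": (RCAN, RCANConfig), "VSR": (VSR, VSRConfig)}[meta["model_class"]]
    model_cls, cfg_cls = cls
    model = model_cls(cfg_cls(**meta["config"]))
    model.load_state_dict(state)
    return model, meta
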