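"""Building blocks: modules, convolutions, linear maps, layer norm."""

from __future__ import annotations

import numpy as np

from ossim.nn.autodiff import Tensor, conv2d


class Module:
    """Base class with recursive parameter discovery and state I/O."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((path, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{path}.{i}."))
        return out

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def parameter(array: np.ndarray) -> Tensor:
    return Tensor(array.astype(np.float32), requires_grad=True)


class Conv2d(Module):
    """Stride-1 'same' convolution with He-initialised weights."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        fan_in = in_channels * kernel * kernel
        self.weight = parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel))
        )
        self.bias = parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Affine layer normalisation over the trailing (channel) axis."""

    def __init__(self, dim: int):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm() * self.gamma + self.beta
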