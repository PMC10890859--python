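"""Residual channel attention network for fast OS-SIM reconstruction.

Maps the three raw phase frames to one sectioned frame. The reference
configuration is three groups of ten residual channel attention blocks
(RCABs), 96 filters with 3x3 body kernels and a 7x7 learnable head; all
counts are configurable so a desk-scale variant trains in minutes on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ossim.nn.autodiff import Tensor
from ossim.nn.layers import Conv2d, Module


@dataclass(frozen=True)
class RCANConfig:
    n_groups: int = 3
    blocks_per_group: int = 10
    n_filters: int = 96
    body_kernel: int = 3
    head_kernel: int = 7
    reduction: int = 16
    in_frames: int = 3
    out_frames: int = 1

    def __post_init__(self) -> None:
        for name in ("n_groups", "blocks_per_group", "n_filters", "in_frames", "out_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        for name in ("body_kernel", "head_kernel"):
            if getattr(self, name) % 2 == 0:
                raise ValueError(f"{name} must be odd")
        if self.n_filters % self.reduction != 0:
            raise ValueError("n_filters must be divisible by the attention reduction")


def tiny_rcan_config(n_filters: int = 8) -> RCANConfig:
    """A configuration small enough to train on a single CPU in minutes."""
    return RCANConfig(
        n_groups=1, blocks_per_group=2, n_filters=n_filters, reduction=max(n_filters // 4, 1)
    )


class ChannelAttention(Module):
    """Global-pooling channel gate: pool -> conv1x1 down -> relu -> conv1x1 up -> sigmoid."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        self.down = Conv2d(channels, channels // reduction, 1, rng)
        self.up = Conv2d(channels // reduction, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.up(self.down(s).relu()).sigmoid()
        return x * s


class RCAB(Module):
    """Residual channel attention block: two convolutions, a channel gate,
    and a residual connection carrying low-frequency content through.

    Setting ``attention = None`` reduces the block to a plain residual block
    (used for ablation)."""

    def __init__(self, channels: int, kernel: int, reduction: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, kernel, rng)
        self.conv2 = Conv2d(channels, channels, kernel, rng)
        self.attention: ChannelAttention | None = ChannelAttention(channels, reduction, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x).relu())
        if self.attention is not None:
            y = self.attention(y)
        return x + y


class ResidualGroup(Module):
    def __init__(self, config: RCANConfig, rng: np.random.Generator):
        self.blocks = [
            RCAB(config.n_filters, config.body_kernel, config.reduction, rng)
            for _ in range(config.blocks_per_group)
        ]
        self.conv = Conv2d(config.n_filters, config.n_filters, config.body_kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for block in self.blocks:
            y = block(y)
        return x + self.conv(y)


class RCAN(Module):
    def __init__(self, config: RCANConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.head = Conv2d(config.in_frames, config.n_filters, config.head_kernel, rng)
        self.groups = [ResidualGroup(config, rng) for _ in range(config.n_groups)]
        self.body = Conv2d(config.n_filters, config.n_filters, config.body_kernel, rng)
        self.tail = Conv2d(config.n_filters, config.out_frames, config.body_kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, in_frames, H, W) -> (N, out_frames, H, W)."""
        f0 = self.head(x)
        y = f0
        for group in self.groups:
            y = group(y)
        return self.tail(self.body(y) + f0)


def build_rcan(config: RCANConfig | None = None, seed: int = 0) -> RCAN:
    """Construct an RCAN with the given (default: reference) configuration."""
    return RCAN(config or RCANConfig(), seed=seed)
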