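"""Video-style transformer for high-fidelity OS-SIM reconstruction.

The three raw frames are embedded into a feature map and passed through a
sequence of windowed channel attention blocks (WCABs). Each WCAB is a pair
of Swin-style transformer layers — windowed multi-head self-attention with
the window partition shifted on alternate layers, plus an MLP, both with
residual connections and layer norm — followed by one residual channel
attention block. A final convolution fuses the features into a single
reconstructed frame. Joint attention over the three frames is what lets the
network fuse moving structure without the shadowing artefacts of subtractive
demodulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ossim.nn.autodiff import Tensor
from ossim.nn.layers import Conv2d, LayerNorm, Linear, Module, parameter
from ossim.nn.rcan import RCAB


@dataclass(frozen=True)
class VSRConfig:
    n_wcabs: int = 5
    swin_layers_per_wcab: int = 2
    window_size: int = 8
    n_heads: int = 4
    embed_dim: int = 48
    mlp_ratio: float = 2.0
    reduction: int = 4
    in_frames: int = 3
    out_frames: int = 1

    def __post_init__(self) -> None:
        for name in ("n_wcabs", "swin_layers_per_wcab", "window_size", "n_heads", "in_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.embed_dim % self.reduction != 0:
            raise ValueError("embed_dim must be divisible by the attention reduction")


def tiny_vsr_config() -> VSRConfig:
    """A configuration small enough to train on a single CPU in minutes."""
    return VSRConfig(n_wcabs=2, swin_layers_per_wcab=2, window_size=8, n_heads=2, embed_dim=16)


class WindowAttention(Module):
    """Multi-head self-attention within (ws x ws) windows.

    A learnable per-head (T x T) additive bias plays the role of the
    relative-position bias. The attention weights of the last forward pass
    are kept on ``last_attention`` for inspection.
    """

    def __init__(self, dim: int, n_heads: int, window_size: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        t = window_size * window_size
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.pos_bias = parameter(np.zeros((n_heads, t, t)))
        self.last_attention: np.ndarray | None = None

    def forward(self, tokens: Tensor) -> Tensor:
        b, t, c = tokens.shape
        h, d = self.n_heads, self.head_dim

        def split(x: Tensor) -> Tensor:  # (B,T,C) -> (B,h,T,d)
            return x.reshape(b, t, h, d).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(tokens)), split(self.k(tokens)), split(self.v(tokens))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d)) + self.pos_bias
        attn = logits.softmax(axis=-1)
        self.last_attention = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


def _window_partition(x: Tensor, window_size: int) -> tuple[Tensor, tuple[int, int, int]]:
    """(N, C, H, W) -> (N * nH * nW, ws*ws, C) token windows."""
    n, c, hgt, wid = x.shape
    ws = window_size
    if hgt % ws or wid % ws:
        pad_h = (-hgt) % ws
        pad_w = (-wid) % ws
        raise ValueError(
            f"spatial shape ({hgt}, {wid}) is not divisible by the window size {ws}; "
            f"pad by ({pad_h}, {pad_w}) pixels first"
        )
    nh, nw = hgt // ws, wid // ws
    tokens = (
        x.transpose(0, 2, 3, 1)
        .reshape(n, nh, ws, nw, ws, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n * nh * nw, ws * ws, c)
    )
    return tokens, (n, nh, nw)


def _window_merge(tokens: Tensor, meta: tuple[int, int, int], window_size: int, channels: int) -> Tensor:
    n, nh, nw = meta
    ws = window_size
    return (
        tokens.reshape(n, nh, nw, ws, ws, channels)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, nh * ws, nw * ws, channels)
        .transpose(0, 3, 1, 2)
    )


class SwinLayer(Module):
    """One windowed-attention transformer layer, cyclically shifted if asked."""

    def __init__(self, config: VSRConfig, shifted: bool, rng: np.random.Generator):
        self.shifted = shifted
        self.window_size = config.window_size
        self.norm1 = LayerNorm(config.embed_dim)
        self.attn = WindowAttention(config.embed_dim, config.n_heads, config.window_size, rng)
        self.norm2 = LayerNorm(config.embed_dim)
        hidden = int(config.embed_dim * config.mlp_ratio)
        self.mlp_in = Linear(config.embed_dim, hidden, rng)
        self.mlp_out = Linear(hidden, config.embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shift = self.window_size // 2 if self.shifted else 0
        y = x.roll((-shift, -shift), axis=(2, 3)) if shift else x
        tokens, meta = _window_partition(y, self.window_size)
        tokens = tokens + self.attn(self.norm1(tokens))
        tokens = tokens + self.mlp_out(self.mlp_in(self.norm2(tokens)).gelu())
        y = _window_merge(tokens, meta, self.window_size, c)
        return y.roll((shift, shift), axis=(2, 3)) if shift else y


class WCAB(Module):
    """Windowed channel attention block: Swin layers then one RCAB."""

    def __init__(self, config: VSRConfig, rng: np.random.Generator, shift_offset: int = 0):
        self.swin_layers = [
            SwinLayer(config, shifted=((i + shift_offset) % 2 == 1), rng=rng)
            for i in range(config.swin_layers_per_wcab)
        ]
        self.rcab = RCAB(config.embed_dim, 3, config.reduction, rng)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.swin_layers:
            x = layer(x)
        return self.rcab(x)


class VSR(Module):
    def __init__(self, config: VSRConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.embed = Conv2d(config.in_frames, config.embed_dim, 3, rng)
        self.wcabs = [WCAB(config, rng) for _ in range(config.n_wcabs)]
        self.fuse = Conv2d(config.embed_dim, config.out_frames, 3, rng)

    @property
    def spatial_multiple(self) -> int:
        return self.config.window_size

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, in_frames, H, W) -> (N, out_frames, H, W); H, W must be
        multiples of the window size."""
        y = self.embed(x)
        skip = y
        for wcab in self.wcabs:
            y = wcab(y)
        return self.fuse(y + skip)


def build_vsr(config: VSRConfig | None = None, seed: int = 0) -> VSR:
    """Construct a VSR network with the given (default: reference) configuration."""
    return VSR(config or VSRConfig(), seed=seed)
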