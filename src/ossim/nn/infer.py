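"""Tiled network inference on raw OS-SIM stacks."""

from __future__ import annotations

import numpy as np

from ossim.forward import OSSimStack
from ossim.nn.autodiff import Tensor
from ossim.nn.data import percentile_normalise
from ossim.nn.layers import Module


def _pad_to_multiple(img: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape[-2:]
    ph, pw = (-h) % multiple, (-w) % multiple
    if ph or pw:
        img = np.pad(img, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return img, (ph, pw)


def _blend_weight(
    h: int, w: int, overlap: int, borders: tuple[bool, bool, bool, bool]
) -> np.ndarray:
    """Per-tile blending weight: flat interior, linear ramp in the overlap.

    A margin of ``overlap // 4`` at interior tile edges gets zero weight —
    predictions there are contaminated by the tile's padding boundary (the
    network's receptive field crosses the cut). Sides flush with the image
    border keep full weight: their padding matches full-frame inference.
    ``borders`` flags (top, bottom, left, right) image-border sides.
    """
    margin = overlap // 4

    def ramp(n: int, at_start: bool, at_end: bool) -> np.ndarray:
        r = np.ones(n)
        k = min(overlap - margin, n // 2)
        if not at_start:
            r[:margin] = 0.0
            if k > margin:
                r[margin:k] = np.arange(1, k - margin + 1) / (k - margin + 1)
        if not at_end:
            r[n - margin :] = 0.0
            if k > margin:
                r[n - k : n - margin] = (np.arange(1, k - margin + 1) / (k - margin + 1))[::-1]
        return r

    top, bottom, left, right = borders
    return np.outer(ramp(h, top, bottom), ramp(w, left, right))


def _forward_frames(model: Module, frames: np.ndarray) -> np.ndarray:
    multiple = getattr(model, "spatial_multiple", 1)
    padded, (ph, pw) = _pad_to_multiple(frames, multiple)
    out = model(Tensor(padded[None].astype(np.float32))).data[0, 0]
    if ph or pw:
        out = out[: out.shape[0] - ph, : out.shape[1] - pw]
    return out


def reconstruct_ml(
    model: Module,
    stack: OSSimStack | np.ndarray,
    tile: int = 128,
    overlap: int = 32,
) -> np.ndarray:
    """Reconstruct a stack with a trained network, tile by tile.

    The raw triplet is percentile-normalised (the convention recorded with
    every checkpoint), cut into overlapping tiles that are blended with
    linear ramps in the overlap, and the result is clipped at zero. Frames
    smaller than one tile are processed whole. For z/t stacks the model is
    applied plane-wise and a volume is returned.
    """
    if isinstance(stack, OSSimStack) and stack.axes != "pyx":
        return np.stack(
            [reconstruct_ml(model, stack.plane(i), tile, overlap) for i in range(stack.n_planes)]
        )
    frames = stack.phase_frames() if isinstance(stack, OSSimStack) else np.asarray(stack)
    if frames.ndim != 3:
        raise ValueError(f"expected (n_frames, H, W) input, got shape {frames.shape}")
    expected = getattr(model, "config", None)
    if expected is not None and frames.shape[0] != expected.in_frames:
        raise ValueError(
            f"model expects {expected.in_frames} input frames, stack has {frames.shape[0]}"
        )
    frames = percentile_normalise(frames)
    h, w = frames.shape[-2:]
    if h <= tile and w <= tile:
        return np.clip(_forward_frames(model, frames), 0.0, None)
    step = tile - overlap
    out = np.zeros((h, w))
    weight = np.zeros((h, w))
    for y0 in range(0, h, step):
        for x0 in range(0, w, step):
            y1, x1 = min(y0 + tile, h), min(x0 + tile, w)
            y0a, x0a = max(y1 - tile, 0), max(x1 - tile, 0)
            patch = frames[:, y0a:y1, x0a:x1]
            pred = _forward_frames(model, patch)
            wgt = _blend_weight(
                y1 - y0a, x1 - x0a, overlap, (y0a == 0, y1 == h, x0a == 0, x1 == w)
            )
            out[y0a:y1, x0a:x1] += pred * wgt
            weight[y0a:y1, x0a:x1] += wgt
            if x1 >= w:
                break
        if y1 >= h:
            break
    return np.clip(out / np.maximum(weight, 1e-12), 0.0, None)


def ml_method(model: Module, tile: int = 128, overlap: int = 32):
    """Wrap a trained model as a reconstruction callable for the benchmarks.

    The pattern-estimate argument of the benchmark interface is accepted and
    ignored: learned reconstruction needs no system-parameter estimation.
    """

    def fn(stack, pattern_estimate=None):
        return reconstruct_ml(model, stack, tile=tile, overlap=overlap)

    return fn
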