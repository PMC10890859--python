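"""Ground-truth structure generators.

Three families of synthetic scenes drive simulation and training:

* 3D filament meshes, emulating cytoskeleton-like samples for volumetric
  benchmarks;
* procedural 2D textures (multiscale noise, blob fields, 2D filaments) that
  stand in for diverse natural-image training material so the package is
  fully self-contained;
* moving-object frame triplets emulating samples that move between the three
  phase-stepped exposures.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage


@dataclass
class Phantom3D:
    """A nonnegative intensity volume in [0, 1] with its provenance."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (86.0, 86.0, 86.0)
    kind: str = "filament-mesh"
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


@dataclass
class MovingTriplet:
    """Three sequential in-focus frames with per-object pixel velocities."""

    frames: np.ndarray  # (3, y, x)
    displacements: np.ndarray  # (n_objects, 2) pixels/frame, (dy, dx)


def _ball(radius: float) -> np.ndarray:
    r = max(int(np.ceil(radius)), 0)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zz**2 + yy**2 + xx**2) <= radius**2 + 1e-9


def _random_curve(rng: np.random.Generator, shape, n_steps: int) -> np.ndarray:
    """Smooth random walk with momentum, reflected at the volume boundary."""
    pos = rng.uniform([0, 0, 0], shape)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    step = 0.5  # voxels, dense enough for 26-connected rasterisation
    pts = [pos.copy()]
    for _ in range(n_steps):
        direction += rng.normal(scale=0.08, size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + step * direction
        for ax in range(3):
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
                direction[ax] = -direction[ax]
            elif pos[ax] > shape[ax] - 1:
                pos[ax] = 2 * (shape[ax] - 1) - pos[ax]
                direction[ax] = -direction[ax]
        pts.append(pos.copy())
    return np.array(pts)


def generate_filament_mesh(
    shape: tuple[int, int, int],
    n_filaments: int = 20,
    thickness_voxels: float = 2.0,
    seed: int = 0,
    steps_per_filament: int | None = None,
) -> Phantom3D:
    """A mesh of dilated smooth random 3D curves, intensity 1 on filaments.

    Each filament is a momentum random walk rasterised at half-voxel steps and
    dilated with a spherical structuring element of the requested thickness,
    so each curve forms a single connected component.
    """
    if any(s < 16 for s in shape):
        raise ValueError(f"volume shape {shape} too small; need at least 16 per axis")
    if n_filaments < 0:
        raise ValueError("n_filaments must be nonnegative")
    if thickness_voxels < 1:
        raise ValueError("thickness must be at least one voxel")
    rng = np.random.default_rng(seed)
    if steps_per_filament is None:
        steps_per_filament = 3 * max(shape)
    vol = np.zeros(shape, dtype=bool)
    for _ in range(n_filaments):
        pts = _random_curve(rng, np.array(shape, dtype=float), steps_per_filament)
        idx = np.clip(np.round(pts).astype(int), 0, np.array(shape) - 1)
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if n_filaments > 0 and thickness_voxels > 1:
        vol = ndimage.binary_dilation(vol, structure=_ball(thickness_voxels / 2.0))
    return Phantom3D(
        data=vol.astype(np.float64),
        kind="filament-mesh",
        params={
            "n_filaments": n_filaments,
            "thickness_voxels": thickness_voxels,
            "steps_per_filament": steps_per_filament,
            "shape": tuple(shape),
        },
        seed=seed,
    )


TEXTURE_KINDS = ("multiscale-noise", "blobs", "filaments-2d")


def generate_texture(shape: tuple[int, int], seed: int = 0, kind: str = "multiscale-noise") -> np.ndarray:
    """Procedural 2D texture in [0, 1] with structure across several octaves.

    These textures provide the statistical diversity that natural-image
    datasets supply in network training: broad-band spatial frequency content
    and varied morphology, without any external data dependency.
    """
    if kind not in TEXTURE_KINDS:
        raise ValueError(f"unknown texture kind {kind!r}; choose from {TEXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    if kind == "multiscale-noise":
        img = np.zeros(shape)
        for octave, sigma in enumerate((1.0, 2.0, 4.0, 8.0, 16.0)):
            layer = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
            layer /= np.abs(layer).max() + 1e-12
            img += layer / (octave + 1)
    elif kind == "blobs":
        img = np.zeros(shape)
        n_blobs = max(6, (ny * nx) // 512)
        yy, xx = np.mgrid[0:ny, 0:nx]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
            s = rng.uniform(1.5, min(ny, nx) / 8)
            amp = rng.uniform(0.3, 1.0)
            img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    else:  # filaments-2d
        img = np.zeros(shape, dtype=bool)
        n_curves = max(4, min(ny, nx) // 16)
        for _ in range(n_curves):
            pos = rng.uniform([0, 0], [ny - 1, nx - 1])
            d = rng.normal(size=2)
            d /= np.linalg.norm(d)
            for _ in range(4 * max(ny, nx)):
                d += rng.normal(scale=0.15, size=2)
                d /= np.linalg.norm(d)
                pos = pos + 0.5 * d
                for ax, lim in enumerate((ny, nx)):
                    if pos[ax] < 0 or pos[ax] > lim - 1:
                        d[ax] = -d[ax]
                        pos[ax] = np.clip(pos[ax], 0, lim - 1)
                img[int(round(pos[0])), int(round(pos[1]))] = True
        img = ndimage.gaussian_filter(img.astype(float), 1.0)
    img = img - img.min()
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img


def fourier_shift(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Sub-pixel translation by a Fourier phase ramp (periodic boundary)."""
    spec = np.fft.fft2(image)
    shifted = ndimage.fourier_shift(spec, shift)
    return np.real(np.fft.ifft2(shifted))


def generate_moving_triplet(
    shape: tuple[int, int],
    n_objects: int = 6,
    max_displacement: float = 2.0,
    seed: int = 0,
) -> MovingTriplet:
    """Three frames of rigidly translating Gaussian-blob objects.

    Object velocities are drawn uniformly in direction with speed uniform in
    [0, max_displacement] pixels/frame; sub-pixel motion uses Fourier
    translation so displacements below the pixel pitch are representable.
    """
    if max_displacement < 0:
        raise ValueError("max_displacement must be nonnegative")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    sprites = []
    velocities = np.zeros((n_objects, 2))
    for i in range(n_objects):
        cy = rng.uniform(0.2 * ny, 0.8 * ny)
        cx = rng.uniform(0.2 * nx, 0.8 * nx)
        s = rng.uniform(1.5, 4.0)
        amp = rng.uniform(0.4, 1.0)
        sprites.append(amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)))
        angle = rng.uniform(0, 2 * np.pi)
        speed = rng.uniform(0, max_displacement)
        velocities[i] = speed * np.array([np.sin(angle), np.cos(angle)])
    frames = np.zeros((3, ny, nx))
    for t in range(3):
        for i, sprite in enumerate(sprites):
            frames[t] += fourier_shift(sprite, tuple(t * velocities[i]))
    frames = np.clip(frames, 0.0, None)
    peak = frames.max()
    if peak > 0:
        frames /= peak
    return MovingTriplet(frames=frames, displacements=velocities)
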