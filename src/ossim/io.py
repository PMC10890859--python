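"""File I/O and run configuration.

Raw stacks travel as multi-page float32 TIFF with page order phase-fastest
and a JSON sidecar carrying every parameter needed to regenerate the file
bit-exactly. Axis order of a TIFF is never inferred: readers must declare a
layout such as "phase", "z,phase" or "phase,t" (fastest-varying axis last).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from ossim.forward import NoiseModel, OSSimStack
from ossim.optics import OpticalConfig, SinusoidalPattern


class LayoutError(ValueError):
    """Raised when a TIFF's page count is inconsistent with the declared layout."""


_AXIS_TOKENS = {"phase": "p", "z": "z", "t": "t"}


def _parse_layout(layout: str) -> list[str]:
    tokens = [t.strip() for t in layout.split(",") if t.strip()]
    for t in tokens:
        if t not in _AXIS_TOKENS:
            raise LayoutError(f"unknown axis {t!r}; valid axes: {sorted(_AXIS_TOKENS)}")
    if "phase" not in tokens:
        raise LayoutError("layout must include the 'phase' axis")
    if len(set(tokens)) != len(tokens):
        raise LayoutError("layout axes must be unique")
    return tokens


def read_stack(path: str | Path, layout: str = "phase") -> OSSimStack:
    """Read a multi-page TIFF as an OS-SIM stack with a declared axis layout.

    Integer data is promoted to float64 without rescaling. The page count
    must be 3 times the product of the non-phase axes; otherwise a
    LayoutError names the expected multiple. A sidecar JSON written by
    :func:`write_stack`, if present, restores pattern/optics/noise metadata.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    if n_pages % 3 != 0:
        raise LayoutError(
            f"{path.name} has {n_pages} pages, which is not a multiple of 3 "
            "(three phase frames per plane are required)"
        )
    tokens = _parse_layout(layout)
    other = n_pages // 3
    dims = [3 if t == "phase" else other for t in tokens]
    if int(np.prod(dims)) != n_pages:
        raise LayoutError(
            f"layout {layout!r} implies {int(np.prod(dims))} pages, file has {n_pages}"
        )
    data = pages.astype(np.float64).reshape(*dims, *pages.shape[1:])
    # canonical order: leading non-phase axes in declared order, then phase
    p_pos = tokens.index("phase")
    order = [i for i in range(len(tokens)) if i != p_pos] + [p_pos]
    data = np.transpose(data, order + [len(tokens), len(tokens) + 1])
    axes = "".join(_AXIS_TOKENS[tokens[i]] for i in order if i != p_pos) + "pyx"
    kwargs: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("pattern"):
            pat = dict(meta["pattern"])
            pat["phase_offsets"] = tuple(pat["phase_offsets"])
            kwargs["pattern"] = SinusoidalPattern(**pat)
        if meta.get("optics"):
            opt = dict(meta["optics"])
            opt["voxel_size"] = tuple(opt["voxel_size"])
            kwargs["optics"] = OpticalConfig(**opt)
        if meta.get("noise"):
            kwargs["noise"] = NoiseModel(**meta["noise"])
        kwargs["pixel_size_nm"] = meta.get("pixel_size_nm", 86.0)
        kwargs["meta"] = meta.get("meta", {})
    return OSSimStack(data=data, axes=axes, **kwargs)


def write_stack(stack: OSSimStack, path: str | Path, force: bool = False) -> Path:
    """Write a stack as float32 multi-page TIFF plus a JSON metadata sidecar.

    Pages are ordered phase-fastest. Refuses to overwrite an existing file
    unless ``force`` is set.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    pages = stack.data.reshape(-1, *stack.frame_shape).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "axes": stack.axes,
        "shape": list(stack.data.shape),
        "pixel_size_nm": stack.pixel_size_nm,
        "pattern": dataclasses.asdict(stack.pattern) if stack.pattern else None,
        "optics": dataclasses.asdict(stack.optics) if stack.optics else None,
        "noise": dataclasses.asdict(stack.noise) if stack.noise else None,
        "meta": stack.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def write_volume(volume: np.ndarray, path: str | Path, force: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    arr = np.asarray(volume, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_OPTICS_KEYS = {
    "na": "numerical_aperture",
    "lambda_em_nm": "emission_wavelength",
    "lambda_ex_nm": "excitation_wavelength",
    "ri": "refractive_index",
    "voxel_nm": "voxel_size",
}
_PATTERN_KEYS = {
    "frequency": "spatial_frequency",
    "orientation": "orientation",
    "modulation": "modulation_depth",
    "phase_offsets": "phase_offsets",
}
_NOISE_KEYS = {
    "gaussian_sigma": "gaussian_sigma",
    "eta": "poisson_factor",
}
_KNOWN_BLOCKS = {
    "optics",
    "pattern",
    "noise",
    "phantom",
    "reconstruction",
    "training",
    "evaluation",
    "seed",
}


class ConfigError(ValueError):
    """Raised on unknown keys or invalid values in a run configuration."""


def _map_block(block: dict, mapping: dict[str, str], name: str) -> dict:
    unknown = set(block) - set(mapping)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in config block {name!r}")
    return {mapping[k]: v for k, v in block.items()}


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for a simulation / reconstruction run."""

    optics: OpticalConfig
    pattern: SinusoidalPattern | None
    noise: NoiseModel | None
    phantom: dict[str, Any]
    reconstruction: dict[str, Any]
    training: dict[str, Any]
    evaluation: dict[str, Any]
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _KNOWN_BLOCKS
        if unknown:
            raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
        opt_raw = _map_block(raw.get("optics", {}), _OPTICS_KEYS, "optics")
        if "voxel_size" in opt_raw:
            v = opt_raw["voxel_size"]
            opt_raw["voxel_size"] = tuple(v) if isinstance(v, (list, tuple)) else (v, v, v)
        try:
            optics = OpticalConfig(**opt_raw)
        except ValueError as exc:
            raise ConfigError(f"invalid optics block: {exc}") from exc
        pattern = None
        if "pattern" in raw:
            pat_raw = _map_block(raw["pattern"], _PATTERN_KEYS, "pattern")
            if "phase_offsets" in pat_raw:
                pat_raw["phase_offsets"] = tuple(pat_raw["phase_offsets"])
            try:
                pattern = SinusoidalPattern(**pat_raw)
            except ValueError as exc:
                raise ConfigError(f"invalid pattern block: {exc}") from exc
        noise = None
        if "noise" in raw:
            try:
                noise = NoiseModel(**_map_block(raw["noise"], _NOISE_KEYS, "noise"))
            except ValueError as exc:
                raise ConfigError(f"invalid noise block: {exc}") from exc
        return cls(
            optics=optics,
            pattern=pattern,
            noise=noise,
            phantom=raw.get("phantom", {}),
            reconstruction=raw.get("reconstruction", {}),
            training=raw.get("training", {}),
            evaluation=raw.get("evaluation", {}),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)
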