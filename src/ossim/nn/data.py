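"""Randomised training-set generation and dataset I/O.

Datasets mix static scenes (procedural textures under randomised optics)
with moving scenes (translating objects seen at three successive positions
by the three phase frames). Inputs and targets are percentile-normalised
per example, so networks learn structure-to-structure mappings independent
of absolute photon counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import h5py
import numpy as np

from ossim.forward import GeneratorConfig, TrainingExample, make_training_example

NORM_PERCENTILES = (1.0, 99.0)


def percentile_normalise(arr: np.ndarray, lo: float = 1.0, hi: float = 99.0) -> np.ndarray:
    a, b = np.percentile(arr, [lo, hi])
    if b <= a:
        return np.zeros_like(arr, dtype=np.float32)
    return ((arr - a) / (b - a)).astype(np.float32)


@dataclass(frozen=True)
class DatasetSpec:
    """Static/moving mix and the generator ranges for each component."""

    n_static: int = 2000
    n_moving: int = 0
    static: GeneratorConfig = field(default_factory=GeneratorConfig)
    moving: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(moving=True))

    def __post_init__(self) -> None:
        if self.n_static < 0 or self.n_moving < 0:
            raise ValueError("example counts must be nonnegative")
        if self.n_static + self.n_moving == 0:
            raise ValueError("the dataset must contain at least one example")


@dataclass
class TrainingSet:
    """Normalised (input, target) arrays plus per-example provenance."""

    inputs: np.ndarray  # (N, 3, H, W) float32 in ~[0, 1]
    targets: np.ndarray  # (N, 1, H, W) float32 in ~[0, 1]
    params: list[dict[str, Any]]

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_static(self) -> int:
        return sum(1 for p in self.params if not p["moving"])

    @property
    def n_moving(self) -> int:
        return sum(1 for p in self.params if p["moving"])


def generate_training_set(
    spec: DatasetSpec, seed: int = 0, keep_examples: bool = False
) -> TrainingSet | tuple[TrainingSet, list[TrainingExample]]:
    """Generate a reproducible dataset of (raw triplet, sectioned target) pairs.

    Static and moving examples are interleaved deterministically from the
    per-example seeds derived from ``seed``; the counts match the spec
    exactly. With ``keep_examples`` the full simulation provenance of every
    example is returned alongside.
    """
    rng = np.random.default_rng(seed)
    kinds = ["static"] * spec.n_static + ["moving"] * spec.n_moving
    rng.shuffle(kinds)
    inputs, targets, params, examples = [], [], [], []
    for kind in kinds:
        gen = spec.static if kind == "static" else replace(spec.moving, moving=True)
        ex_seed = int(rng.integers(2**31))
        ex = make_training_example(gen, seed=ex_seed)
        inputs.append(percentile_normalise(ex.stack.data, *NORM_PERCENTILES))
        targets.append(percentile_normalise(ex.target, *NORM_PERCENTILES)[None])
        params.append(ex.params)
        if keep_examples:
            examples.append(ex)
    ts = TrainingSet(
        inputs=np.stack(inputs), targets=np.stack(targets), params=params
    )
    return (ts, examples) if keep_examples else ts


def save_dataset(ts: TrainingSet, path: str) -> None:
    import json

    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=ts.inputs, compression="gzip")
        f.create_dataset("targets", data=ts.targets, compression="gzip")
        f.attrs["params_json"] = json.dumps(ts.params)
        f.attrs["normalisation"] = f"percentile {NORM_PERCENTILES}"


def load_dataset(path: str) -> TrainingSet:
    import json

    with h5py.File(path, "r") as f:
        return TrainingSet(
            inputs=f["inputs"][:],
            targets=f["targets"][:],
            params=json.loads(f.attrs["params_json"]),
        )
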