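"""Image, configuration and report I/O.

TIFF is the canonical intermediate: float images are stored as float32
(lossless at stored precision), integer inputs as uint16.  PNG output is
8-bit and intended for visualization only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .phantom import DEFAULT_CAPACITY, MAX_VAL


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as float64 (rows = depth, cols = A-lines)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB(A) visualization to gray
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image")
    return arr.astype(np.float64)


def write_image(path: str | Path, image: np.ndarray,
                max_val: float = MAX_VAL) -> None:
    """Write TIFF (float32, or uint16 for integer input) or 8-bit PNG."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        if np.issubdtype(image.dtype, np.integer):
            tifffile.imwrite(path, image.astype(np.uint16))
        else:
            tifffile.imwrite(path, image.astype(np.float32))
    elif path.suffix.lower() == ".png":
        arr = np.clip(np.asarray(image, float), 0, max_val)
        iio.imwrite(path, np.round(arr * 255.0 / max_val).astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables in one flat, YAML-serializable record."""

    patch_height: int = 8
    patch_width: int = 8
    n_atoms: int = 128
    sparsity: int = 2
    train_error: float = 5.28
    iterations: int = 20
    capacity: float = DEFAULT_CAPACITY
    min_run: int = 1
    stride: int = 1
    seed: int = 0
    process_all_patches: bool = True
    max_training_patches: int = 200_000
    max_val: float = MAX_VAL

    def __post_init__(self) -> None:
        if self.patch_height < 1 or self.patch_width < 1:
            raise ValueError("patch size must be positive")
        if self.sparsity < 1 or self.n_atoms < 1 or self.iterations < 1:
            raise ValueError("sparsity/n_atoms/iterations must be >= 1")
        if self.train_error <= 0 or self.capacity <= 0:
            raise ValueError("train_error and capacity must be positive")
        if self.stride < 1 or self.min_run < 1:
            raise ValueError("stride and min_run must be >= 1")

    @property
    def patch_size(self) -> tuple[int, int]:
        return (self.patch_height, self.patch_width)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(cfg), f, sort_keys=False)


def write_report_csv(rows: list[dict], path: str | Path) -> None:
    import csv

    rows = list(rows)
    if not rows:
        raise ValueError("no report rows")
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def write_report_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
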