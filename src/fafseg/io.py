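"""Raster and report I/O.

Fixed on-disk dialect: binary masks are single-channel 8-bit rasters with
foreground 255 (any nonzero value reads back as foreground); ternary maps
encode background/potential/confident as 0/128/255; probability maps are
16-bit PNGs scaled to the full range; prediction and annotation stacks
are directories of per-member PNGs (or multi-page TIFFs).  Metric reports
serialize as CSV (one row per image pair) and JSON (aggregate), with
undefined metrics written as empty cells / JSON null — never as 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import ternary as tern

_TERNARY_CODES = {tern.B: 0, tern.P: 128, tern.C: 255}
_TERNARY_DECODE = {v: k for k, v in _TERNARY_CODES.items()}


def _read_single_channel(path: str | Path, reduce: str | None) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if reduce == "first":
            arr = arr[..., 0]
        elif reduce == "any":
            arr = arr.max(axis=-1)
        else:
            raise ValueError(f"{path} is multi-channel and no reduction rule is configured")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel raster, got shape {arr.shape}")
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale 8-bit image."""
    return _read_single_channel(path, reduce="first").astype(np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_mask(path: str | Path, reduce: str | None = None) -> np.ndarray:
    """Read a binary mask: any value > 0 is foreground."""
    return _read_single_channel(path, reduce) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 0/255 single-channel."""
    m = np.asarray(mask).astype(bool)
    iio.imwrite(Path(path), (m * np.uint8(255)))


def read_ternary(path: str | Path) -> np.ndarray:
    """Read a ternary map from the 0/128/255 encoding."""
    arr = _read_single_channel(path, reduce=None)
    out = np.zeros(arr.shape, dtype=np.uint8)
    known = np.zeros(arr.shape, dtype=bool)
    for code, label in _TERNARY_DECODE.items():
        hit = arr == code
        out[hit] = label
        known |= hit
    if not known.all():
        bad = np.unique(arr[~known])
        raise ValueError(f"{path}: pixel values {bad.tolist()} are not a ternary encoding")
    return out


def write_ternary(tmap: np.ndarray, path: str | Path) -> None:
    """Write a ternary map with the fixed 0/128/255 encoding (lossless)."""
    t = tern.validate_ternary(tmap)
    out = np.zeros(t.shape, dtype=np.uint8)
    for label, code in _TERNARY_CODES.items():
        out[t == label] = code
    iio.imwrite(Path(path), out)


def read_probability_map(path: str | Path) -> np.ndarray:
    arr = _read_single_channel(path, reduce=None)
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return arr.astype(float) / scale


def write_probability_map(pmap: np.ndarray, path: str | Path) -> None:
    """Write probabilities in [0, 1] as a 16-bit PNG (fixed /65535 scaling)."""
    p = np.clip(np.asarray(pmap, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(p * 65535).astype(np.uint16))


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    """Write a (k, H, W) probability stack as a multi-page 16-bit TIFF."""
    p = np.clip(np.asarray(stack, dtype=float), 0.0, 1.0)
    tifffile.imwrite(Path(path), np.round(p * 65535).astype(np.uint16))


def read_stack_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float) / 65535.0


def write_mask_stack(stack: np.ndarray, directory: str | Path, prefix: str = "expert") -> list[Path]:
    """Write each layer of a binary stack as ``<prefix>_<k>.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, layer in enumerate(np.asarray(stack).astype(bool)):
        p = directory / f"{prefix}_{k}.png"
        write_mask(layer, p)
        paths.append(p)
    return paths


def read_mask_stack(paths: list[str | Path]) -> np.ndarray:
    masks = [read_mask(p) for p in paths]
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"stack layers disagree on grid: {shapes}")
    return np.stack(masks)


def write_distance_matrix(D: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(D, dtype=float)).to_csv(path, index=False, header=False)


def read_distance_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def write_report(rows: list[dict], aggregate: dict, csv_path: str | Path | None = None,
                 json_path: str | Path | None = None) -> None:
    """Serialize per-pair rows as CSV and the aggregate as JSON.

    ``None`` metric values survive as empty CSV cells and JSON nulls.
    """
    if csv_path is not None:
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({"aggregate": aggregate, "rows": rows}, fh, indent=2)


def save_scene_bundle(scene, directory: str | Path) -> Path:
    """Write a synthetic scene as a directory of rasters plus scene.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_image(scene.image, directory / "image.png")
    write_mask(scene.true_hf, directory / "true_hf.png")
    write_mask(scene.true_ra, directory / "true_ra.png")
    if scene.expert_stack is not None:
        write_mask_stack(scene.expert_stack, directory, prefix="expert")
    registry = [
        {
            "kind": c.kind,
            "center": [float(c.center[0]), float(c.center[1])],
            "semi_axes": [float(c.semi_axes[0]), float(c.semi_axes[1])],
            "angle": float(c.angle),
            "brightness_offset": float(c.brightness_offset),
            "anchor": bool(c.anchor),
            "area": c.area,
            "visibility": c.visibility,
        }
        for c in scene.components
    ]
    with open(directory / "scene.yaml", "w") as fh:
        yaml.safe_dump({"params": scene.params, "components": registry}, fh, sort_keys=False)
    return directory
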