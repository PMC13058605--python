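"""File round-trips for the pipeline's modalities.

Images are single-channel 16-bit TIFFs with the physical pixel size recorded
in a YAML sidecar (``<image>.meta.yaml``); voxel masks are multi-page TIFF
stacks with a matching sidecar; tabular data travel as TSV.  Generation and
analysis parameters are echoed into a YAML config snapshot for provenance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .morphometry import VoxelVolume
from .segmentation import ReflectanceImage

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
    "write_config_snapshot",
]

_U16_MAX = 65535


def write_image(img: ReflectanceImage, path: str | Path) -> Path:
    """Write a [0, 1] reflectance image as 16-bit TIFF plus metadata sidecar."""
    path = Path(path)
    data = np.clip(img.intensities, 0, 1)
    tifffile.imwrite(path, (data * _U16_MAX).round().astype(np.uint16))
    meta = {
        "pixel_size_um": float(img.pixel_size),
        "group_min": float(img.group_min),
        "image_id": img.image_id,
        "bit_depth": 16,
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))
    return path


def read_image(path: str | Path) -> ReflectanceImage:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    data = tifffile.imread(path).astype(float) / _U16_MAX
    return ReflectanceImage(
        data,
        pixel_size=meta["pixel_size_um"],
        group_min=meta.get("group_min", 0.0),
        image_id=meta.get("image_id", path.stem),
    )


def write_mask(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a binary voxel mask as a multi-page 8-bit TIFF stack + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.values.astype(np.uint8))
    meta = {
        "voxel_size_um": [float(s) for s in vol.spacing],
        "cell_id": vol.cell_id,
        "group_min": float(vol.group_min),
        "time_h": float(vol.time_h),
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))
    return path


def read_mask(path: str | Path) -> VoxelVolume:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    data = tifffile.imread(path).astype(bool)
    return VoxelVolume(
        data,
        voxel_size=tuple(meta["voxel_size_um"]),
        cell_id=meta.get("cell_id", path.stem),
        group_min=meta.get("group_min", 0.0),
        time_h=meta.get("time_h", 0.0),
    )


def write_table(df: pd.DataFrame, path: str | Path, precision: int = 6) -> Path:
    """TSV with numeric columns at fixed significant digits for stable diffs."""
    path = Path(path)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.{precision}g}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_config_snapshot(config: Any, path: str | Path) -> Path:
    """Serialize a (possibly nested) dataclass config to YAML for provenance."""
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))
    return path
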