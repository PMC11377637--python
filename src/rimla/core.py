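"""Shared spatial containers and NIfTI/CSV I/O helpers."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: modality tags used throughout the package
MODALITIES = ("T1", "T2", "T2/T1")

#: canonical lesion-class order (enlarging, shrinking, stable, new)
CLASS_ORDER = ("enlarging", "shrinking", "stable", "new")


@dataclasses.dataclass
class QuantMap:
    """A 3-D scalar volume with physical voxel dimensions.

    The unit of all spatial computation: a quantitative map (T1 or T2 in
    ms, T2/T1 unitless) or a derived z-score map. ``data`` may contain
    NaN where a value is undefined (e.g. outside the atlas validity
    mask).
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"QuantMap requires a 3-D volume, got ndim={self.data.ndim}")
        vd = tuple(float(v) for v in self.voxel_dims)
        if len(vd) != 3 or any(v <= 0 for v in vd):
            raise ValueError(f"voxel_dims must be 3 positive floats, got {self.voxel_dims}")
        self.voxel_dims = vd

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in microlitres (1 mm^3 = 1 uL)."""
        return float(np.prod(self.voxel_dims))

    def same_grid(self, other: "QuantMap") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.voxel_dims, other.voxel_dims
        )


def _affine_from_voxel_dims(voxel_dims) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims
    return aff


def write_nifti(path, data: np.ndarray, voxel_dims) -> None:
    """Write a volume as NIfTI with a diagonal affine carrying voxel size."""
    img = nib.Nifti1Image(np.asarray(data), _affine_from_voxel_dims(voxel_dims))
    img.header.set_zooms(tuple(float(v) for v in voxel_dims))
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (data, voxel_dims in mm)."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), zooms


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a table with a fixed float format (9 significant digits)."""
    df.to_csv(path, index=False, float_format="%.9g")


def read_csv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV, raising a descriptive error on malformed content."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"CSV {path} is missing required columns {missing}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-entity RNG stream.

    Streams derived from (seed, *keys) are independent of processing
    order; string keys are hashed stably (crc32).
    """
    import zlib

    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            ints.append(int(k) & 0xFFFFFFFF)
        else:
            ints.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(ints)
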