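"""File formats: HDF5 projection sets and TIFF tile volumes.

Projection sets follow the data-exchange-style HDF5 layout::

    /exchange/data        (n_proj, rows, cols)  raw projections
    /exchange/data_dark   (n_dark, rows, cols)
    /exchange/data_white  (n_flat, rows, cols)
    /exchange/theta       (n_proj,) degrees
    attrs on /exchange: pixel_size_um, timestamp_s, grid_index, axis_offset_px

Tile volumes are 32-bit multi-page TIFF stacks (one page per z slice) with a
JSON sidecar carrying mosaic-space origin, voxel size, timestamp and the
reconstruction parameters used.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

__all__ = [
    "ProjectionSet", "TileVolume",
    "read_projection_set", "write_projection_set",
    "read_tile_volume", "write_tile_volume",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when an input file is missing a required dataset/attribute."""


@dataclass
class ProjectionSet:
    """One tile's raw projections plus calibration frames and metadata."""

    data: np.ndarray            # (n_proj, rows, cols)
    darks: np.ndarray           # (n_dark, rows, cols)
    flats: np.ndarray           # (n_flat, rows, cols)
    angles_deg: np.ndarray      # (n_proj,)
    pixel_size_um: float
    timestamp_s: float = 0.0
    grid_index: tuple[int, int, int] = (0, 0, 0)
    axis_offset_px: float = 0.0

    @property
    def n_proj(self) -> int:
        return self.data.shape[0]

    @property
    def detector_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class TileVolume:
    """Reconstructed tile block positioned in mosaic space."""

    volume: np.ndarray          # (nz, ny, nx) float32
    voxel_size_um: float
    origin_mm: tuple[float, float, float]   # mm position of voxel (0,0,0) centre
    grid_index: tuple[int, int, int] = (0, 0, 0)
    timestamp_s: float = 0.0
    meta: dict = field(default_factory=dict)


def write_projection_set(pset: ProjectionSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("exchange")
        g.create_dataset("data", data=np.asarray(pset.data, dtype=np.float32))
        g.create_dataset("data_dark", data=np.asarray(pset.darks, dtype=np.float32))
        g.create_dataset("data_white", data=np.asarray(pset.flats, dtype=np.float32))
        g.create_dataset("theta", data=np.asarray(pset.angles_deg, dtype=np.float64))
        g.attrs["pixel_size_um"] = float(pset.pixel_size_um)
        g.attrs["timestamp_s"] = float(pset.timestamp_s)
        g.attrs["grid_index"] = np.asarray(pset.grid_index, dtype=np.int64)
        g.attrs["axis_offset_px"] = float(pset.axis_offset_px)


def _require(group, name: str, path: str):
    if name not in group:
        raise SchemaError(f"{path}: missing dataset /exchange/{name}")
    return group[name]


def _require_attr(group, name: str, path: str):
    if name not in group.attrs:
        raise SchemaError(f"{path}: missing attribute /exchange@{name}")
    return group.attrs[name]


def read_projection_set(path: str) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        if "exchange" not in f:
            raise SchemaError(f"{path}: missing group /exchange")
        g = f["exchange"]
        data = _require(g, "data", path)[...]
        darks = _require(g, "data_dark", path)[...]
        flats = _require(g, "data_white", path)[...]
        theta = _require(g, "theta", path)[...]
        pix = float(_require_attr(g, "pixel_size_um", path))
        ts = float(_require_attr(g, "timestamp_s", path))
        gi = tuple(int(v) for v in _require_attr(g, "grid_index", path))
        ax = float(_require_attr(g, "axis_offset_px", path))
    return ProjectionSet(data=data, darks=darks, flats=flats,
                         angles_deg=theta, pixel_size_um=pix, timestamp_s=ts,
                         grid_index=gi, axis_offset_px=ax)


def write_tile_volume(tile: TileVolume, base_path: str) -> tuple[str, str]:
    """Write a tile volume as ``<base>.tif`` plus ``<base>.json`` sidecar."""
    tif_path = base_path + ".tif"
    json_path = base_path + ".json"
    tifffile.imwrite(tif_path, np.asarray(tile.volume, dtype=np.float32))
    sidecar = {
        "voxel_size_um": tile.voxel_size_um,
        "origin_mm": list(tile.origin_mm),
        "grid_index": list(tile.grid_index),
        "timestamp_s": tile.timestamp_s,
        "shape": list(tile.volume.shape),
        "meta": tile.meta,
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return tif_path, json_path


def read_tile_volume(base_path: str) -> TileVolume:
    tif_path = base_path + ".tif"
    json_path = base_path + ".json"
    if not os.path.exists(json_path):
        raise SchemaError(f"missing sidecar {json_path}")
    with open(json_path) as fh:
        sidecar = json.load(fh)
    vol = tifffile.imread(tif_path)
    if vol.ndim == 2:
        vol = vol[None]
    return TileVolume(volume=vol,
                      voxel_size_um=float(sidecar["voxel_size_um"]),
                      origin_mm=tuple(sidecar["origin_mm"]),
                      grid_index=tuple(sidecar["grid_index"]),
                      timestamp_s=float(sidecar.get("timestamp_s", 0.0)),
                      meta=sidecar.get("meta", {}))
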