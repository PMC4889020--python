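"""Volume containers and file I/O.

Grid conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` with z the section/depth axis, so slice
  index ``k`` sits at depth ``k * spacing_um`` micrometres;
* voxel spacing is isotropic, in micrometres (micro-CT protocols for
  paraffin-embedded lung tissue typically scan at 8 um);
* voxel ``i`` occupies the closed cube ``[i*s, (i+1)*s]`` per axis, so a
  voxel's volume is ``spacing_um ** 3`` um^3; tissue volumes are reported
  in mm^3 and number densities per mm^3.

Volumes are stored as multi-page TIFF (one page per z-slice, ascending z)
plus a JSON sidecar that is the single source of grid metadata; TIFF
resolution tags are ignored on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("foci3d")

UM3_PER_MM3 = 1e9


def sidecar_path(path: str | Path) -> Path:
    """JSON metadata sidecar for a volume file (``volume.tif`` -> ``volume.json``)."""
    p = Path(path)
    return p.with_suffix(".json")


@dataclass
class GrayVolume:
    """A 3D scalar image on an isotropic grid.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Gray values, any finite scalar dtype.
    spacing_um : float
        Isotropic voxel spacing in micrometres, > 0.
    origin_um : ndarray of 3 floats
        Position of voxel (0,0,0)'s corner in micrometres; carried through
        cropping so subvolumes remember where they came from.
    """

    data: np.ndarray
    spacing_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if not self.spacing_um > 0:
            raise ValueError(f"spacing_um must be > 0, got {self.spacing_um}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("gray data must be finite")
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.spacing_um) ** 3


@dataclass
class LabelVolume:
    """A 3D label image: 0 = background, k > 0 = component id.

    Ids need not be contiguous (filtering may remove some).  Shares the grid
    conventions of :class:`GrayVolume`.
    """

    data: np.ndarray
    spacing_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label data must be integer, got {self.data.dtype}")
        if (self.data < 0).any():
            raise ValueError("labels must be non-negative")
        if not self.spacing_um > 0:
            raise ValueError(f"spacing_um must be > 0, got {self.spacing_um}")
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.spacing_um) ** 3

    def ids(self) -> np.ndarray:
        u = np.unique(self.data)
        return u[u > 0]


@dataclass
class SliceLabelStack:
    """Sparse per-slice 2D label images at known z indices, gaps allowed.

    This is the form manual lesion annotation arrives in: histological
    sections are labeled on matched micro-CT slices at a known z step, and
    ribbon breaks leave missing levels.
    """

    entries: list[tuple[int, np.ndarray]]
    target_shape: tuple[int, int]
    spacing_um: float
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        z_prev = None
        for z, img in self.entries:
            if z_prev is not None and z <= z_prev:
                raise ValueError(f"z indices must be strictly increasing (got {z} after {z_prev})")
            if img.shape != tuple(self.target_shape):
                raise ValueError(
                    f"slice at z={z} has shape {img.shape}, expected {self.target_shape}"
                )
            z_prev = z

    @property
    def z_indices(self) -> list[int]:
        return [z for z, _ in self.entries]

    def gaps(self) -> list[int]:
        """Missing z indices strictly between the first and last present slice."""
        zs = self.z_indices
        present = set(zs)
        return [z for z in range(zs[0], zs[-1] + 1) if z not in present]

    @property
    def depth_span_um(self) -> float:
        """Depth covered from first to last slice, inclusive of the last voxel."""
        zs = self.z_indices
        return (zs[-1] - zs[0] + 1) * self.spacing_um


def write_volume(volume: GrayVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as multi-page TIFF (one page per z slice) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data)
    meta = {
        "spacing_um": float(volume.spacing_um),
        "origin_um": [float(v) for v in volume.origin_um],
        "shape": list(volume.data.shape),
        "dtype": str(volume.data.dtype),
        "kind": "label" if isinstance(volume, LabelVolume) else "gray",
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    logger.info("wrote %s volume %s shape=%s spacing=%g um",
                meta["kind"], path, volume.data.shape, volume.spacing_um)


def read_volume(path: str | Path, kind: str | None = None) -> GrayVolume | LabelVolume:
    """Read a multi-page TIFF volume with its JSON sidecar.

    ``kind`` forces "gray" or "label"; by default the sidecar's record is used.
    Raises ``FileNotFoundError`` naming the sidecar if it is missing, and
    ``ValueError`` with the offending page index if page shapes disagree.
    """
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sc} for volume {path}")
    meta = json.loads(sc.read_text())
    with tifffile.TiffFile(path) as tf:
        shapes = [p.shape for p in tf.pages]
        for i, s in enumerate(shapes):
            if s != shapes[0]:
                raise ValueError(f"TIFF page {i} has shape {s}, expected {shapes[0]}")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    kind = kind or meta.get("kind", "gray")
    cls = LabelVolume if kind == "label" else GrayVolume
    vol = cls(data, spacing_um=meta["spacing_um"],
              origin_um=np.asarray(meta.get("origin_um", [0.0, 0.0, 0.0])))
    logger.info("read %s volume %s shape=%s spacing=%g um", kind, path, data.shape, vol.spacing_um)
    return vol


def read_slice_stack(manifest: str | Path, spacing_um: float | None = None) -> SliceLabelStack:
    """Read sparse per-slice labels from a CSV manifest.

    The manifest has columns ``filename`` and ``z_index``; filenames are
    resolved relative to the manifest's directory.  An optional sidecar
    ``<manifest>.json`` may carry ``spacing_um`` and ``z_step_um``; an
    explicit ``spacing_um`` argument overrides it.  Gaps (missing z) are
    preserved, never filled here.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    if df.empty:
        raise ValueError(f"empty slice manifest {manifest}")
    if df["z_index"].duplicated().any():
        dup = df.loc[df["z_index"].duplicated(), "z_index"].iloc[0]
        raise ValueError(f"duplicate z index {dup} in manifest {manifest}")
    meta: dict = {}
    sc = sidecar_path(manifest)
    if sc.exists():
        meta = json.loads(sc.read_text())
    if spacing_um is None:
        spacing_um = meta.get("spacing_um", 8.0)
    df = df.sort_values("z_index")
    entries = []
    for _, row in df.iterrows():
        img = tifffile.imread(manifest.parent / row["filename"])
        entries.append((int(row["z_index"]), np.asarray(img)))
    shape = entries[0][1].shape
    return SliceLabelStack(entries=entries, target_shape=shape, spacing_um=spacing_um,
                           z_step_um=meta.get("z_step_um"))


def write_slice_stack(stack: SliceLabelStack, out_dir: str | Path) -> Path:
    """Write each slice as a TIFF plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for z, img in stack.entries:
        name = f"slice_z{z:05d}.tif"
        tifffile.imwrite(out_dir / name, img)
        rows.append({"filename": name, "z_index": z})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    sidecar_path(manifest).write_text(json.dumps(
        {"spacing_um": stack.spacing_um, "z_step_um": stack.z_step_um}))
    return manifest
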