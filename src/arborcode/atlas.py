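"""Annotation volumes: integer label grids with a declared mid-sagittal mirror plane.

The reference space is a 3-D grid of isotropic voxels (default 25 μm). Every
region is expected to have a mirrored twin across the midplane of the declared
``mirror_axis``, so hemisphere handling (soma mirroring, contralateral domain
copies) reduces to a single-axis reflection.

Conventions used throughout the package:

* world coordinates are in μm; a point ``p`` maps to voxel
  ``floor((p - origin) / voxel_size)`` (0-based, half-open voxels);
* the mirror plane sits at the grid midpoint of ``mirror_axis``; voxel
  indices below the midpoint are tagged hemisphere ``"left"``;
* region id 0 means unlabeled / outside every region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AnnotationVolume", "read_nrrd", "write_nrrd"]


class OutOfBoundsError(ValueError):
    """A point falls outside the annotation volume."""


@dataclass
class AnnotationVolume:
    """3-D integer region-label grid plus the geometry needed to interpret it.

    Parameters
    ----------
    labels
        Integer array of shape ``(nx, ny, nz)``; 0 = unlabeled.
    voxel_size
        Isotropic voxel edge length in μm.
    origin
        World coordinate (μm) of the corner of voxel (0, 0, 0).
    mirror_axis
        Axis whose grid midplane is the sagittal mirror.
    regions
        Table with columns ``id, name, hemisphere`` (one row per region).
    """

    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mirror_axis: int = 0
    regions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "name", "hemisphere"])
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0 <= self.mirror_axis <= 2:
            raise ValueError("mirror_axis must be 0, 1 or 2")
        self.origin = np.asarray(self.origin, dtype=float)

    # ------------------------------------------------------------------ geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size

    @property
    def mirror_center_um(self) -> float:
        """World coordinate of the mirror plane along ``mirror_axis``."""
        return float(
            self.origin[self.mirror_axis]
            + self.shape[self.mirror_axis] * self.voxel_size / 2.0
        )

    def to_voxel(self, points: np.ndarray, strict: bool = True) -> np.ndarray:
        """Map μm point(s) to 0-based voxel indices via the floor convention."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)
        oob = (idx < 0).any(axis=1) | (idx >= np.asarray(self.shape)).any(axis=1)
        if strict and oob.any():
            bad = pts[oob][0]
            raise OutOfBoundsError(f"point {bad} outside volume bounds")
        out = idx if np.asarray(points).ndim == 2 else idx[0]
        return out

    def voxel_center(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (μm) of voxel center(s)."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx + 0.5) * self.voxel_size

    def region_of(self, points: np.ndarray) -> np.ndarray:
        """Region id at each μm point; 0 for out-of-bounds or unlabeled."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)
        oob = (idx < 0).any(axis=1) | (idx >= np.asarray(self.shape)).any(axis=1)
        ids = np.zeros(len(pts), dtype=self.labels.dtype)
        ok = ~oob
        if ok.any():
            ids[ok] = self.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        return ids if np.asarray(points).ndim == 2 else ids[0]

    # ------------------------------------------------------------------ mirroring

    def mirror_point(self, points: np.ndarray) -> np.ndarray:
        """Reflect μm point(s) about the mirror plane (an involution)."""
        pts = np.array(np.atleast_2d(points), dtype=float)
        c = self.mirror_center_um
        pts[:, self.mirror_axis] = 2.0 * c - pts[:, self.mirror_axis]
        return pts if np.asarray(points).ndim == 2 else pts[0]

    def mirror_voxel(self, idx: np.ndarray) -> np.ndarray:
        """Reflect voxel index/indices: i -> N-1-i along the mirror axis."""
        out = np.array(np.atleast_2d(idx), dtype=np.int64)
        n = self.shape[self.mirror_axis]
        out[:, self.mirror_axis] = n - 1 - out[:, self.mirror_axis]
        return out if np.asarray(idx).ndim == 2 else out[0]

    def hemisphere_of_point(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        side = np.where(pts[:, self.mirror_axis] < self.mirror_center_um, "left", "right")
        return side if np.asarray(points).ndim == 2 else side[0]

    def mirror_to_hemisphere(self, points: np.ndarray, side: str = "left") -> np.ndarray:
        """Reflect only points lying in the non-canonical hemisphere.

        Points already on the canonical ``side`` are returned unchanged.
        """
        pts = np.array(np.atleast_2d(points), dtype=float)
        on_side = self.hemisphere_of_point(pts) == side
        pts[~on_side] = self.mirror_point(pts[~on_side]) if (~on_side).any() else pts[~on_side]
        return pts if np.asarray(points).ndim == 2 else pts[0]

    # ------------------------------------------------------------------ regions

    def region_voxels(self, region_id: int) -> np.ndarray:
        """All voxel indices labeled ``region_id``, as an (n, 3) array."""
        return np.argwhere(self.labels == region_id)

    def region_name(self, region_id: int) -> str:
        row = self.regions[self.regions["id"] == region_id]
        return str(row["name"].iloc[0]) if len(row) else f"region_{region_id}"

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]

    # ------------------------------------------------------------------ persistence

    def save(self, nrrd_path, region_table_path=None) -> None:
        write_nrrd(self, nrrd_path)
        if region_table_path is not None:
            self.regions.to_csv(region_table_path, index=False)

    @classmethod
    def load(cls, nrrd_path, region_table_path=None) -> "AnnotationVolume":
        vol = read_nrrd(nrrd_path)
        if region_table_path is not None:
            vol.regions = pd.read_csv(region_table_path)
        return vol


# ---------------------------------------------------------------------- NRRD I/O
#
# Minimal NRRD codec restricted to what this package writes: 3-D integer
# volumes, ascii encoding, fastest-first (Fortran) raster order per the NRRD
# specification. Geometry metadata rides along as NRRD key:=value pairs.

_NRRD_MAGIC = "NRRD0004"
_TYPE_MAP = {"int32": np.int32, "int64": np.int64, "short": np.int16, "int16": np.int16}


def write_nrrd(vol: AnnotationVolume, path) -> None:
    labels = np.asarray(vol.labels, dtype=np.int32)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_NRRD_MAGIC}\n")
        fh.write("type: int32\n")
        fh.write("dimension: 3\n")
        fh.write("sizes: {} {} {}\n".format(*labels.shape))
        fh.write("spacings: {0} {0} {0}\n".format(vol.voxel_size))
        fh.write("encoding: ascii\n")
        fh.write("origin:={} {} {}\n".format(*vol.origin))
        fh.write(f"mirror axis:={vol.mirror_axis}\n")
        fh.write("\n")
        # NRRD raster order: first listed axis varies fastest.
        flat = labels.flatten(order="F")
        for start in range(0, flat.size, 16):
            fh.write(" ".join(str(v) for v in flat[start : start + 16]))
            fh.write("\n")


def read_nrrd(path) -> AnnotationVolume:
    with open(path, "r", encoding="utf-8") as fh:
        magic = fh.readline().strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        header: dict[str, str] = {}
        for line in fh:
            line = line.rstrip("\n")
            if line == "":
                break
            if line.startswith("#"):
                continue
            if ":=" in line:
                key, val = line.split(":=", 1)
                header[key.strip()] = val.strip()
            elif ":" in line:
                key, val = line.split(":", 1)
                header[key.strip()] = val.strip()
        if header.get("encoding", "ascii") != "ascii":
            raise ValueError("only ascii-encoded NRRD is supported")
        sizes = tuple(int(s) for s in header["sizes"].split())
        dtype = _TYPE_MAP.get(header.get("type", "int32"), np.int32)
        data = np.loadtxt(io.StringIO(fh.read()), dtype=dtype).reshape(-1)
        labels = data.reshape(sizes, order="F")
    voxel_size = float(header.get("spacings", "25").split()[0])
    origin = np.array([float(v) for v in header.get("origin", "0 0 0").split()])
    mirror_axis = int(header.get("mirror axis", 0))
    return AnnotationVolume(
        labels=labels, voxel_size=voxel_size, origin=origin, mirror_axis=mirror_axis
    )
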