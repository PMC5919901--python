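"""Shared spatial data model: volumes, grids, meshes, landmarks, and file I/O.

Conventions used throughout the package:

* voxel indices are 0-based; world coordinates (mm, RAS+) are obtained as
  ``world = affine @ (i, j, k, 1)``;
* the +x axis is the left-right axis used for midsagittal flips;
* scalar images are interpolated trilinearly, label images by nearest
  neighbour; out-of-bounds sample points are clamped to the grid edge for
  scalars and map to background (0) for labels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy.ndimage import map_coordinates
from skimage.measure import marching_cubes

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "LabelVolume",
    "TissueVolumeSet",
    "TriangleMesh",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "trilinear_sample",
    "nearest_sample",
    "extract_isosurface",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_table",
    "write_table",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D voxel lattice with an affine voxel-to-world (mm) mapping."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if len(self.shape) != 3 or any(s < 2 for s in self.shape):
            raise ValueError(f"grid shape must be 3 components >= 2, got {self.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        det = np.linalg.det(self.affine[:3, :3])
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def __eq__(self, other):
        return (
            isinstance(other, VoxelGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=1e-9)
        )


@dataclass
class ScalarVolume:
    """A real-valued lattice on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"lattice shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in scalar volume")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class LabelVolume:
    """A non-negative integer label lattice; 0 is background."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label lattice is not integral")
            self.labels = np.round(self.labels).astype(np.int32)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label lattice shape does not match grid")
        if self.labels.min() < 0:
            raise ValueError("negative label id")

    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class TissueVolumeSet:
    """Co-registered GM/WM/CSF fraction maps on one shared grid."""

    gm: ScalarVolume
    wm: ScalarVolume
    csf: ScalarVolume

    def __post_init__(self):
        if not (self.gm.grid == self.wm.grid == self.csf.grid):
            raise ValueError("tissue maps must share one grid")
        for name in ("gm", "wm", "csf"):
            v = getattr(self, name).values
            if v.min() < -1e-9 or v.max() > 1 + 1e-9:
                raise ValueError(f"{name} fractions outside [0, 1]")
        total = self.gm.values + self.wm.values + self.csf.values
        if total.max() > 1 + 1e-6:
            raise ValueError("gm+wm+csf exceeds 1")

    @property
    def grid(self) -> VoxelGrid:
        return self.gm.grid


@dataclass
class TriangleMesh:
    """Triangular surface mesh with vertices in world mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def area(self) -> float:
        return float(self.to_trimesh().area)

    def enclosed_volume(self) -> float:
        return float(abs(self.to_trimesh().volume))

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals."""
        return np.asarray(self.to_trimesh().vertex_normals, dtype=float)


@dataclass
class LandmarkSet:
    """Named 3-D landmark coordinates (world mm)."""

    names: list[str]
    points: np.ndarray

    def __post_init__(self):
        self.names = [str(n) for n in self.names]
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.names) != len(self.points):
            raise ValueError("names/points length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate landmark names")

    def __len__(self):
        return len(self.names)

    def subset(self, names: list[str]) -> "LandmarkSet":
        idx = {n: i for i, n in enumerate(self.names)}
        rows = [idx[n] for n in names]
        return LandmarkSet(list(names), self.points[rows])


# ---------------------------------------------------------------------------
# volume I/O (NIfTI-1 via nibabel)

def read_volume(path) -> ScalarVolume | LabelVolume:
    """Read a NIfTI-1 volume; integer dtypes come back as :class:`LabelVolume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D image, got shape {data.shape}")
    grid = VoxelGrid(data.shape, np.asarray(img.affine))
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(grid, data.astype(np.int32))
    return ScalarVolume(grid, data.astype(float))


def write_volume(volume: ScalarVolume | LabelVolume, path) -> None:
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.int32)
    else:
        data = volume.values.astype(np.float64)
    img = nib.Nifti1Image(data, volume.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# interpolation

def trilinear_sample(volume: ScalarVolume, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at voxel coordinates, edge-clamped out of bounds."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite sample points")
    return map_coordinates(
        volume.values, pts.T, order=1, mode="nearest", prefilter=False
    )


def nearest_sample(labels: LabelVolume, points: np.ndarray) -> np.ndarray:
    """Nearest-neighbour label lookup; points outside the grid return 0.

    Coordinates are rounded half-away-from-zero per axis.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    # np.round ties to even; emulate round-half-away-from-zero
    idx = np.floor(np.abs(pts) + 0.5) * np.sign(pts)
    idx = idx.astype(np.int64)
    out = np.zeros(len(pts), dtype=labels.labels.dtype)
    shape = np.array(labels.grid.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    ii = idx[inside]
    out[inside] = labels.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


# ---------------------------------------------------------------------------
# isosurface

def extract_isosurface(volume: ScalarVolume, level: float) -> TriangleMesh:
    """Marching-cubes isosurface at ``level``, returned in world mm.

    Raises ``ValueError`` when the level does not cross the value range.
    """
    vmin, vmax = volume.values.min(), volume.values.max()
    if not (vmin < level < vmax):
        raise ValueError(f"level {level} outside value range [{vmin}, {vmax}]")
    verts, faces, _, _ = marching_cubes(volume.values, level=level)
    verts_world = volume.grid.voxel_to_world(verts)
    mesh = trimesh.Trimesh(verts_world, faces, process=False)
    # orient outward: enclosed signed volume should be positive
    if mesh.volume < 0:
        faces = faces[:, ::-1]
    return TriangleMesh(verts_world, faces)


# ---------------------------------------------------------------------------
# mesh / landmark / table I/O

def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write a binary little-endian PLY (exact float storage)."""
    mesh.to_trimesh().export(str(path), file_type="ply", encoding="binary")


def read_mesh(path) -> TriangleMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tm = trimesh.load(str(path), file_type="ply", process=False)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_landmarks(lmk: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z"])
        for name, p in zip(lmk.names, lmk.points):
            w.writerow([name, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    names, pts = [], []
    with open(path, newline="") as fh:
        rdr = csv.reader(fh)
        header = next(rdr, None)
        if header is None or [h.strip().lower() for h in header[:4]] != ["name", "x", "y", "z"]:
            raise ValueError(f"{path}: line 1: expected header name,x,y,z")
        for lineno, row in enumerate(rdr, start=2):
            if not row:
                continue
            if len(row) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
            try:
                pts.append([float(row[1]), float(row[2]), float(row[3])])
            except ValueError as e:
                raise ValueError(f"{path}: line {lineno}: bad coordinate: {e}") from None
            names.append(row[0])
    return LandmarkSet(names, np.array(pts))


def write_table(df, path) -> None:
    df.to_csv(path, index=False)


def read_table(path):
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)
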