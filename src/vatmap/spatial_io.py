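"""Spatial containers and file I/O with one fixed world-coordinate convention.

Everything in this package lives in world millimetres, RAS+ orientation, with
voxel *centers* (not corners) as the grid reference points.  Streamline files
(TRK/TCK) store points in format-specific conventions; they are converted to
world mm on read.  Volumes are NIfTI-1 with an axis-aligned isotropic affine;
anything else is rejected rather than silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from nibabel import streamlines as nibs

from vatmap.errors import FormatError, UnsupportedGeometryError

__all__ = [
    "Tractogram",
    "GridSpec",
    "DensityVolume",
    "read_tractogram",
    "write_tractogram",
    "read_volume",
    "write_volume",
]


@dataclass
class Tractogram:
    """A set of streamlines: 3D polylines in world millimetres (RAS+).

    Parameters
    ----------
    streamlines
        Sequence of ``(n_i, 3)`` float arrays, each with at least two points.
    space_tag
        Identifier of the reference space the coordinates live in
        (e.g. ``"MNI152"`` for normative data, ``"synthetic"`` for generated
        test anatomy).
    """

    streamlines: list[np.ndarray]
    space_tag: str = "world"

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise FormatError(f"streamline {i}: expected an (n, 3) array, got shape {arr.shape}")
            if arr.shape[0] < 2:
                raise FormatError(f"streamline {i}: fewer than 2 points ({arr.shape[0]})")
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"streamline {i}: non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates over all points; raises on empty."""
        if not self.streamlines:
            raise FormatError("empty tractogram has no bounds")
        pts = np.vstack(self.streamlines)
        return pts.min(axis=0), pts.max(axis=0)


@dataclass(frozen=True)
class GridSpec:
    """Isotropic, axis-aligned voxel grid in world mm.

    ``origin`` is the world coordinate of the *center* of voxel (0, 0, 0).
    Voxel index ``i`` maps to world ``origin + i * voxel_size``.
    """

    origin: tuple[float, float, float]
    voxel_size: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise UnsupportedGeometryError(f"voxel_size must be > 0, got {self.voxel_size}")
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise UnsupportedGeometryError(f"dims must be 3 positive integers, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, center convention)."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=np.float64) * self.voxel_size

    def world_to_voxel_continuous(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=np.float64) - np.asarray(self.origin)) / self.voxel_size

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index (no bounds check)."""
        return np.rint(self.world_to_voxel_continuous(xyz)).astype(np.int64)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)


@dataclass
class DensityVolume:
    """Nonnegative scalar field on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.dims):
            raise FormatError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if np.any(self.values < 0):
            raise FormatError("density values must be nonnegative")

    def total_mass(self) -> float:
        return float(self.values.sum())


def read_tractogram(path: str | Path) -> Tractogram:
    """Load a TRK or TCK file; all points are returned in world mm (RAS+).

    The on-disk convention (TRK's voxel-order corner coordinates, TCK's
    scanner mm) is resolved by the format reader; this function always hands
    back RAS+ world millimetres.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such tractogram file: {path}")
    try:
        tf = nibs.load(str(path))
    except Exception as exc:  # nibabel raises assorted header errors
        raise FormatError(f"could not parse tractogram {path}: {exc}") from exc
    # nibabel applies affine_to_rasmm on access, so these are world mm
    sls = [np.asarray(s, dtype=np.float64) for s in tf.tractogram.streamlines]
    for i, s in enumerate(sls):
        if s.shape[0] < 2:
            raise FormatError(f"{path}: streamline record {i} has {s.shape[0]} point(s)")
        if not np.all(np.isfinite(s)):
            raise FormatError(f"{path}: streamline record {i} has non-finite coordinates")
    return Tractogram(sls, space_tag="world")


def write_tractogram(t: Tractogram, path: str | Path) -> None:
    """Write TRK or TCK (chosen by file extension), points in world mm."""
    path = Path(path)
    suffix = path.suffix.lower()
    tg = nibs.Tractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    if suffix == ".tck":
        nibs.TckFile(tg).save(str(path))
    elif suffix == ".trk":
        # TRK needs a reference grid in its header; an identity voxel-to-world
        # with unit voxels is sufficient since our points are already RAS mm.
        header = nibs.trk.TrkFile.create_empty_header()
        header[nib.streamlines.Field.VOXEL_TO_RASMM] = np.eye(4)
        header[nib.streamlines.Field.VOXEL_SIZES] = (1.0, 1.0, 1.0)
        header[nib.streamlines.Field.DIMENSIONS] = (1, 1, 1)
        header[nib.streamlines.Field.VOXEL_ORDER] = b"RAS"
        nibs.TrkFile(tg, header=header).save(str(path))
    else:
        raise FormatError(f"unsupported tractogram format {suffix!r} (use .trk or .tck)")


_ISO_ATOL = 1e-4  # mm tolerance when checking isotropy / axis alignment


def read_volume(path: str | Path) -> DensityVolume:
    """Load a NIfTI-1 volume into a :class:`DensityVolume`.

    The affine must be axis-aligned with equal positive scales; oblique,
    sheared or anisotropic grids raise :class:`UnsupportedGeometryError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    diag = np.diag(rot)
    if np.any(np.abs(rot - np.diag(diag)) > _ISO_ATOL):
        raise UnsupportedGeometryError(f"{path}: affine is sheared or oblique:\n{aff}")
    if np.any(diag <= 0):
        raise UnsupportedGeometryError(f"{path}: affine has non-positive scales {diag} (RAS+ required)")
    if np.max(diag) - np.min(diag) > _ISO_ATOL:
        raise UnsupportedGeometryError(f"{path}: voxels are anisotropic {diag}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise UnsupportedGeometryError(f"{path}: expected a 3D volume, got {data.ndim}D")
    grid = GridSpec(origin=tuple(aff[:3, 3]), voxel_size=float(np.mean(diag)), dims=data.shape)
    return DensityVolume(grid, data)


def write_volume(v: DensityVolume, path: str | Path) -> None:
    """Write a NIfTI-1 volume whose affine encodes the grid spec."""
    img = nib.Nifti1Image(v.values.astype(np.float64), v.grid.affine)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
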