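"""Voxel-grid data model, NIfTI/gradient-table I/O, and mask algebra.

Conventions fixed package-wide:

* voxel indices are 0-based;
* the third array axis is the superior->inferior (slice) axis, with
  vertebral-level values increasing inferiorly;
* every volume participating in one analysis shares a single
  :class:`VoxelGrid` (checked on read and on every operation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

SLICE_AXIS = 2
B0_THRESHOLD = 50.0  # s/mm^2; smaller nominal b treated as b = 0

PATHWAY_NAMES = ("LDo", "RDo", "LV", "RV", "LL", "RL")
SUBREGION_NAMES = ("LDH", "RDH", "LVH", "RVH", "LIH", "RIH")


class GridMismatchError(ValueError):
    """Raised when a volume's grid disagrees with the analysis grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice: dimensions (nx, ny, nz) and voxel size in mm."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive counts, got {self.dims}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def slice_area_mm2(self) -> float:
        return self.voxel_size[0] * self.voxel_size[1]

    @property
    def is_isotropic(self) -> bool:
        dx, dy, dz = self.voxel_size
        return abs(dx - dy) < 1e-9 and abs(dx - dz) < 1e-9

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def check_same(self, other: "VoxelGrid", what: str = "volume") -> None:
        if self.dims != other.dims or not np.allclose(
            self.voxel_size, other.voxel_size, atol=1e-6
        ):
            raise GridMismatchError(
                f"{what}: grid mismatch — expected dims={self.dims} "
                f"voxel={self.voxel_size}, got dims={other.dims} voxel={other.voxel_size}"
            )


def grid_from_header(img: nib.Nifti1Image) -> VoxelGrid:
    dims = tuple(int(d) for d in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(dims, zooms)


@dataclass
class LabelVolume:
    """Binary mask or probability map on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray
    kind: str = "binary"  # "binary" | "probability" | "label"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.dims:
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid dims {self.grid.dims}"
            )
        if self.kind == "binary":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"binary mask contains values other than 0/1: {vals[:8]}")
            self.data = self.data.astype(np.uint8)
        elif self.kind == "probability":
            if self.data.min() < 0 or self.data.max() > 1:
                raise ValueError("probability map values must lie in [0, 1]")
            self.data = self.data.astype(np.float64)

    def count(self) -> int:
        return int(np.count_nonzero(self.data))


@dataclass
class ContinuousLevelMap:
    """Voxelwise vertebral coordinate: 0 outside the cord, [2, 6) inside.

    A value of e.g. 2.37 means 37% of the way down the C2 vertebral level.
    """

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.dims:
            raise GridMismatchError(
                f"level map shape {self.data.shape} != grid dims {self.grid.dims}"
            )
        inside = self.data > 0
        if inside.any():
            vals = self.data[inside]
            if vals.min() < 2.0 - 1e-9 or vals.max() >= 6.0:
                raise ValueError("nonzero level values must lie in [2.0, 6.0)")


@dataclass
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions, one row per DWI volume."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=np.float64).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError(
                f"bvals length {len(self.bvals)} != bvecs length {len(self.bvecs)}"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        nonzero = norms > 0
        if nonzero.any() and np.abs(norms[nonzero] - 1.0).max() > 1e-6:
            raise ValueError("nonzero gradient directions must be unit-norm to 1e-6")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD

    @property
    def n_b0(self) -> int:
        return int(self.is_b0.sum())


@dataclass
class DWIVolume:
    """4D diffusion-weighted series with its gradient table."""

    grid: VoxelGrid
    data: np.ndarray  # (nx, ny, nz, nvol)
    gradients: GradientTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[:3] != self.grid.dims:
            raise GridMismatchError(
                f"DWI shape {self.data.shape} incompatible with grid {self.grid.dims}"
            )
        if self.data.shape[3] != len(self.gradients):
            raise ValueError(
                f"DWI has {self.data.shape[3]} volumes but gradient table "
                f"has {len(self.gradients)} entries"
            )
        if self.data.min() < 0:
            raise ValueError("DWI signals must be nonnegative")


@dataclass
class RegionSet:
    """Named binary masks at atlas resolution.

    ``cord``, ``wm`` and ``gm`` are mandatory; six WM pathways (left/right
    dorsal, ventral, lateral columns) and six GM subregions (left/right
    dorsal, ventral, intermediate horns) partition WM and GM respectively;
    ``lesion`` is optional and must lie inside the cord.
    """

    grid: VoxelGrid
    cord: LabelVolume
    wm: LabelVolume
    gm: LabelVolume
    pathways: dict[str, LabelVolume] = field(default_factory=dict)
    subregions: dict[str, LabelVolume] = field(default_factory=dict)
    lesion: LabelVolume | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, vol in self.items():
            self.grid.check_same(vol.grid, what=f"region '{name}'")
        cord = self.cord.data.astype(bool)
        wm = self.wm.data.astype(bool)
        gm = self.gm.data.astype(bool)
        if np.any(wm & gm):
            raise ValueError("WM and GM overlap")
        if not np.array_equal(wm, cord & ~gm):
            raise ValueError("WM must equal cord AND NOT GM")
        if self.pathways:
            if set(self.pathways) != set(PATHWAY_NAMES):
                raise ValueError(f"pathway names must be {PATHWAY_NAMES}")
            stack = np.stack([self.pathways[n].data for n in PATHWAY_NAMES])
            if stack.sum(axis=0).max() > 1:
                raise ValueError("pathway masks overlap")
            if not np.array_equal(stack.any(axis=0), wm):
                raise ValueError("pathways must partition WM")
        if self.subregions:
            if set(self.subregions) != set(SUBREGION_NAMES):
                raise ValueError(f"subregion names must be {SUBREGION_NAMES}")
            stack = np.stack([self.subregions[n].data for n in SUBREGION_NAMES])
            if stack.sum(axis=0).max() > 1:
                raise ValueError("subregion masks overlap")
            if not np.array_equal(stack.any(axis=0), gm):
                raise ValueError("subregions must partition GM")
        if self.lesion is not None and np.any(self.lesion.data.astype(bool) & ~cord):
            raise ValueError("lesion mask must lie inside the cord")

    def items(self) -> Iterable[tuple[str, LabelVolume]]:
        yield "cord", self.cord
        yield "WM", self.wm
        yield "GM", self.gm
        for name in PATHWAY_NAMES:
            if name in self.pathways:
                yield name, self.pathways[name]
        for name in SUBREGION_NAMES:
            if name in self.subregions:
                yield name, self.subregions[name]
        if self.lesion is not None:
            yield "lesion", self.lesion

    def analysis_regions(self) -> dict[str, LabelVolume]:
        """The 15 regions profiled along the cord (lesion excluded)."""
        out = {"cord": self.cord, "WM": self.wm, "GM": self.gm}
        out.update({n: self.pathways[n] for n in PATHWAY_NAMES if n in self.pathways})
        out.update({n: self.subregions[n] for n in SUBREGION_NAMES if n in self.subregions})
        return out


@dataclass
class SubjectRecord:
    id: str
    group: str  # "HC" | "pwRRMS"
    age: float
    sex: str  # "F" | "M"
    edss: float | None = None
    tug_s: float | None = None
    t25_s: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("HC", "pwRRMS"):
            raise ValueError(f"group must be HC or pwRRMS, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.edss is not None:
            if abs(self.edss * 2 - round(self.edss * 2)) > 1e-9 or not 0 <= self.edss <= 10:
                raise ValueError(f"EDSS must lie on the 0-10 half-point grid, got {self.edss}")
        for name in ("tug_s", "t25_s"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# NIfTI and gradient-table I/O


def write_volume(obj: LabelVolume | ContinuousLevelMap | DWIVolume | np.ndarray,
                 path: str | Path, grid: VoxelGrid | None = None) -> None:
    """Write a volume as NIfTI-1; masks as uint8, maps as float32."""
    path = Path(path)
    if isinstance(obj, LabelVolume):
        data = obj.data.astype(np.uint8 if obj.kind == "binary" else np.float32)
        grid = obj.grid
    elif isinstance(obj, ContinuousLevelMap):
        data = obj.data.astype(np.float32)
        grid = obj.grid
    elif isinstance(obj, DWIVolume):
        data = obj.data.astype(np.float32)
        grid = obj.grid
    else:
        if grid is None:
            raise ValueError("grid required when writing a bare array")
        data = np.asarray(obj).astype(np.float32)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_volume(path: str | Path, expected_grid: VoxelGrid | None = None,
                kind: str = "auto",
                gradients: GradientTable | None = None):
    """Read a NIfTI-1 volume, checking its grid against the analysis grid.

    ``kind``: "binary", "probability", "level", "dwi" or "auto" (binary if the
    stored values are {0,1}, probability otherwise; 4D files require
    ``gradients``).
    """
    path = Path(path)
    img = nib.load(str(path))
    grid = grid_from_header(img)
    if expected_grid is not None:
        expected_grid.check_same(grid, what=str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 or kind == "dwi":
        if gradients is None:
            raise ValueError("4D DWI input requires a gradient table")
        return DWIVolume(grid, data.astype(np.float64), gradients)
    if kind == "level":
        return ContinuousLevelMap(grid, data)
    if kind == "auto":
        kind = "binary" if np.all(np.isin(np.unique(data), (0, 1))) else "probability"
    return LabelVolume(grid, data, kind=kind)


def read_gradient_table(bvals_path: str | Path, bvecs_path: str | Path) -> GradientTable:
    """Read the two-file plain-text gradient dialect.

    ``bvals``: one whitespace-separated row of b-values. ``bvecs``: three rows
    (x, y, z components). Directions are re-normalized to unit length;
    b < 50 s/mm^2 is treated as b = 0 with a zero direction.
    """
    try:
        bvals = np.loadtxt(bvals_path, dtype=float).ravel()
        bvecs = np.loadtxt(bvecs_path, dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric content in gradient files: {exc}") from exc
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, 1)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # stored convention is rows = components
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"gradient count mismatch: {len(bvals)} b-values vs {len(bvecs)} directions"
        )
    bvals = np.where(bvals < B0_THRESHOLD, 0.0, bvals)
    norms = np.linalg.norm(bvecs, axis=1)
    out = np.zeros_like(bvecs)
    nz = (norms > 0) & (bvals > 0)
    out[nz] = bvecs[nz] / norms[nz, None]
    return GradientTable(bvals, out)


def write_gradient_table(table: GradientTable, bvals_path: str | Path,
                         bvecs_path: str | Path) -> None:
    np.savetxt(bvals_path, table.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, table.bvecs.T, fmt="%.10f")


def read_subject_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    return df


# ---------------------------------------------------------------------------
# Mask algebra


def subtract_masks(cord: LabelVolume, gm: LabelVolume) -> LabelVolume:
    """WM mask by subtracting the GM mask from the full cord mask."""
    cord.grid.check_same(gm.grid, what="subtract_masks")
    if cord.kind != "binary" or gm.kind != "binary":
        raise ValueError("subtract_masks requires binary masks")
    out = (cord.data.astype(bool) & ~gm.data.astype(bool)).astype(np.uint8)
    return LabelVolume(cord.grid, out, kind="binary")


def binarize_probability(mask: LabelVolume, threshold: float = 0.5) -> LabelVolume:
    """Binarize a probability map strictly above ``threshold``."""
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    out = (np.asarray(mask.data, dtype=float) > threshold).astype(np.uint8)
    return LabelVolume(mask.grid, out, kind="binary")


def resample(volume: LabelVolume | ContinuousLevelMap, target_grid: VoxelGrid,
             mode: str = "nearest"):
    """Resample between grids covering the same physical extent.

    Label volumes use nearest-neighbour (no new label values appear);
    continuous maps use trilinear interpolation.
    """
    if mode not in ("nearest", "linear"):
        raise ValueError(f"mode must be 'nearest' or 'linear', got {mode!r}")
    src_extent = np.array(volume.grid.dims) * np.array(volume.grid.voxel_size)
    tgt_extent = np.array(target_grid.dims) * np.array(target_grid.voxel_size)
    if not np.allclose(src_extent, tgt_extent, rtol=1e-3):
        raise ValueError(
            f"grids cover different extents: {src_extent} mm vs {tgt_extent} mm"
        )
    is_label = isinstance(volume, LabelVolume)
    if is_label and mode == "linear":
        raise ValueError("linear interpolation is not allowed for label volumes")
    if volume.grid.dims == target_grid.dims:
        data = volume.data.copy()
    else:
        factors = np.array(target_grid.dims) / np.array(volume.grid.dims)
        order = 0 if mode == "nearest" else 1
        data = ndimage.zoom(volume.data.astype(float), factors, order=order,
                            mode="nearest", grid_mode=True)
    if is_label:
        return LabelVolume(target_grid, np.round(data).astype(volume.data.dtype)
                           if volume.kind != "probability" else data,
                           kind=volume.kind)
    return ContinuousLevelMap(target_grid, np.clip(data, 0, np.nextafter(6.0, 0)))
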