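"""Geometric ROI masks and voxel time-series extraction.

Masks are built in the mm space of a supplied voxel grid: a sphere of given
radius (voxel-center distance rule) or an axis-aligned cube of given edge.
No coordinate-space conversion is performed; ``RoiSpec.space_label`` is
carried as documentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .timeseries import RoiTimeSeries


@dataclass(frozen=True)
class VoxelGrid:
    """3-D voxel lattice with an affine voxel-index -> mm map (0-based indices)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @classmethod
    def default_epi(cls) -> "VoxelGrid":
        """64 x 64 x 47 grid at 3.3 x 3.3 x 3 mm, centered on the origin."""
        shape = (64, 64, 47)
        spacing = np.array([3.3, 3.3, 3.0])
        affine = np.diag([*spacing, 1.0])
        affine[:3, 3] = -spacing * (np.array(shape) - 1) / 2.0
        return cls(shape=shape, affine=affine)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: Sequence[float]) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(xyz)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def snap_to_voxel(self, center_mm: Sequence[float]) -> np.ndarray:
        """Index of the nearest in-grid voxel center."""
        ijk = np.round(self.mm_to_voxel(center_mm)[0]).astype(int)
        return np.clip(ijk, 0, np.array(self.shape) - 1)


@dataclass(frozen=True)
class RoiSpec:
    """Named ROI definition: exactly one of mask_file, sphere, or cube."""

    name: str
    hemisphere: str = "none"  # "L", "R", or "none"
    mask_file: str | None = None
    sphere: tuple[Sequence[float], float] | None = None  # (center mm, radius mm)
    cube: tuple[Sequence[float], float] | None = None  # (center mm, edge mm)
    space_label: str = ""

    def __post_init__(self) -> None:
        defs = [d for d in (self.mask_file, self.sphere, self.cube) if d is not None]
        if len(defs) != 1:
            raise ValueError(f"ROI {self.name!r}: exactly one definition required")
        if self.hemisphere not in ("L", "R", "none"):
            raise ValueError(f"ROI {self.name!r}: bad hemisphere {self.hemisphere!r}")
        for geom in (self.sphere, self.cube):
            if geom is not None and geom[1] <= 0:
                raise ValueError(f"ROI {self.name!r}: radius/edge must be > 0")


def _candidate_box(grid: VoxelGrid, center_mm: np.ndarray, reach_mm: float):
    """Voxel-index bounding box guaranteed to contain all candidate voxels."""
    inv = np.linalg.inv(grid.affine)[:3, :3]
    # per-index-axis reach: how many index steps can lie within reach_mm
    steps = np.abs(inv) @ np.full(3, reach_mm)
    ijk0 = grid.mm_to_voxel(center_mm)[0]
    lo = np.maximum(np.floor(ijk0 - steps - 1).astype(int), 0)
    hi = np.minimum(np.ceil(ijk0 + steps + 1).astype(int), np.array(grid.shape) - 1)
    return lo, hi


def _box_centers(grid: VoxelGrid, lo: np.ndarray, hi: np.ndarray):
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    return idx, grid.voxel_to_mm(idx)


def build_sphere_mask(
    center: Sequence[float], radius: float, grid: VoxelGrid
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius`` mm.

    The requested mm center is first snapped to the nearest voxel center
    (so a vanishing radius selects exactly one voxel).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    center = np.asarray(center, dtype=float)
    if not np.all(np.isfinite(center)):
        raise ValueError("center must be finite")
    snapped = grid.voxel_to_mm(grid.snap_to_voxel(center))[0]
    if np.linalg.norm(snapped - center) > radius + float(
        np.linalg.norm(grid.affine[:3, :3], 2)
    ):
        raise ValueError("sphere lies entirely outside the grid")
    lo, hi = _candidate_box(grid, snapped, radius)
    idx, centers = _box_centers(grid, lo, hi)
    keep = np.linalg.norm(centers - snapped, axis=1) <= radius
    mask = np.zeros(grid.shape, dtype=bool)
    mask[idx[keep, 0], idx[keep, 1], idx[keep, 2]] = True
    if not mask.any():
        raise ValueError("sphere mask is empty (outside grid?)")
    return mask


def build_cube_mask(
    center: Sequence[float], edge: float, grid: VoxelGrid
) -> np.ndarray:
    """Axis-aligned cube: voxel centers with |delta| <= edge/2 on each mm axis."""
    if edge <= 0:
        raise ValueError("edge must be > 0")
    center = np.asarray(center, dtype=float)
    if not np.all(np.isfinite(center)):
        raise ValueError("center must be finite")
    snapped = grid.voxel_to_mm(grid.snap_to_voxel(center))[0]
    half = edge / 2.0
    if np.any(np.abs(snapped - center) > half + float(
        np.linalg.norm(grid.affine[:3, :3], 2)
    )):
        raise ValueError("cube lies entirely outside the grid")
    reach = half * np.sqrt(3)
    lo, hi = _candidate_box(grid, snapped, reach)
    idx, centers = _box_centers(grid, lo, hi)
    keep = np.all(np.abs(centers - snapped) <= half, axis=1)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[idx[keep, 0], idx[keep, 1], idx[keep, 2]] = True
    if not mask.any():
        raise ValueError("cube mask is empty (outside grid?)")
    return mask


def mask_from_spec(spec: RoiSpec, grid: VoxelGrid) -> np.ndarray:
    if spec.mask_file is not None:
        mask, mgrid = load_mask(spec.mask_file)
        if mgrid.shape != grid.shape or not np.allclose(mgrid.affine, grid.affine):
            raise ValueError(f"ROI {spec.name!r}: mask grid does not match image grid")
        return mask
    if spec.sphere is not None:
        return build_sphere_mask(spec.sphere[0], spec.sphere[1], grid)
    return build_cube_mask(spec.cube[0], spec.cube[1], grid)


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_mask(mask: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = VoxelGrid(shape=tuple(data.shape[:3]), affine=img.affine)
    return data > 0, grid


def save_image4d(data: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid.affine), str(path))


def extract_roi_timeseries(
    image4d,
    mask: np.ndarray,
    run_labels: Sequence[int],
    tr: float | None = None,
    roi: str = "",
    subject: str = "",
    hemisphere: str = "",
) -> RoiTimeSeries:
    """Extract a time x voxel matrix for the masked voxels of a 4-D image.

    ``image4d`` may be a NIfTI image or an (x, y, z, t) array.  Voxel column
    order is ascending C-order linear index over the mask.
    """
    if isinstance(image4d, nib.spatialimages.SpatialImage):
        data = np.asarray(image4d.dataobj)
        if tr is None:
            tr = float(image4d.header.get_zooms()[3]) if data.ndim == 4 else 1.0
    else:
        data = np.asarray(image4d)
    if data.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image grid {data.shape[:3]}"
        )
    if not mask.any():
        raise ValueError("empty mask")
    series = data[mask]  # (n_voxels, t) in C order of the mask
    return RoiTimeSeries(
        data=series.T.astype(float),
        run_labels=np.asarray(run_labels, dtype=int),
        tr=float(tr if tr is not None else 1.0),
        roi=roi,
        subject=subject,
        hemisphere=hemisphere,
    )


def embed_in_volume(
    ts: RoiTimeSeries, mask: np.ndarray, grid: VoxelGrid, fill: float = 0.0
) -> np.ndarray:
    """Place a time x voxel matrix back into a 4-D volume at the masked voxels."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() != ts.n_voxels:
        raise ValueError("mask voxel count does not match time series")
    vol = np.full((*grid.shape, ts.n_volumes), fill, dtype=float)
    vol[mask] = ts.data.T
    return vol
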