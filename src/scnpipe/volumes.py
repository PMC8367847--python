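"""Volumetric morphometry maps: I/O, smoothing, resampling, masking, vectorization.

The analysis operates on per-subject log-Jacobian determinant maps: voxelwise
log expansion/contraction factors relative to a group template, with the affine
(head-size) component already removed so values are centered near zero.  This
module turns a cohort of such maps into the masked voxels x subjects matrix
that the network factorization consumes.

Preprocessing order follows the morphometry convention: smooth in the
log-Jacobian domain, resample to the analysis resolution, mask, and only then
(optionally) exponentiate voxel values so the factorization sees strictly
positive data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

# sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VolumetricMap:
    """One subject's 3D scalar field on a regular grid.

    values are dimensionless log-Jacobians; spacing_mm is the voxel size per
    axis; affine maps voxel indices to world coordinates.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all three spacing components must be > 0")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class AtlasMask:
    """Labelled (or binary) mask on the analysis grid; label 0 is background."""

    labels: np.ndarray
    region_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be a 3D label volume")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative integers")
        if not np.any(self.labels > 0):
            raise ValueError("mask has no in-mask voxels")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.labels))


@dataclass
class VoxelMatrix:
    """Masked voxels x subjects matrix plus the index map back to the grid.

    Rows follow a fixed last-axis-fastest (C-order) scan of the in-mask
    voxels, so the matrix is reproducible across runs and columns of a basis
    matrix can be scattered back onto the grid.
    """

    data: np.ndarray
    voxel_index: np.ndarray
    subject_ids: list[str]
    grid_shape: tuple[int, int, int]
    transform_log: list[str] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[1]

    def scatter_back(self, column: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a length-V vector back onto the 3D grid (out-of-mask = fill)."""
        column = np.asarray(column, dtype=float)
        if column.shape != (self.n_voxels,):
            raise ValueError("column length must equal the number of in-mask voxels")
        out = np.full(self.grid_shape, fill, dtype=float)
        out[tuple(self.voxel_index.T)] = column
        return out

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            data=self.data,
            voxel_index=self.voxel_index,
            subject_ids=np.asarray(self.subject_ids, dtype=object),
            grid_shape=np.asarray(self.grid_shape),
            transform_log=json.dumps(self.transform_log),
        )

    @classmethod
    def load(cls, path: str | Path) -> "VoxelMatrix":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                data=z["data"],
                voxel_index=z["voxel_index"],
                subject_ids=[str(s) for s in z["subject_ids"]],
                grid_shape=tuple(int(i) for i in z["grid_shape"]),
                transform_log=json.loads(str(z["transform_log"])),
            )


def load_map(
    path: str | Path,
    expected_grid: tuple[int, int, int] | None = None,
    subject_id: str | None = None,
) -> VolumetricMap:
    """Read a 3D NIfTI volume into a VolumetricMap.

    NaN or Inf voxels are a load error (a missing value in a Jacobian map
    signals a registration failure, not data to impute).
    """
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj, dtype=float)
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    if values.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {values.ndim}D")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite values in {path}")
    if expected_grid is not None and values.shape != tuple(expected_grid):
        raise ValueError(
            f"grid mismatch in {path}: expected {tuple(expected_grid)}, got {values.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return VolumetricMap(values=values, spacing_mm=spacing, affine=img.affine, subject_id=sid)


def save_map(vmap: VolumetricMap, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vmap.values, dtype=np.float32), vmap.affine)
    img.header.set_zooms(vmap.spacing_mm)
    nib.save(img, str(path))


def load_mask(path: str | Path, expected_grid: tuple[int, int, int] | None = None) -> AtlasMask:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    labels = np.rint(labels).astype(int)
    if expected_grid is not None and labels.shape != tuple(expected_grid):
        raise ValueError(f"mask grid mismatch: expected {tuple(expected_grid)}, got {labels.shape}")
    return AtlasMask(labels=labels)


def smooth_gaussian(vmap: VolumetricMap, fwhm_mm: float) -> VolumetricMap:
    """Gaussian-smooth in the map's native (log) domain.

    The kernel sigma per axis is (fwhm_mm / (2 sqrt(2 ln 2))) / spacing so the
    smoothing extent is isotropic in millimetres regardless of voxel size.
    Reflect padding at the boundary avoids attenuating mask-adjacent signal.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in vmap.spacing_mm]
    smoothed = ndimage.gaussian_filter(vmap.values, sigma=sigma_vox, mode="reflect")
    return VolumetricMap(
        values=smoothed,
        spacing_mm=vmap.spacing_mm,
        affine=vmap.affine,
        subject_id=vmap.subject_id,
    )


def _resample_grid(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    target: float,
) -> tuple[tuple[int, int, int], list[np.ndarray]]:
    new_shape = tuple(int(np.ceil(n * s / target)) for n, s in zip(shape, spacing))
    # new voxel i sits at i * target mm along the axis -> old index i * target / s
    coords = [np.arange(n) * target / s for n, s in zip(new_shape, spacing)]
    return new_shape, coords


def downsample(vmap: VolumetricMap, target_spacing_mm: float) -> VolumetricMap:
    """Resample onto an isotropic grid at target_spacing_mm (trilinear)."""
    if any(target_spacing_mm < s for s in vmap.spacing_mm):
        raise ValueError("upsampling request: target spacing is finer than the input grid")
    new_shape, coords = _resample_grid(vmap.shape, vmap.spacing_mm, target_spacing_mm)
    grid = np.meshgrid(*coords, indexing="ij")
    resampled = ndimage.map_coordinates(vmap.values, np.asarray(grid), order=1, mode="nearest")
    scale = np.diag(
        [target_spacing_mm / s for s in vmap.spacing_mm] + [1.0]
    )
    new_affine = vmap.affine @ scale
    return VolumetricMap(
        values=resampled.reshape(new_shape),
        spacing_mm=(target_spacing_mm,) * 3,
        affine=new_affine,
        subject_id=vmap.subject_id,
    )


def downsample_mask(mask: AtlasMask, spacing_mm: tuple[float, float, float], target_spacing_mm: float) -> AtlasMask:
    """Nearest-neighbour resampling for label volumes."""
    if any(target_spacing_mm < s for s in spacing_mm):
        raise ValueError("upsampling request for mask")
    _, coords = _resample_grid(mask.labels.shape, tuple(spacing_mm), target_spacing_mm)
    grid = np.meshgrid(*coords, indexing="ij")
    resampled = ndimage.map_coordinates(mask.labels, np.asarray(grid), order=0, mode="nearest")
    return AtlasMask(labels=resampled.astype(int), region_names=mask.region_names)


def build_voxel_matrix(
    maps: Sequence[VolumetricMap],
    mask: AtlasMask,
    exponentiate: bool = True,
) -> VoxelMatrix:
    """Stack in-mask voxels of each map into a V x N matrix.

    With exponentiate=True, voxel values are exponentiated elementwise so the
    matrix is strictly positive, as the non-negative factorization requires.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    grid = mask.labels.shape
    for m in maps:
        if m.shape != grid:
            raise ValueError(
                f"grid mismatch for subject {m.subject_id!r}: {m.shape} vs mask {grid}"
            )
    ids = [m.subject_id for m in maps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_ids")
    # np.nonzero on a C-ordered array yields last-axis-fastest scan order
    idx = np.nonzero(mask.labels > 0)
    voxel_index = np.stack(idx, axis=1)
    data = np.empty((voxel_index.shape[0], len(maps)), dtype=float)
    for j, m in enumerate(maps):
        data[:, j] = m.values[idx]
    log = [f"mask({voxel_index.shape[0]} voxels)"]
    if exponentiate:
        data = np.exp(data)
        log.append("exponentiate")
    return VoxelMatrix(
        data=data,
        voxel_index=voxel_index,
        subject_ids=ids,
        grid_shape=grid,
        transform_log=log,
    )


def preprocess_maps(
    maps: Sequence[VolumetricMap],
    fwhm_mm: float | None = 4.0,
    target_spacing_mm: float | None = 2.0,
) -> list[VolumetricMap]:
    """Smooth (log domain) then downsample each map; either step optional."""
    out = []
    for m in maps:
        if fwhm_mm is not None:
            m = smooth_gaussian(m, fwhm_mm)
        if target_spacing_mm is not None and any(
            target_spacing_mm > s for s in m.spacing_mm
        ):
            m = downsample(m, target_spacing_mm)
        out.append(m)
    return out
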