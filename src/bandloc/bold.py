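"""BOLD Z-statistic volumes mapped onto dipole patches.

A voxelwise Z volume (NIfTI, already in the head frame of the patch model)
is related to patches by nearest patch center within a distance cap, then
aggregated with a dual threshold: a voxel is active at Z ≥ 2.5, and a patch
is active when at least a fraction (default 25 %) of its voxels are active,
in which case its value is the mean Z over the suprathreshold voxels;
otherwise the patch is zero.  NaN voxels mark non-brain and are excluded
from both counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import GeometryError, ParameterError
from .forward import CorticalPatchModel

__all__ = [
    "StatVolume",
    "VoxelPatchAssignment",
    "PatchActivation",
    "load_stat_volume",
    "assign_voxels_to_patches",
    "threshold_aggregate",
    "save_assignment",
    "load_assignment",
]


@dataclass
class StatVolume:
    """Voxel Z-scores on a 3D grid with a voxel→mm affine."""

    data: np.ndarray     # 3D float; NaN = outside brain
    affine: np.ndarray   # 4x4
    resolution: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("stat volume must be 3-D")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine must be an invertible 4x4 transform")

    def voxel_coords_mm(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(flat indices, mm coordinates) of voxels, optionally restricted to a mask."""
        if mask is None:
            mask = np.ones(self.data.shape, dtype=bool)
        ijk = np.argwhere(mask)
        flat = np.ravel_multi_index(ijk.T, self.data.shape)
        homog = np.c_[ijk, np.ones(len(ijk))]
        mm = homog @ self.affine.T
        return flat, mm[:, :3]


def load_stat_volume(path, extra_affine: np.ndarray | None = None) -> StatVolume:
    """Read a NIfTI Z volume; ``extra_affine`` maps it into the patch frame."""
    img = nib.load(str(path))
    affine = img.affine
    if extra_affine is not None:
        extra_affine = np.asarray(extra_affine, dtype=float)
        if extra_affine.shape != (4, 4):
            raise ParameterError("extra affine must be 4x4")
        affine = extra_affine @ affine
    zooms = img.header.get_zooms()[:3]
    return StatVolume(
        data=np.asarray(img.get_fdata(), dtype=float),
        affine=affine,
        resolution="x".join(f"{z:g}" for z in zooms),
    )


@dataclass
class VoxelPatchAssignment:
    """Each voxel related to at most one patch (flat index → patch id)."""

    voxel_index: np.ndarray   # (n_assigned,) flat voxel indices
    patch_id: np.ndarray      # (n_assigned,) patch ids
    n_patches: int

    @property
    def per_patch_count(self) -> np.ndarray:
        return np.bincount(self.patch_id, minlength=self.n_patches)


@dataclass
class PatchActivation:
    """Per-patch mean suprathreshold Z (or exactly 0)."""

    values: np.ndarray
    z_min: float
    fraction: float


def assign_voxels_to_patches(
    vol: StatVolume,
    patches: CorticalPatchModel,
    max_dist: float = 6.0,
) -> VoxelPatchAssignment:
    """Nearest-patch-center assignment with a distance cap (mm).

    Ties within 1e-9 mm go to the lowest patch id, making the assignment
    deterministic and voxel-order independent.  The default 6 mm cap is
    about one inter-patch spacing, so voxels far from any cortical patch
    stay unassigned.
    """
    from scipy.spatial import cKDTree

    finite = np.isfinite(vol.data)
    flat, mm = vol.voxel_coords_mm(finite)
    if len(flat) == 0:
        raise GeometryError("volume has no in-brain voxels")
    tree = cKDTree(patches.centers)
    k = min(2, patches.n_patches)
    dist, idx = tree.query(mm, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    nearest = idx[:, 0].copy()
    if k == 2:
        tie = (dist[:, 1] - dist[:, 0]) < 1e-9
        nearest[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
    keep = dist[:, 0] <= max_dist
    if not np.any(keep):
        raise GeometryError(
            f"no voxel within {max_dist} mm of any patch center; volume and "
            "patch model are probably in different frames"
        )
    return VoxelPatchAssignment(
        voxel_index=flat[keep], patch_id=nearest[keep],
        n_patches=patches.n_patches,
    )


def threshold_aggregate(
    vol: StatVolume,
    asg: VoxelPatchAssignment,
    z_min: float = 2.5,
    fraction: float = 0.25,
) -> PatchActivation:
    """Dual-threshold aggregation of voxel Z onto patches.

    Patch value = mean Z over its suprathreshold voxels when their fraction
    among the patch's (non-NaN) voxels reaches ``fraction``; else exactly 0.
    Lowering either threshold can only enlarge the active set.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must be in [0, 1]")
    z = vol.data.ravel()[asg.voxel_index]
    finite = np.isfinite(z)
    pid = asg.patch_id[finite]
    z = z[finite]
    n_total = np.bincount(pid, minlength=asg.n_patches)
    supra = z >= z_min
    n_supra = np.bincount(pid[supra], minlength=asg.n_patches)
    sum_supra = np.bincount(pid[supra], weights=z[supra], minlength=asg.n_patches)
    values = np.zeros(asg.n_patches)
    has = n_total > 0
    frac = np.zeros(asg.n_patches)
    frac[has] = n_supra[has] / n_total[has]
    active = has & (frac >= fraction) & (n_supra > 0)
    values[active] = sum_supra[active] / n_supra[active]
    return PatchActivation(values=values, z_min=z_min, fraction=fraction)


def save_assignment(asg: VoxelPatchAssignment, path) -> None:
    """Delimited (voxel index, patch id) rows."""
    with open(path, "w") as fh:
        fh.write(f"# n_patches {asg.n_patches}\n")
        for v, p in zip(asg.voxel_index, asg.patch_id):
            fh.write(f"{v} {p}\n")


def load_assignment(path) -> VoxelPatchAssignment:
    n_patches = 0
    vox, pid = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts[0] == "#":
                n_patches = int(parts[2])
                continue
            vox.append(int(parts[0]))
            pid.append(int(parts[1]))
    return VoxelPatchAssignment(
        voxel_index=np.array(vox, dtype=int),
        patch_id=np.array(pid, dtype=int),
        n_patches=n_patches or (max(pid) + 1 if pid else 0),
    )
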