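"""Volume I/O and the geometric conventions shared by the whole pipeline.

All volumes carry a NIfTI-style 4x4 voxel-to-world affine in RAS+
millimetres.  Landmarks and measurements downstream are always expressed in
world mm, never voxel indices, so results are invariant to how the grid is
oriented.  Label volumes use the fixed code table in :data:`LABEL_CODES`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LABEL_CODES",
    "LABEL_NAMES",
    "LabelVolume",
    "ImageVolume",
    "read_label_volume",
    "write_label_volume",
    "read_image_volume",
    "write_image_volume",
    "resample_labels",
]

#: Label code table: background, endocervical canal (ECC), inner stroma /
#: subglandular zone (SGZ), outer stroma (OS), fluid-filled cysts, bladder.
LABEL_CODES = {
    "background": 0,
    "canal": 1,
    "inner_stroma": 2,
    "outer_stroma": 3,
    "cyst": 4,
    "bladder": 5,
}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}
_VALID_CODES = frozenset(LABEL_CODES.values())


def _check_geometry(spacing: np.ndarray, affine: np.ndarray) -> None:
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")


@dataclass
class LabelVolume:
    """3D integer label grid with voxel spacing and world (mm) affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            if np.max(np.abs(self.voxels - rounded), initial=0.0) > 1e-6:
                raise ValueError("label data is not integer-valued")
            self.voxels = rounded.astype(np.int16)
        self.voxels = self.voxels.astype(np.int16, copy=False)
        present = set(np.unique(self.voxels).tolist())
        unknown = present - _VALID_CODES
        if unknown:
            raise ValueError(f"unknown label code(s): {sorted(unknown)}")
        _check_geometry(self.spacing, self.affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (sx, sy, sz) in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def label_at(self, xyz: np.ndarray) -> int:
        """Nearest-neighbour label at a world point (background off-grid)."""
        ijk = np.rint(self.world_to_voxel(xyz)).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(self.shape)):
            return 0
        return int(self.voxels[tuple(ijk)])


@dataclass
class ImageVolume:
    """3D real-valued intensity grid, same geometric conventions."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        _check_geometry(self.spacing, self.affine)

    spacing = LabelVolume.spacing
    shape = LabelVolume.shape
    voxel_to_world = LabelVolume.voxel_to_world
    world_to_voxel = LabelVolume.world_to_voxel

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI label map, validating integer data and label codes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return LabelVolume(voxels=data, affine=img.affine)


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a label map as NIfTI plus a JSON sidecar with the code table."""
    path = Path(path)
    img = nib.Nifti1Image(vol.voxels.astype(np.int16), vol.affine)
    nib.save(img, str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    sidecar.write_text(json.dumps(LABEL_CODES, indent=2))


def read_image_volume(path: str | Path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return ImageVolume(voxels=np.asanyarray(img.dataobj), affine=img.affine)


def write_image_volume(vol: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine), str(path))


def resample_labels(vol: LabelVolume, new_spacing: float) -> LabelVolume:
    """Nearest-neighbour resample onto an isotropic grid of ``new_spacing`` mm.

    The output grid covers the same world extent as the input.  Labels are
    never interpolated, so no new codes can appear.
    """
    if not np.isfinite(new_spacing) or new_spacing <= 0:
        raise ValueError(f"new_spacing must be > 0, got {new_spacing}")
    # New grid axes follow the input's axis directions with unit spacing scaled.
    R = vol.affine[:3, :3] / vol.spacing  # direction cosines per column
    old_shape = np.array(vol.shape)
    extent = vol.spacing * old_shape  # world extent along each grid axis
    new_shape = np.maximum(1, np.rint(extent / new_spacing).astype(int))
    if np.array_equal(new_shape, old_shape) and np.allclose(new_spacing, vol.spacing):
        return LabelVolume(voxels=vol.voxels.copy(), affine=vol.affine.copy())
    new_affine = np.eye(4)
    new_affine[:3, :3] = R * new_spacing
    # Keep the world centre of the grid fixed.
    old_centre = vol.voxel_to_world((old_shape - 1) / 2.0)
    new_affine[:3, 3] = old_centre - new_affine[:3, :3] @ ((new_shape - 1) / 2.0)
    # Map new voxel indices into old voxel indices: inv(A_old) @ A_new.
    M = np.linalg.inv(vol.affine) @ new_affine
    out = ndimage.affine_transform(
        vol.voxels,
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(new_shape),
        order=0,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    return LabelVolume(voxels=out, affine=new_affine)
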