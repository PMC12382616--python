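"""In-memory containers and NIfTI I/O for volumes and 4D series."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import InvalidInputError


@dataclass
class SubjectTimeSeries:
    """A 4D BOLD series with its voxel-to-world affine and brain mask.

    ``data`` has shape (x, y, z, n); ``mask`` is boolean (x, y, z).
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    tr: float = 2.5

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise InvalidInputError("BOLD data must be 4D (x, y, z, time)")
        if self.mask.shape != self.data.shape[:3]:
            raise InvalidInputError("mask shape must match the spatial grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def frame_matrix(self) -> np.ndarray:
        """Return the (n_volumes, n_mask_voxels) data matrix."""
        return self.data[self.mask].T

    def from_frame_matrix(self, matrix: np.ndarray) -> np.ndarray:
        """Scatter an (n, V) matrix back into a 4D array (zeros outside mask)."""
        out = np.zeros(self.data.shape, dtype=float)
        out[self.mask] = matrix.T
        return out

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr))
        return img


def save_volume(values: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def save_label_volume(values: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.int16), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_series(series: SubjectTimeSeries, path) -> None:
    nib.save(series.to_nifti(), str(path))


def load_series(path, mask: np.ndarray, tr: float = 2.5) -> SubjectTimeSeries:
    img = nib.load(str(path))
    return SubjectTimeSeries(
        data=np.asarray(img.dataobj, dtype=float),
        affine=img.affine,
        mask=mask,
        tr=tr,
    )


def mask_to_world(affine: np.ndarray, voxel_coords: np.ndarray) -> np.ndarray:
    """Map (N, 3) voxel indices to world coordinates under a 4x4 affine."""
    voxel_coords = np.atleast_2d(voxel_coords)
    hom = np.c_[voxel_coords, np.ones(len(voxel_coords))]
    return (affine @ hom.T).T[:, :3]
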