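"""3D image containers with isotropic spacing and NIfTI I/O.

World-coordinate convention used throughout the package: the position of
voxel index ``i`` (0-based) along any axis is ``(i + 0.5) * spacing_mm``,
i.e. indices address voxel centers, the grid origin is a voxel corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class ImageVolume:
    """A scalar 3D grid with isotropic voxel spacing in millimetres."""

    data: np.ndarray
    spacing_mm: float = 0.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_mm(self, index) -> np.ndarray:
        """World position of a voxel index under the voxel-center convention."""
        return (np.asarray(index, dtype=float) + 0.5) * self.spacing_mm

    def mm_to_index(self, position_mm) -> np.ndarray:
        """Fractional voxel index of a world position (inverse of index_to_mm)."""
        return np.asarray(position_mm, dtype=float) / self.spacing_mm - 0.5


@dataclass
class AnnotationMap:
    """Integer label volume; label 0 is background, labels >= 1 are nodes."""

    labels: np.ndarray
    spacing_mm: float = 0.8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("annotation labels must be integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def node_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]


@dataclass
class NodeProperties:
    label: int
    center_mm: np.ndarray
    volume_ml: float
    voxel_count: int = field(default=0)


def _affine(spacing_mm: float) -> np.ndarray:
    aff = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    # voxel-center convention: index 0 sits at spacing/2 from the grid corner
    aff[:3, 3] = 0.5 * spacing_mm
    return aff


def save_volume(volume: ImageVolume | AnnotationMap, path: str) -> None:
    """Write a volume or label map as NIfTI; spacing goes into the affine."""
    data = volume.data if isinstance(volume, ImageVolume) else volume.labels
    if not isinstance(volume, ImageVolume):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(np.asarray(data), _affine(volume.spacing_mm))
    nib.save(img, path)


def load_volume(path: str) -> ImageVolume:
    img = nib.load(path)
    spacing = float(img.header.get_zooms()[0])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing)


def load_annotation(path: str) -> AnnotationMap:
    img = nib.load(path)
    spacing = float(img.header.get_zooms()[0])
    return AnnotationMap(np.asarray(img.dataobj).astype(np.int32), spacing)
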