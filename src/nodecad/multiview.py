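"""Multi-view 2D patch extraction around candidate locations.

Patches of 65 x 65 samples at the voxel pitch (0.8 mm -> a 52 x 52 mm
field of view) are resliced on the nine symmetry planes of a cube centered
on the candidate: three planes parallel to the cube faces (the axial /
coronal / sagittal planes) and six planes running diagonally from one
edge to the opposite edge.  The 1-view set is the original image plane,
the 3-view set the three axis-aligned planes, the 9-view set all nine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stage1 import Candidate
from .volume import ImageVolume

PATCH_SIZE = 65
PATCH_STEP_MM = 0.8

_SQ2 = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class ViewBasis:
    """One oriented sampling plane: two orthonormal in-plane axes."""

    view_id: int
    u: tuple[float, float, float]
    v: tuple[float, float, float]

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def __post_init__(self) -> None:
        u, v = np.asarray(self.u), np.asarray(self.v)
        if not (np.isclose(np.linalg.norm(u), 1) and np.isclose(np.linalg.norm(v), 1)):
            raise ValueError("basis vectors must be unit length")
        if not np.isclose(np.dot(u, v), 0):
            raise ValueError("basis vectors must be orthogonal")


def enumerate_view_bases() -> list[ViewBasis]:
    """The nine symmetry-plane bases of a cube, in fixed documented order.

    Views 0-2 are axis-aligned (view 0 = the original/coronal image plane,
    spanned by the first two grid axes).  Views 3-8 are the edge-diagonal
    planes: u is a face diagonal, v the coordinate axis orthogonal to that
    face.  Subsets: 1-view = {0}, 3-view = {0,1,2}, 9-view = all.
    """
    e = np.eye(3)
    bases = [
        ViewBasis(0, tuple(e[0]), tuple(e[1])),
        ViewBasis(1, tuple(e[0]), tuple(e[2])),
        ViewBasis(2, tuple(e[1]), tuple(e[2])),
    ]
    diagonals = [
        ((1, 1, 0), 2),
        ((1, -1, 0), 2),
        ((1, 0, 1), 1),
        ((-1, 0, 1), 1),
        ((0, 1, 1), 0),
        ((0, 1, -1), 0),
    ]
    for i, (diag, axis) in enumerate(diagonals):
        u = tuple(np.asarray(diag, dtype=float) * _SQ2)
        bases.append(ViewBasis(3 + i, u, tuple(e[axis])))
    return bases


VIEW_SUBSETS = {1: [0], 3: [0, 1, 2], 9: list(range(9))}


@dataclass
class PatchSet:
    """The 1/3/9 resliced patches around one candidate."""

    candidate: Candidate
    patches: np.ndarray  # (k, 65, 65)
    view_ids: list[int]
    label: int | None = None  # 1 = node, 0 = non-node

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        if self.patches.ndim != 3 or self.patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"patches must be (k, {PATCH_SIZE}, {PATCH_SIZE}), got {self.patches.shape}"
            )
        if self.patches.shape[0] != len(self.view_ids):
            raise ValueError("patch count does not match view_ids")


def extract_patch(
    volume: ImageVolume,
    center_mm,
    basis: ViewBasis,
    size: int = PATCH_SIZE,
    step_mm: float = PATCH_STEP_MM,
) -> np.ndarray:
    """Reslice one oriented patch by trilinear interpolation.

    Sample p(i, j) = center + (i - size//2) * step * u + (j - size//2) * step * v.
    Samples outside the volume are zero-padded (zero equals the normalized
    background mean, so border candidates still yield full patches).
    """
    if size < 3 or size % 2 == 0:
        raise ValueError("patch size must be odd and >= 3")
    center_mm = np.asarray(center_mm, dtype=float)
    half = size // 2
    offs = (np.arange(size) - half) * step_mm
    u = np.asarray(basis.u)
    v = np.asarray(basis.v)
    pts = (
        center_mm[None, None, :]
        + offs[:, None, None] * u[None, None, :]
        + offs[None, :, None] * v[None, None, :]
    )  # (size, size, 3) world mm
    idx = pts / volume.spacing_mm - 0.5  # fractional voxel indices
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        volume.data.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    )


def make_view_set(
    volume: ImageVolume,
    candidate: Candidate,
    n_views: int,
    size: int = PATCH_SIZE,
    step_mm: float = PATCH_STEP_MM,
    label: int | None = None,
) -> PatchSet:
    """Extract the fixed-order 1/3/9-view patch set for one candidate."""
    if n_views not in VIEW_SUBSETS:
        raise ValueError(f"n_views must be one of {sorted(VIEW_SUBSETS)}")
    bases = enumerate_view_bases()
    ids = VIEW_SUBSETS[n_views]
    patches = np.stack(
        [extract_patch(volume, candidate.position_mm, bases[i], size, step_mm) for i in ids]
    )
    return PatchSet(candidate=candidate, patches=patches, view_ids=list(ids), label=label)
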