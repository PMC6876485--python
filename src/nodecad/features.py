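"""Per-voxel feature maps for the stage-1 voxel classifier.

Three feature families: per-volume standardized intensities of each MR
channel; Hessian-eigenvalue shape features (blobness, vesselness,
sheetness) computed at multiple Gaussian scales and aggregated by maximum;
and positional features (normalized grid coordinates plus optional signed
distances to labelled landmark masks) standing in for atlas-based
position information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

DEFAULT_SCALES_MM = (1.6, 2.4, 3.2)


class DegenerateInputError(ValueError):
    pass


@dataclass
class FeatureStack:
    """Named scalar feature volumes sharing one grid."""

    names: list[str]
    maps: list[np.ndarray]
    spacing_mm: float
    scales_mm: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.maps):
            raise ValueError("names and maps must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        shapes = {m.shape for m in self.maps}
        if len(shapes) > 1:
            raise ValueError(f"feature maps disagree on shape: {shapes}")
        for name, m in zip(self.names, self.maps):
            if not np.all(np.isfinite(m)):
                raise ValueError(f"non-finite values in feature map {name!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.maps[0].shape

    def as_matrix(self) -> np.ndarray:
        """(n_voxels, n_features) row-major view of the stack."""
        return np.stack([m.ravel() for m in self.maps], axis=1)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[self.names.index(name)]

    @staticmethod
    def concatenate(stacks: list["FeatureStack"]) -> "FeatureStack":
        names = [n for st in stacks for n in st.names]
        maps = [m for st in stacks for m in st.maps]
        scales = tuple(sorted({sc for st in stacks for sc in st.scales_mm}))
        return FeatureStack(names, maps, stacks[0].spacing_mm, scales)


def normalize_intensity(volume: ImageVolume) -> ImageVolume:
    """Standardize intensities by the per-volume mean and population SD."""
    data = volume.data
    if data.size <= 1:
        raise DegenerateInputError("volume must have more than one voxel")
    mu = data.mean()
    sigma = data.std()  # population SD
    if sigma == 0:
        raise DegenerateInputError("volume has zero intensity variance")
    return ImageVolume((data - mu) / sigma, volume.spacing_mm)


def _hessian_eigenvalues(data: np.ndarray, sigma_vox: float, spacing: float):
    """Eigenvalues of the scale-normalized Gaussian Hessian, |l1|<=|l2|<=|l3|."""
    h = np.empty(data.shape + (3, 3))
    orders = {(0, 0): (2, 0, 0), (1, 1): (0, 2, 0), (2, 2): (0, 0, 2),
              (0, 1): (1, 1, 0), (0, 2): (1, 0, 1), (1, 2): (0, 1, 1)}
    for (i, j), order in orders.items():
        d = ndimage.gaussian_filter(data, sigma_vox, order=order, mode="nearest")
        h[..., i, j] = d
        if i != j:
            h[..., j, i] = d
    # gamma=2 scale normalization keeps responses comparable across scales;
    # derivatives are per-voxel, so the physical factor is (sigma_vox)^2
    h *= sigma_vox**2
    eig = np.linalg.eigvalsh(h.reshape(-1, 3, 3))
    order = np.argsort(np.abs(eig), axis=1)
    eig = np.take_along_axis(eig, order, axis=1)
    return eig.reshape(data.shape + (3,))


def _shape_responses(eig: np.ndarray, alpha: float, beta: float):
    """Frangi-style bright-structure responses from sorted eigenvalues.

    blobness: all three eigenvalues negative and of comparable magnitude;
    vesselness: l1 ~ 0, l2 ~ l3 << 0; sheetness: l1 ~ l2 ~ 0, l3 << 0.
    Each response is a product of ratio terms and a second-order
    structureness term 1 - exp(-S^2 / 2c^2) with per-volume adaptive c.
    """
    l1, l2, l3 = eig[..., 0], eig[..., 1], eig[..., 2]
    a1, a2, a3 = np.abs(l1), np.abs(l2), np.abs(l3)
    eps = np.finfo(float).tiny
    s2 = a1**2 + a2**2 + a3**2  # squared Frobenius norm
    c = 0.5 * np.sqrt(s2.max())
    if c == 0:
        z = np.zeros_like(l1)
        return z, z.copy(), z.copy()
    structness = 1.0 - np.exp(-s2 / (2 * c**2))

    ra = a2 / np.maximum(a3, eps)           # ~1 tube/blob, ~0 sheet
    rb = a1 / np.maximum(np.sqrt(a2 * a3), eps)  # ~1 blob, ~0 tube/sheet
    rs = np.sqrt(a1 * a2) / np.maximum(a3, eps)  # ~0 sheet, ~1 blob

    vessel = (
        (1.0 - np.exp(-(ra**2) / (2 * alpha**2)))
        * np.exp(-(rb**2) / (2 * beta**2))
        * structness
    )
    vessel[(l2 >= 0) | (l3 >= 0)] = 0.0

    blob = np.exp(-((1.0 - rb) ** 2) / (2 * beta**2)) * np.exp(
        -((1.0 - ra) ** 2) / (2 * alpha**2)
    ) * structness
    blob[(l1 >= 0) | (l2 >= 0) | (l3 >= 0)] = 0.0

    sheet = (
        (1.0 - np.exp(-((1.0 - ra) ** 2) / (2 * alpha**2)))
        * np.exp(-(rs**2) / (2 * beta**2))
        * structness
    )
    sheet[l3 >= 0] = 0.0
    return blob, vessel, sheet


def hessian_shape_features(
    volume: ImageVolume,
    scales_mm: list[float] | tuple[float, ...] = DEFAULT_SCALES_MM,
    alpha: float = 0.5,
    beta: float = 0.5,
    bright: bool = True,
) -> FeatureStack:
    """Blobness, vesselness and sheetness maps, max-aggregated over scales.

    All maps are bounded to [0, 1].  ``bright=False`` flips the intensity
    polarity before filtering (dark structures on a bright background).
    """
    scales = tuple(float(s) for s in scales_mm)
    if len(scales) == 0:
        raise ValueError("at least one Hessian scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError("scales_mm must all be positive")
    data = volume.data.astype(np.float64)
    if not bright:
        data = -data
    best = [np.zeros(data.shape) for _ in range(3)]
    for scale in scales:
        eig = _hessian_eigenvalues(data, scale / volume.spacing_mm, volume.spacing_mm)
        for i, resp in enumerate(_shape_responses(eig, alpha, beta)):
            np.maximum(best[i], resp, out=best[i])
    return FeatureStack(
        ["blobness", "vesselness", "sheetness"], best, volume.spacing_mm, scales
    )


def positional_features(
    volume: ImageVolume, landmarks: list[tuple[str, np.ndarray]] | None = None
) -> FeatureStack:
    """Normalized coordinate maps plus signed landmark distances in mm.

    Each axis coordinate is scaled to [0, 1] over the grid.  For every
    landmark mask a signed Euclidean distance map is added: negative inside
    the mask, positive outside.
    """
    shape = volume.shape
    names, maps = [], []
    for ax, name in enumerate(("coord_x", "coord_y", "coord_z")):
        n = shape[ax]
        coord = np.arange(n, dtype=np.float64) / max(n - 1, 1)
        view = [1, 1, 1]
        view[ax] = n
        maps.append(np.broadcast_to(coord.reshape(view), shape).copy())
        names.append(name)
    for name, mask in landmarks or []:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(
                f"landmark {name!r} shape {mask.shape} does not match grid {shape}"
            )
        s = volume.spacing_mm
        outside = ndimage.distance_transform_edt(~mask, sampling=s)
        inside = ndimage.distance_transform_edt(mask, sampling=s)
        maps.append(outside - inside)
        names.append(f"dist_{name}")
    return FeatureStack(names, maps, volume.spacing_mm)


def compute_default_features(
    t1_like: ImageVolume,
    t2s_like: ImageVolume | None = None,
    scales_mm=DEFAULT_SCALES_MM,
    landmarks=None,
) -> FeatureStack:
    """The default stage-1 feature stack.

    Standardized intensity per channel, Hessian shape features on the
    T1-like channel (the channel in which nodes are bright), and positional
    features.
    """
    stacks = []
    t1n = normalize_intensity(t1_like)
    stacks.append(
        FeatureStack(["intensity_t1"], [t1n.data], t1_like.spacing_mm)
    )
    if t2s_like is not None:
        t2n = normalize_intensity(t2s_like)
        stacks.append(
            FeatureStack(["intensity_t2s"], [t2n.data], t2s_like.spacing_mm)
        )
    stacks.append(hessian_shape_features(t1n, scales_mm))
    stacks.append(positional_features(t1_like, landmarks))
    return FeatureStack.concatenate(stacks)
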