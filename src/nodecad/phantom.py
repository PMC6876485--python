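"""Synthetic dual-channel 3D phantoms with ground-truth node annotations.

The phantoms emulate co-registered isotropic pelvic MR Lymphography
volumes: a T1-weighted-like channel in which lymph nodes appear as bright
nodular structures, and a T2*-weighted-like channel sharing the same
geometry with independent contrasts.  Besides ellipsoidal nodes (3-10 mm,
the size range of non-enlarged lymph nodes) the scenes contain curved
bright tubes emulating blood vessels and thin slabs emulating fascia-like
sheets -- the structures a nodular-blob detector confuses with nodes.
Additive Gaussian noise is applied per channel.

No MR physics, bias fields, contrast-uptake kinetics or patient anatomy
are simulated; the phantoms exist so that every stage of the detection
pipeline is trainable and measurable with known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .volume import AnnotationMap, ImageVolume, NodeProperties, save_volume


class PlacementError(RuntimeError):
    """Raised when structures cannot be placed without overlap."""


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise settings for one synthetic scene.

    Contrasts are (T1-like, T2*-like) intensity offsets added on top of
    ``background_level``; all intensities are in arbitrary units.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 0.8
    n_nodes: int = 5
    node_diameter_range_mm: tuple[float, float] = (3.0, 10.0)
    n_vessels: int = 3
    vessel_radius_range_mm: tuple[float, float] = (1.2, 2.5)
    n_sheets: int = 1
    sheet_thickness_mm: float = 1.6
    node_contrast: tuple[float, float] = (1.0, 0.6)
    vessel_contrast: tuple[float, float] = (0.85, 0.9)
    sheet_contrast: tuple[float, float] = (0.5, 0.5)
    background_level: tuple[float, float] = (0.2, 0.2)
    noise_sd: float = 0.05
    hypointense_nodes_t2: bool = False
    margin_voxels: int = 3
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nodes", "n_vessels", "n_sheets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        lo, hi = self.node_diameter_range_mm
        if not (0 < lo <= hi <= 10.0):
            raise ValueError(
                "node_diameter_range_mm must satisfy 0 < min <= max <= 10 mm "
                "(the maximum size of non-enlarged lymph nodes)"
            )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in (
            "grid_shape",
            "node_diameter_range_mm",
            "vessel_radius_range_mm",
            "node_contrast",
            "vessel_contrast",
            "sheet_contrast",
            "background_level",
        ):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Phantom:
    """Two co-registered channels plus the ground-truth node label map."""

    t1_like: ImageVolume
    t2s_like: ImageVolume
    annotation: AnnotationMap
    config: PhantomConfig = field(repr=False, default=None)

    @property
    def channels(self) -> dict[str, ImageVolume]:
        return {"T1-like": self.t1_like, "T2*-like": self.t2s_like}

    def save(self, prefix: str) -> dict[str, str]:
        paths = {
            "t1_like": f"{prefix}_t1.nii.gz",
            "t2s_like": f"{prefix}_t2s.nii.gz",
            "annotation": f"{prefix}_labels.nii.gz",
        }
        save_volume(self.t1_like, paths["t1_like"])
        save_volume(self.t2s_like, paths["t2s_like"])
        save_volume(self.annotation, paths["annotation"])
        return paths


def _voxel_center_grid(shape, spacing):
    axes = [(np.arange(n) + 0.5) * spacing for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _ellipsoid_mask(grid_mm, center_mm, semiaxes_mm, rotation):
    rel = np.stack([g - c for g, c in zip(grid_mm, center_mm)], axis=-1)
    local = rel @ rotation  # rotate into the ellipsoid frame
    d = (local / semiaxes_mm) ** 2
    return d.sum(axis=-1) <= 1.0


def _vessel_path(rng, start_mm, end_mm, wiggle_mm, n_ctrl=4, n_samples=160):
    """Mildly curved polyline from start to end, densely resampled.

    Control points along the chord are perturbed orthogonally so the tube
    intersects sampling planes both longitudinally and transversally.
    """
    t = np.linspace(0.0, 1.0, n_ctrl)
    pts = start_mm[None] * (1 - t)[:, None] + end_mm[None] * t[:, None]
    pts[1:-1] += rng.normal(scale=wiggle_mm, size=(n_ctrl - 2, 3))
    # Catmull-Rom-like dense resampling via piecewise linear interpolation of
    # an upsampled smooth parameterization
    ts = np.linspace(0.0, 1.0, n_samples)
    path = np.empty((n_samples, 3))
    for ax in range(3):
        path[:, ax] = np.interp(ts, t, pts[:, ax])
    # smooth corners with a small moving average (keeps endpoints)
    k = 9
    kernel = np.ones(k) / k
    for ax in range(3):
        padded = np.concatenate(
            [np.full(k // 2, path[0, ax]), path[:, ax], np.full(k // 2, path[-1, ax])]
        )
        path[:, ax] = np.convolve(padded, kernel, mode="valid")
    return path


def _stamp_tube(mask, path_mm, radius_mm, spacing):
    """Rasterize a tube by stamping spheres along a dense path."""
    shape = mask.shape
    r_vox = radius_mm / spacing
    ir = int(np.ceil(r_vox))
    offs = np.arange(-ir, ir + 1)
    oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")
    ball = (oz**2 + oy**2 + ox**2) <= r_vox**2
    ball_idx = np.argwhere(ball) - ir
    for p in path_mm:
        c = np.round(p / spacing - 0.5).astype(int)
        pts = ball_idx + c
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[ok]
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Generate one deterministic dual-channel phantom.

    Nodes are randomly oriented ellipsoids labelled 1..n_nodes, vessels are
    curved tubes, sheets are thin slabs; each is brighter than background in
    the T1-like channel.  Placement retries until structures do not overlap;
    raises :class:`PlacementError` after ``config.max_retries`` failures.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    s = config.spacing_mm
    grid_mm = _voxel_center_grid(shape, s)
    extent_mm = np.array(shape) * s

    labels = np.zeros(shape, dtype=np.int32)
    node_masks = []
    node_centers = []
    node_radii = []

    margin_mm = config.margin_voxels * s
    dlo, dhi = config.node_diameter_range_mm
    for k in range(config.n_nodes):
        placed = False
        for _ in range(config.max_retries):
            diam = rng.uniform(dlo, dhi)
            semi = 0.5 * diam * rng.uniform(0.75, 1.0, size=3)
            semi[rng.integers(3)] = 0.5 * diam  # major axis equals the diameter
            rmax = semi.max()
            lo = margin_mm + rmax
            hi = extent_mm - margin_mm - rmax
            if np.any(hi <= lo):
                raise PlacementError("grid too small for requested node geometry")
            center = rng.uniform(lo, hi)
            if any(
                np.linalg.norm(center - c) < rmax + r + 1.0
                for c, r in zip(node_centers, node_radii)
            ):
                continue
            rot = _random_rotation(rng)
            mask = _ellipsoid_mask(grid_mm, center, semi, rot)
            if mask.sum() == 0 or np.any(labels[mask] > 0):
                continue
            labels[mask] = k + 1
            node_masks.append(mask)
            node_centers.append(center)
            node_radii.append(rmax)
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place node {k + 1} without overlap")

    vessel_mask = np.zeros(shape, dtype=bool)
    rlo, rhi = config.vessel_radius_range_mm
    for _ in range(config.n_vessels):
        placed = False
        for _ in range(config.max_retries):
            radius = rng.uniform(rlo, rhi)
            axis = rng.integers(3)
            start = rng.uniform(margin_mm, extent_mm - margin_mm)
            end = rng.uniform(margin_mm, extent_mm - margin_mm)
            start[axis], end[axis] = margin_mm, extent_mm[axis] - margin_mm
            path = _vessel_path(rng, start, end, wiggle_mm=0.12 * extent_mm.mean())
            clearance = np.array(node_radii) + radius + 1.0 if node_centers else None
            if node_centers:
                d = np.linalg.norm(
                    path[:, None, :] - np.asarray(node_centers)[None], axis=-1
                )
                if np.any(d.min(axis=0) < clearance):
                    continue
            _stamp_tube(vessel_mask, path, radius, s)
            placed = True
            break
        if not placed:
            raise PlacementError("could not route a vessel clear of the nodes")
    vessel_mask &= labels == 0

    sheet_mask = np.zeros(shape, dtype=bool)
    for _ in range(config.n_sheets):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        center = rng.uniform(0.3 * extent_mm, 0.7 * extent_mm)
        dist = sum((g - c) * n for g, c, n in zip(grid_mm, center, normal))
        sheet_mask |= np.abs(dist) <= 0.5 * config.sheet_thickness_mm
    sheet_mask &= (labels == 0) & ~vessel_mask

    channels = []
    node_all = labels > 0
    for ch in range(2):
        img = np.full(shape, config.background_level[ch], dtype=np.float64)
        node_c = config.node_contrast[ch]
        if ch == 1 and config.hypointense_nodes_t2:
            node_c = -node_c
        img[node_all] += node_c
        img[vessel_mask] += config.vessel_contrast[ch]
        img[sheet_mask] += config.sheet_contrast[ch]
        img += rng.normal(scale=config.noise_sd, size=shape)
        channels.append(ImageVolume(img, s))

    return Phantom(channels[0], channels[1], AnnotationMap(labels, s), config)


def node_properties(
    annotation: AnnotationMap, spacing_mm: float | None = None
) -> list[NodeProperties]:
    """Per-node center of gravity (mm, voxel-center convention) and volume (ml).

    volume_ml = voxel_count * spacing^3 / 1000; the center is the unweighted
    mean of member voxel centers.
    """
    s = annotation.spacing_mm if spacing_mm is None else spacing_mm
    out = []
    for lab in annotation.node_labels():
        idx = np.argwhere(annotation.labels == lab)
        center = (idx.mean(axis=0) + 0.5) * s
        count = len(idx)
        out.append(
            NodeProperties(
                label=int(lab),
                center_mm=center,
                volume_ml=count * s**3 / 1000.0,
                voxel_count=count,
            )
        )
    return out
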