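"""Pipeline configuration: defaults, YAML round-trip, seed fan-out."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .features import DEFAULT_SCALES_MM
from .mvcnn import TrainConfig
from .phantom import PhantomConfig

# fixed offsets so one global seed reproducibly fans out to independent
# per-module streams
SEED_OFFSETS = {
    "phantom": 11,
    "voxel_training": 23,
    "folds": 37,
    "cnn_training": 41,
    "cnn_init": 53,
    "bootstrap": 67,
    "null_test": 79,
}


def module_seed(global_seed: int, module: str, extra: int = 0) -> int:
    return (int(global_seed) * 1000003 + SEED_OFFSETS[module] + extra) % (2**31 - 1)


@dataclass
class Stage1Config:
    n_rounds: int = 200
    window_diameter_mm: float = 10.0
    floor: float = 0.01
    max_voxels_per_class: int = 4000
    scales_mm: tuple[float, ...] = DEFAULT_SCALES_MM


@dataclass
class EvalConfig:
    n_boot: int = 1000
    fp_lo: float = 0.25
    fp_hi: float = 32.0
    k_folds: int = 5


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, defaulting to the reference
    operating values (200 boosting rounds, 10 mm maxima window, 65-voxel
    patches, the standard network and training settings, pAUC over
    0.25-32 FP/node)."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_phantoms: int = 20
    stage1: Stage1Config = field(default_factory=Stage1Config)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    n_views: int = 3
    fp_subsample: float = 1.0
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "phantom" in kwargs:
            ph = dict(kwargs["phantom"])
            for key in (
                "grid_shape", "node_diameter_range_mm", "vessel_radius_range_mm",
                "node_contrast", "vessel_contrast", "sheet_contrast",
                "background_level",
            ):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = PhantomConfig(**ph)
        if "stage1" in kwargs:
            st = dict(kwargs["stage1"])
            if "scales_mm" in st:
                st["scales_mm"] = tuple(st["scales_mm"])
            kwargs["stage1"] = Stage1Config(**st)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "eval" in kwargs:
            kwargs["eval"] = EvalConfig(**kwargs["eval"])
        return cls(**kwargs)
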