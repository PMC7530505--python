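"""Run configuration: one YAML/JSON file covering every pipeline stage.

A single global seed deterministically derives per-module seeds, so a run
is reproducible end to end from the config file alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .classification_model import ClsConfig
from .segmentation_model import SegConfig
from .synthetic_data import PhantomConfig
from .training import ClsTrainConfig, SegTrainConfig

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(global_seed: int, module: str) -> int:
    """Stable per-module seed below 2^31 derived from the global seed."""
    import zlib

    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF,
                                 zlib.crc32(module.encode()) & 0x7FFFFFFF])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _build(cls, section: dict, seed: int | None = None, seed_field: str = "seed"):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in (section or {}).items() if k in names}
    unknown = set(section or {}) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    for key in ("tumor_area_range", "intensity_scale_range",
                "intensity_offset_range", "conv_filters"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if seed is not None and seed_field in names and seed_field not in kwargs:
        kwargs[seed_field] = seed
    return cls(**kwargs)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs"
    test_fraction: float = 0.2
    n_folds: int = 10
    percentiles: tuple = (1.0, 99.0)
    mask_threshold: float = 0.5
    synth: PhantomConfig = field(default_factory=PhantomConfig)
    seg: SegConfig = field(default_factory=SegConfig)
    seg_train: SegTrainConfig = field(default_factory=SegTrainConfig)
    cls: ClsConfig = field(default_factory=ClsConfig)
    cls_train: ClsTrainConfig = field(default_factory=ClsTrainConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        seed = int(d.get("seed", 0))
        return cls(
            seed=seed,
            output_dir=d.get("output_dir", "runs"),
            test_fraction=float(d.get("test_fraction", 0.2)),
            n_folds=int(d.get("n_folds", 10)),
            percentiles=tuple(d.get("percentiles", (1.0, 99.0))),
            mask_threshold=float(d.get("mask_threshold", 0.5)),
            synth=_build(PhantomConfig, d.get("synth", {}),
                         derive_seed(seed, "synth")),
            seg=_build(SegConfig, d.get("seg", {})),
            seg_train=_build(SegTrainConfig, d.get("seg_train", {}),
                             derive_seed(seed, "seg_train")),
            cls=_build(ClsConfig, d.get("cls", {})),
            cls_train=_build(ClsTrainConfig, d.get("cls_train", {}),
                             derive_seed(seed, "cls_train")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "test_fraction": self.test_fraction,
            "n_folds": self.n_folds,
            "percentiles": list(self.percentiles),
            "mask_threshold": self.mask_threshold,
            "synth": dataclasses.asdict(self.synth),
            "seg": dataclasses.asdict(self.seg),
            "seg_train": dataclasses.asdict(self.seg_train),
            "cls": dataclasses.asdict(self.cls),
            "cls_train": dataclasses.asdict(self.cls_train),
        }

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=1)
            else:
                yaml.safe_dump(self.to_dict(), fh)
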