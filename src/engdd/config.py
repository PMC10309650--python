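"""Run configuration: nested dataclasses with YAML (de)serialisation.

Every block mirrors one stage of the pipeline; unknown keys are a hard
error so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cascade_forest import CascadeHyperparams
from .dnn import DnnHyperparams
from .grownet import GrownetHyperparams


@dataclass
class PcaConfig:
    d: int = 100
    standardize: bool = True
    per_fold: bool = True  # refit on training entities inside each CV round


@dataclass
class SamplingConfig:
    ratio: float = 1.0
    seed: int = 0
    resample_negatives: bool = True  # fresh negatives per repetition
    resample_folds: bool = True      # fresh folds per repetition


@dataclass
class CvConfig:
    scheme: str = "pair"  # pair | drug | target
    k: int = 5
    repetitions: int = 20


@dataclass
class EnsembleConfig:
    grid_step: float = 0.1
    val_fraction: float = 0.2
    refit: bool = False          # refit learners on all training pairs
    threshold: float = 0.5
    weights: tuple[float, float, float] | None = None  # fixed, skip tuning


@dataclass
class RunConfig:
    pca: PcaConfig = field(default_factory=PcaConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    grownet: GrownetHyperparams = field(default_factory=GrownetHyperparams)
    dnn: DnnHyperparams = field(default_factory=DnnHyperparams)
    cascade: CascadeHyperparams = field(default_factory=CascadeHyperparams)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        for block, values in (raw or {}).items():
            if not hasattr(cfg, block):
                raise KeyError(f"unknown config block {block!r}")
            sub = getattr(cfg, block)
            names = {f.name for f in dataclasses.fields(sub)}
            for key, val in (values or {}).items():
                if key not in names:
                    raise KeyError(f"unknown config key {block}.{key}")
                if key in ("hidden_dims",) and val is not None:
                    val = tuple(val)
                if key == "weights" and val is not None:
                    val = tuple(float(v) for v in val)
                setattr(sub, key, val)
            sub.__post_init__() if hasattr(sub, "__post_init__") else None
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(listify(dataclasses.asdict(self)), fh,
                           sort_keys=False)
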