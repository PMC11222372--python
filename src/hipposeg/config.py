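"""Run configuration: nested config dataclasses, named ablation presets,
YAML round-tripping with strict key checking, and the cross-validation
split utility."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .losses import LossSpec
from .model import ModelConfig
from .training import TrainConfig


@dataclasses.dataclass
class PreprocessConfig:
    margin: int = 32
    target_shape: tuple[int, int, int] = (267, 182, 174)
    reference: str | None = None   # histogram-matching reference subject id
    modalities: tuple[str, ...] = ("t1w", "t2w")


@dataclasses.dataclass
class PathsConfig:
    images: str | None = None
    labels: str | None = None
    out: str | None = None


@dataclasses.dataclass
class RunConfig:
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    loss: LossSpec = dataclasses.field(default_factory=LossSpec)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    paths: PathsConfig = dataclasses.field(default_factory=PathsConfig)
    preset: str = "dsnet"


#: preset name -> overrides on top of the full default config
_PRESETS: dict[str, dict] = {
    "dsnet": {},
    "dsnet-no-cbam": {"model": {"cbam_enabled": False}},
    "dsnet-no-transformer": {"model": {"transformer_stages": ()}},
    "dsnet-single-branch": {"model": {"dual_branch": False},
                            "loss": {"lambda1": 0.0}},
    "dsnet-t1w": {"model": {"in_channels": 1},
                  "preprocess": {"modalities": ("t1w",)}},
    "dsnet-t2w": {"model": {"in_channels": 1},
                  "preprocess": {"modalities": ("t2w",)}},
    "dsnet-tf-l4": {"model": {"transformer_stages": (4,)}},
    "dsnet-tf-l4l5": {"model": {"transformer_stages": (4, 5)}},
    "dsnet-tiny": {"model": {"base_channels": 4, "token_dim": 32, "n_heads": 2},
                   "train": {"patch_size": (32, 32, 32)}},
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def resolve_preset(name: str) -> RunConfig:
    """A fully explicit RunConfig for a named model variant."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; valid presets: "
                       f"{', '.join(preset_names())}")
    cfg = RunConfig(preset=name)
    for section, overrides in _PRESETS[name].items():
        sub = getattr(cfg, section)
        for key, val in overrides.items():
            setattr(sub, key, val)
    cfg.model.validate()
    return cfg


# ---------------------------------------------------------------- YAML IO

_TUPLE_FIELDS = {"patch_size", "target_shape", "transformer_stages",
                 "modalities", "intensity_shift_range", "scale_range",
                 "grid_shape", "spacing", "organ_axes"}


def _to_dict(obj) -> dict:
    def convert(v):
        if isinstance(v, tuple):
            return list(v)
        return v
    return {f.name: convert(getattr(obj, f.name))
            for f in dataclasses.fields(obj)}


def save_config(cfg: RunConfig, path: str | Path) -> None:
    payload = {
        "preset": cfg.preset,
        "model": _to_dict(cfg.model),
        "train": _to_dict(cfg.train),
        "loss": _to_dict(cfg.loss),
        "preprocess": _to_dict(cfg.preprocess),
        "paths": _to_dict(cfg.paths),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _from_dict(cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    sections = {"model": ModelConfig, "train": TrainConfig, "loss": LossSpec,
                "preprocess": PreprocessConfig, "paths": PathsConfig}
    unknown = set(payload) - set(sections) - {"preset"}
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {name: _from_dict(cls, payload.get(name, {}))
              for name, cls in sections.items()}
    return RunConfig(preset=payload.get("preset", "dsnet"), **kwargs)


# ---------------------------------------------------------------- CV splits

def split_folds(subject_ids: Sequence[str], k: int, seed: int = 0,
                ) -> list[tuple[list[str], list[str], list[str]]]:
    """k-fold split into (train, val, test) id lists.

    Subjects are shuffled once; the k test folds partition the cohort
    (remainders spread deterministically over the first folds). The
    validation set of fold i is the test fold of (i+1) mod k; training is
    everything else. With 25 subjects and k=5 this yields 15/5/5.
    """
    ids = list(subject_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds cohort size {len(ids)}")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = [order[i::k] for i in range(k)]
    out = []
    for i in range(k):
        test = folds[i]
        val = folds[(i + 1) % k]
        train = [s for s in order if s not in test and s not in val]
        out.append((train, val, test))
    return out
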