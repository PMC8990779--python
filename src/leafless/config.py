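"""YAML run configuration.

A single YAML file can carry the settings of a whole run, grouped under
``scene``, ``filters``, ``training`` and ``dataset`` keys, each mapping
onto the corresponding dataclass / keyword arguments::

    scene:    {height: 64, width: 64, berry_radius: [6, 9]}
    filters:  {min_area: 25, min_axis_ratio: 0.3}
    training: {epochs: 30, lambda_l1: 100, channels: GB, seed: 1}
    dataset:  {n_train_leaves: 18, n_test_leaves: 6,
               train_multiplicity: 9, test_multiplicity: 3}

Unknown keys raise rather than being silently dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .counting import FilterConfig
from .occlusion import ToySceneSpec
from .pix2pix import TrainConfig

_DATASET_KEYS = {
    "n_train_leaves", "n_test_leaves", "train_multiplicity",
    "test_multiplicity", "train_fraction", "admissibility_threshold",
    "literal_admissibility", "edge_closure_width", "min_on_patch_fraction",
    "seed",
}


@dataclass(frozen=True)
class RunConfig:
    scene: ToySceneSpec = field(default_factory=ToySceneSpec)
    filters: FilterConfig = field(default_factory=FilterConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    dataset: dict = field(default_factory=dict)


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
    # YAML lists map onto the tuple-valued range fields
    coerced = {k: tuple(v) if isinstance(v, list) else v
               for k, v in section.items()}
    return cls(**coerced)


def load_run_config(path) -> RunConfig:
    """Parse a YAML run configuration file into typed config objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run configuration must be a YAML mapping")
    unknown = set(raw) - {"scene", "filters", "training", "dataset"}
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    dataset = dict(raw.get("dataset") or {})
    bad = set(dataset) - _DATASET_KEYS
    if bad:
        raise ValueError(f"unknown dataset keys: {sorted(bad)}")
    return RunConfig(
        scene=_build(ToySceneSpec, raw.get("scene") or {}, "scene"),
        filters=_build(FilterConfig, raw.get("filters") or {}, "filters"),
        training=_build(TrainConfig, raw.get("training") or {}, "training"),
        dataset=dataset,
    )
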