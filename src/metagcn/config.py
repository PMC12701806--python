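"""YAML configuration loading for the CLI.

One file may describe any subset of the stages::

    cohort:    {n_regions: 90, class_counts: [30, 92, 243], ...}
    se:        {r: 16}
    ae:        {hidden: 128, latent: 64, epochs: 120, lr: 0.001}
    task:      {k_train_s: 3, k_train_q: 5, k_test_s: 3, t: 10, M: 200}
    adjacency: {beta1: 0.8, beta2: 0.6667, rule: mean_ge}
    meta:      {alpha1: 0.01, alpha2: 0.003, dropout: 0.5, ...}
    ablation:  {no_se: false, no_ae: false, no_meta: false, no_ni: false}
    folds: 5
    repeats: 1
    seed: 0

Unknown keys fail loudly rather than being silently ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .evaluate import RunConfig
from .features import SEAEConfig
from .gcn import MetaConfig
from .model import AblationFlags, AdjacencyConfig
from .tasks import TaskSamplingConfig


def _build(cls, mapping: dict, section: str, **extra):
    mapping = dict(mapping or {})
    mapping.update(extra)
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"valid keys: {sorted(valid)}"
        )
    return cls(**mapping)


def load_yaml(path: str | Path | None) -> dict:
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    return data


def cohort_config(data: dict, seed: int | None = None) -> CohortConfig:
    section = dict(data.get("cohort") or {})
    if "class_counts" in section:
        section["class_counts"] = tuple(section["class_counts"])
    if "class_labels" in section and section["class_labels"] is not None:
        section["class_labels"] = tuple(section["class_labels"])
    if seed is not None:
        section["seed"] = seed
    return _build(CohortConfig, section, "cohort")


def feature_config(data: dict) -> SEAEConfig:
    merged = dict(data.get("ae") or {})
    se = dict(data.get("se") or {})
    if "r" in se:
        merged["r"] = se.pop("r")
    if "frozen_stats" in se:  # accepted alias; z is always frozen from training
        se.pop("frozen_stats")
    if se:
        raise ValueError(f"unknown key(s) {sorted(se)} in config section 'se'")
    return _build(SEAEConfig, merged, "ae")


def run_config(data: dict, n_classes: int, seed: int | None = None) -> RunConfig:
    task = dict(data.get("task") or {})
    task.setdefault("C", n_classes)
    top = {k: data[k] for k in ("folds", "repeats", "seed") if k in data}
    if seed is not None:
        top["seed"] = seed
    return _build(
        RunConfig,
        top,
        "run",
        feature_cfg=feature_config(data),
        task_cfg=_build(TaskSamplingConfig, task, "task"),
        meta_cfg=_build(MetaConfig, data.get("meta") or {}, "meta"),
        adj_cfg=_build(AdjacencyConfig, data.get("adjacency") or {}, "adjacency"),
        ablation=_build(AblationFlags, data.get("ablation") or {}, "ablation"),
    )
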