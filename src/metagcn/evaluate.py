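"""Cross-validation, ablation and graph-size-sweep harnesses.

The headline protocol is stratified 5-fold cross-validation: per fold the
SE-AE block and the meta-learned GCN are trained on the training split only
and the held-out split is predicted through meta-testing tasks.  Repeats
rerun the whole procedure with seeds seed, seed+1, ... and all fold results
are aggregated as mean +/- sd per metric.  Reports are plain dicts that
serialise to stable JSON (sorted keys, no timestamps), so a repeated run with
the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort
from .features import SEAEConfig
from .gcn import MetaConfig
from .metrics import compute_metrics
from .model import AblationFlags, AdjacencyConfig, MetaGCNModel
from .tasks import TaskSamplingConfig

METRICS = ("acc", "sen", "spe", "auc", "f1")


@dataclass(frozen=True)
class RunConfig:
    """Composite configuration of a full evaluation run."""

    feature_cfg: SEAEConfig = SEAEConfig()
    task_cfg: TaskSamplingConfig | None = None
    meta_cfg: MetaConfig = MetaConfig()
    adj_cfg: AdjacencyConfig = AdjacencyConfig()
    ablation: AblationFlags = AblationFlags()
    folds: int = 5
    repeats: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _config_echo(cfg: RunConfig) -> dict:
    def as_dict(obj):
        return None if obj is None else dataclasses.asdict(obj)

    return {
        "feature_cfg": as_dict(cfg.feature_cfg),
        "task_cfg": as_dict(cfg.task_cfg),
        "meta_cfg": as_dict(cfg.meta_cfg),
        "adj_cfg": as_dict(cfg.adj_cfg),
        "ablation": as_dict(cfg.ablation),
        "folds": cfg.folds,
        "repeats": cfg.repeats,
        "seed": cfg.seed,
    }


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialisation of an evaluation report."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"


def cross_validate(cohort: Cohort, run_cfg: RunConfig = RunConfig()) -> dict:
    """Stratified k-fold cross-validation of the full pipeline.

    Returns a report dict: per-fold metrics, mean/std aggregates, summed
    confusion matrix, pooled per-class recall, and a config echo sufficient
    to reproduce the run bit for bit.
    """
    run_cfg.validate()
    y = cohort.labels()
    n_classes = len(cohort.class_labels)
    counts = np.bincount(y[y >= 0], minlength=n_classes)
    if counts.min() < run_cfg.folds:
        small = int(np.argmin(counts))
        raise ValueError(
            f"class {cohort.class_labels[small]} has {counts.min()} subjects, "
            f"fewer than folds={run_cfg.folds}; reduce the fold count"
        )
    labelled = np.flatnonzero(y >= 0)

    per_fold = []
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    all_true, all_pred, all_scores = [], [], []
    for rep in range(run_cfg.repeats):
        rep_seed = run_cfg.seed + rep
        skf = StratifiedKFold(
            n_splits=run_cfg.folds, shuffle=True, random_state=rep_seed
        )
        for fold, (tr, te) in enumerate(skf.split(labelled, y[labelled])):
            train_idx, test_idx = labelled[tr], labelled[te]
            model = MetaGCNModel.from_cohort(
                cohort,
                feature_cfg=run_cfg.feature_cfg,
                task_cfg=run_cfg.task_cfg,
                meta_cfg=run_cfg.meta_cfg,
                adj_cfg=run_cfg.adj_cfg,
                ablation=run_cfg.ablation,
            )
            res = model.fit(train_idx, seed=rep_seed * 1009 + fold)
            y_pred, scores = res.predict(test_idx)
            m = compute_metrics(y[test_idx], y_pred, scores, n_classes)
            confusion += np.array(m["confusion"])
            all_true.append(y[test_idx])
            all_pred.append(y_pred)
            all_scores.append(scores)
            per_fold.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    **{k: m[k] for k in METRICS},
                    "per_class_recall": m["per_class_recall"],
                }
            )

    pooled = compute_metrics(
        np.concatenate(all_true),
        np.concatenate(all_pred),
        np.concatenate(all_scores),
        n_classes,
    )
    report = {
        "class_labels": list(cohort.class_labels),
        "n_subjects": int(labelled.size),
        "per_fold": per_fold,
        "mean": {k: float(np.nanmean([f[k] for f in per_fold])) for k in METRICS},
        "std": {k: float(np.nanstd([f[k] for f in per_fold])) for k in METRICS},
        "max": {k: float(np.nanmax([f[k] for f in per_fold])) for k in METRICS},
        "min": {k: float(np.nanmin([f[k] for f in per_fold])) for k in METRICS},
        "confusion": confusion.tolist(),
        "pooled": {k: pooled[k] for k in METRICS},
        "pooled_per_class_recall": pooled["per_class_recall"],
        "n_predictions": int(sum(len(t) for t in all_true)),
        "config": _config_echo(run_cfg),
    }
    return report


ABLATION_VARIANTS = {
    "full": AblationFlags(),
    "-SE": AblationFlags(no_se=True),
    "-AE": AblationFlags(no_ae=True),
    "-Meta": AblationFlags(no_meta=True),
    "-NI": AblationFlags(no_ni=True),
    "-SE-AE": AblationFlags(no_se=True, no_ae=True),
}


def run_ablation(
    cohort: Cohort,
    run_cfg: RunConfig = RunConfig(),
    variants: Iterable[str] = tuple(ABLATION_VARIANTS),
) -> dict:
    """Cross-validate the full model and each component-removed variant.

    The full model is always included.  Returns {variant: report}.
    """
    names = list(variants)
    if "full" not in names:
        names.insert(0, "full")
    out = {}
    for name in names:
        if name not in ABLATION_VARIANTS:
            raise ValueError(
                f"unknown ablation {name!r}; choose from {sorted(ABLATION_VARIANTS)}"
            )
        cfg = dataclasses.replace(run_cfg, ablation=ABLATION_VARIANTS[name])
        out[name] = cross_validate(cohort, cfg)
    return out


def sweep_graph_size(
    cohort: Cohort,
    run_cfg: RunConfig,
    grid: Iterable[tuple[int, int]],
) -> dict:
    """Cross-validate over a grid of (k_train_s, k_train_q) task sizes.

    Every cell shares the run seed, so the sweep isolates the effect of the
    task-graph size.  Returns {"ks,kq": report}.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid is empty")
    base_task = run_cfg.task_cfg or TaskSamplingConfig(C=len(cohort.class_labels))
    out = {}
    for ks, kq in grid:
        cfg = dataclasses.replace(
            run_cfg,
            task_cfg=dataclasses.replace(base_task, k_train_s=ks, k_train_q=kq),
        )
        out[f"{ks},{kq}"] = cross_validate(cohort, cfg)
    return out
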