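"""Episodic task sampling and phenotype-similarity adjacency.

A meta-task is a small graph of subjects: a label-balanced *support* set used
for within-task adaptation, a *query* set used for evaluation or prediction,
and a binary adjacency built from the three non-image features (age, sex,
APOE4 count).  Two subjects are similar on feature u when

    1 - |s_i^u - s_j^u| / range_u  >=  beta1,

with range_u the max-min spread of feature u over the training subjects, and
an edge is drawn when the mean of the three per-feature indicators reaches
beta2 (so the default beta2 = 2/3 requires similarity on at least two of the
three features).  The diagonal is always zero.

Training tasks draw both support and query from the training split with
exactly k subjects per class each, which is how severe label imbalance is
neutralised at the task level.  Test tasks draw a balanced support from the
training split while their query sets partition the test split, so every
held-out subject is predicted exactly once and a single new subject can be
scored on its own (query size t = 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskSamplingConfig:
    """Sampling sizes for meta-training and meta-testing tasks.

    k_train_s / k_train_q: per-class support/query sizes of training tasks
    (the best-performing published configuration is 3 / 5); k_test_s: per-class
    support size at test; t: query size per test task; M: number of
    meta-training tasks in the pool.
    """

    C: int
    k_train_s: int = 3
    k_train_q: int = 5
    k_test_s: int = 3
    t: int = 10
    M: int = 200
    seed: int = 0

    def validate(self) -> None:
        for name in ("C", "k_train_s", "k_train_q", "k_test_s", "t", "M"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.C < 2:
            raise ValueError("need C >= 2 classes")


@dataclass
class MetaTask:
    """One small graph: ordered node ids (support block first), masks, labels
    (-1 where unknown), binary adjacency A and node features X."""

    node_ids: np.ndarray
    support_mask: np.ndarray
    query_mask: np.ndarray
    labels: np.ndarray
    A: np.ndarray
    X: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_ids.shape[0]


def _class_indices(labels: np.ndarray, C: int) -> list[np.ndarray]:
    out = []
    for c in range(C):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            raise ValueError(f"class {c} is absent from the provided labels")
        out.append(idx)
    return out


def _sample_balanced(
    by_class: list[np.ndarray], k_s: int, k_q: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    sup, qry = [], []
    for c, members in enumerate(by_class):
        need = k_s + k_q
        if members.size >= need:
            picked = rng.choice(members, size=need, replace=False)
        else:
            logger.warning(
                "class %d has %d members < k_s+k_q=%d; sampling with replacement",
                c,
                members.size,
                need,
            )
            picked = rng.choice(members, size=need, replace=True)
        sup.append(picked[:k_s])
        qry.append(picked[k_s:])
    return np.concatenate(sup), np.concatenate(qry)


def sample_train_tasks(
    labels: np.ndarray, cfg: TaskSamplingConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample M label-balanced (support_ids, query_ids) pairs.

    Each task holds exactly k_train_s support and k_train_q query subjects per
    class; across tasks subjects may repeat freely (resampling is what makes a
    small cohort yield many tasks).
    """
    cfg.validate()
    labels = np.asarray(labels)
    by_class = _class_indices(labels, cfg.C)
    rng = np.random.default_rng(cfg.seed)
    return [
        _sample_balanced(by_class, cfg.k_train_s, cfg.k_train_q, rng)
        for _ in range(cfg.M)
    ]


def sample_test_tasks(
    train_labels: np.ndarray,
    test_ids: np.ndarray,
    cfg: TaskSamplingConfig,
    train_ids: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build P = ceil(|test|/t) tasks whose query sets partition test_ids.

    Supports are label-balanced draws from the training split; ``train_ids``
    maps positions in ``train_labels`` to global subject indices (identity by
    default).  The last task's query may be smaller than t.
    """
    cfg.validate()
    train_labels = np.asarray(train_labels)
    test_ids = np.asarray(test_ids)
    if test_ids.size == 0:
        raise ValueError("test_ids is empty")
    if train_ids is None:
        train_ids = np.arange(train_labels.shape[0])
    by_class = _class_indices(train_labels, cfg.C)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(test_ids)
    P = math.ceil(test_ids.size / cfg.t)
    tasks = []
    for p in range(P):
        query = order[p * cfg.t : (p + 1) * cfg.t]
        sup = []
        for members in by_class:
            replace = members.size < cfg.k_test_s
            sup.append(rng.choice(members, size=cfg.k_test_s, replace=replace))
        support = train_ids[np.concatenate(sup)]
        tasks.append((support, query))
    return tasks


def pairwise_feature_indicator(
    si_u: float, sj_u: float, range_u: float, beta1: float
) -> int:
    """Per-feature similarity indicator: 1 iff 1 - |si-sj|/range >= beta1.

    A zero range (feature constant over the cohort) makes every pair
    identical on that feature; the indicator is then 1 by convention.
    """
    if range_u == 0:
        return 1
    return int(1.0 - abs(si_u - sj_u) / range_u >= beta1)


def feature_ranges(phenotypes: np.ndarray) -> np.ndarray:
    """max - min per non-image feature column ("extreme value"), to be
    computed on the training split and frozen."""
    phenotypes = np.asarray(phenotypes, dtype=float)
    return phenotypes.max(axis=0) - phenotypes.min(axis=0)


def build_adjacency(
    phenotypes: np.ndarray,
    beta1: float,
    beta2: float,
    ranges: np.ndarray,
    rule: str = "mean_ge",
) -> np.ndarray:
    """Binary phenotype-similarity adjacency over a set of subjects.

    ``phenotypes`` is (n, 3): age, sex, apoe4 per row.  ``rule="mean_ge"``
    draws an edge when the mean of the three indicators >= beta2;
    ``"sum_ge"`` uses sum >= 3*beta2 (identical edge set, kept as an explicit
    alternative reading).  Output is symmetric, hollow, {0,1}-valued.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    if phenotypes.ndim != 2 or phenotypes.shape[1] != 3:
        raise ValueError(f"phenotypes must be (n, 3), got {phenotypes.shape}")
    if np.isnan(phenotypes).any():
        i, u = np.argwhere(np.isnan(phenotypes))[0]
        raise ValueError(f"subject {i} is missing non-image feature {u}")
    ranges = np.asarray(ranges, dtype=float)
    if ranges.shape != (3,):
        raise ValueError("ranges must have one entry per non-image feature")
    n = phenotypes.shape[0]
    score = np.zeros((n, n))
    for u in range(3):
        col = phenotypes[:, u]
        dist = np.abs(col[:, None] - col[None, :])
        if ranges[u] == 0:
            ind = np.ones((n, n))
        else:
            ind = (1.0 - dist / ranges[u] >= beta1).astype(float)
        score += ind
    if rule == "mean_ge":
        A = (score / 3.0 >= beta2).astype(float)
    elif rule == "sum_ge":
        A = (score >= 3.0 * beta2).astype(float)
    else:
        raise ValueError(f"unknown adjacency rule {rule!r}")
    np.fill_diagonal(A, 0.0)
    return A


def build_task(
    support_ids: np.ndarray,
    query_ids: np.ndarray,
    X_all: np.ndarray,
    labels_all: np.ndarray,
    phenotypes_all: np.ndarray,
    beta1: float,
    beta2: float,
    ranges: np.ndarray,
    rule: str = "mean_ge",
    query_labels_known: bool = True,
) -> MetaTask:
    """Assemble a MetaTask graph from global subject indices.

    Nodes are ordered support block first then query block, each block sorted
    by subject index so masks and adjacency are reproducible.  Query labels
    are hidden (-1) when ``query_labels_known`` is False (meta-testing).
    """
    support_ids = np.sort(np.asarray(support_ids))
    query_ids = np.sort(np.asarray(query_ids))
    node_ids = np.concatenate([support_ids, query_ids])
    n = node_ids.size
    support_mask = np.zeros(n, dtype=bool)
    support_mask[: support_ids.size] = True
    query_mask = ~support_mask
    labels = np.asarray(labels_all)[node_ids].copy()
    if not query_labels_known:
        labels[query_mask] = -1
    A = build_adjacency(
        np.asarray(phenotypes_all)[node_ids], beta1, beta2, ranges, rule=rule
    )
    return MetaTask(
        node_ids=node_ids,
        support_mask=support_mask,
        query_mask=query_mask,
        labels=labels,
        A=A,
        X=np.asarray(X_all)[node_ids],
    )
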