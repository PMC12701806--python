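"""Model/Results interface over the full pipeline.

:class:`MetaGCNModel` holds one cohort's data (connectivity features, labels,
phenotypes) together with the feature-processing, task-sampling and
meta-learning configurations; :meth:`MetaGCNModel.fit` trains the SE-AE block
and meta-trains the GCN on a chosen subject subset and returns a
:class:`MetaGCNResults` carrying the learned parameters, the training log and
``predict`` / ``summary`` methods.  Ablation switches (``no_se``, ``no_ae``,
``no_meta``, ``no_ni``) remove one component each while keeping the rest of
the pipeline identical, which is how component contributions are measured.

Typical use::

    cohort = generate_cohort(CohortConfig(seed=7))
    model = MetaGCNModel.from_cohort(cohort)
    res = model.fit(train_idx)
    pred, scores = res.predict(test_idx)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import gcn, tasks
from .cohort import Cohort
from .features import SEAEConfig, SEParams, AEParams, encode, fit_se_ae
from .gcn import MetaConfig
from .tasks import TaskSamplingConfig


@dataclass(frozen=True)
class AdjacencyConfig:
    """Thresholds of the phenotype-similarity graph.

    beta1 gates per-feature similarity, beta2 the aggregated indicator mean.
    The defaults (0.9, 1.0) draw an edge only between subjects similar on all
    three of age (within 10% of the training-cohort age range), sex and APOE4
    dose — a sparse, high-precision graph, which is what the neighbourhood-
    averaging GCN assumes (edges between demographically near-identical
    subjects are the ones most likely to join same-condition subjects).
    beta2 = 2/3 (any two of three features) gives a denser graph that carries
    more relational signal when node features are weak, at the price of more
    cross-condition edges.
    """

    beta1: float = 0.9
    beta2: float = 1.0
    rule: str = "mean_ge"


@dataclass(frozen=True)
class AblationFlags:
    no_se: bool = False
    no_ae: bool = False
    no_meta: bool = False
    no_ni: bool = False

    def tag(self) -> str:
        parts = [
            name.replace("no_", "-").upper().replace("-NO", "")
            for name, on in (
                ("no_se", self.no_se),
                ("no_ae", self.no_ae),
                ("no_meta", self.no_meta),
                ("no_ni", self.no_ni),
            )
            if on
        ]
        return "".join(parts) if parts else "full"


class MetaGCNModel:
    """Few-shot GCN disease classifier over a functional-connectivity cohort.

    Parameters
    ----------
    X : (N, d) array
        Raw flattened connectivity features.
    y : (N,) int array
        Class labels, -1 where unknown.
    phenotypes : (N, 3) array
        age, sex, apoe4 per subject (graph-edge features).
    feature_cfg, task_cfg, meta_cfg, adj_cfg
        Stage configurations; sensible defaults throughout.
    ablation
        Component switches; all off reproduces the full pipeline.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        phenotypes: np.ndarray,
        n_classes: int | None = None,
        feature_cfg: SEAEConfig = SEAEConfig(),
        task_cfg: TaskSamplingConfig | None = None,
        meta_cfg: MetaConfig = MetaConfig(),
        adj_cfg: AdjacencyConfig = AdjacencyConfig(),
        ablation: AblationFlags = AblationFlags(),
        class_names: tuple[str, ...] | None = None,
        pretrained: tuple[SEParams, AEParams] | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.phenotypes = np.asarray(phenotypes, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on subject count")
        if self.phenotypes.shape != (self.X.shape[0], 3):
            raise ValueError("phenotypes must be (N, 3): age, sex, apoe4")
        if n_classes is None:
            n_classes = int(self.y[self.y >= 0].max()) + 1
        self.n_classes = n_classes
        self.feature_cfg = feature_cfg
        self.task_cfg = task_cfg or TaskSamplingConfig(C=n_classes)
        if self.task_cfg.C != n_classes:
            raise ValueError("task_cfg.C disagrees with the number of classes")
        self.meta_cfg = meta_cfg
        self.adj_cfg = adj_cfg
        self.ablation = ablation
        self.class_names = class_names or tuple(f"class{c}" for c in range(n_classes))
        self.pretrained = pretrained

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "MetaGCNModel":
        return cls(
            cohort.feature_matrix(),
            cohort.labels(),
            cohort.phenotypes(),
            n_classes=len(cohort.class_labels),
            class_names=tuple(cohort.class_labels),
            **kwargs,
        )

    # ------------------------------------------------------------------
    def fit(self, train_idx: np.ndarray | None = None, seed: int | None = None):
        """Train on ``train_idx`` (all labelled subjects by default).

        Runs, in order: SE-AE feature fit on the training subjects (with a
        held-out validation slice for snapshot selection), encoding of the
        whole cohort with the frozen parameters, task sampling, and
        meta-training (or a single plain-GCN fit under ``no_meta``).
        """
        if train_idx is None:
            train_idx = np.flatnonzero(self.y >= 0)
        train_idx = np.asarray(train_idx)
        y_train = self.y[train_idx]
        if np.any(y_train < 0):
            raise ValueError("training subjects must be labelled")
        for c in range(self.n_classes):
            if not np.any(y_train == c):
                raise ValueError(f"class {c} missing from the training subjects")
        seed = self.meta_cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)

        # --- feature processing -------------------------------------------------
        se_params = ae_params = None
        fit_log: dict = {}
        if self.ablation.no_ae:
            feats = self.X
        elif self.pretrained is not None:
            se_params, ae_params = self.pretrained
            feats = encode(
                self.X, se_params, ae_params, se_enabled=not self.ablation.no_se
            )
        else:
            fcfg = replace(
                self.feature_cfg,
                seed=int(rng.integers(2**31)),
                se_enabled=not self.ablation.no_se,
            )
            val_n = max(1, train_idx.size // 10)
            perm = rng.permutation(train_idx.size)
            val_sel = train_idx[perm[:val_n]]
            tr_sel = train_idx[perm[val_n:]]
            se_params, ae_params, fit_log = fit_se_ae(
                self.X[tr_sel], self.X[val_sel], fcfg
            )
            feats = encode(self.X, se_params, ae_params, se_enabled=fcfg.se_enabled)

        # --- graph ingredients --------------------------------------------------
        ranges = tasks.feature_ranges(self.phenotypes[train_idx])

        task_cfg = replace(self.task_cfg, seed=int(rng.integers(2**31)))
        meta_cfg = replace(self.meta_cfg, seed=int(rng.integers(2**31)))

        if self.ablation.no_meta:
            theta, log = self._fit_plain_gcn(feats, train_idx, meta_cfg)
        else:
            pairs = tasks.sample_train_tasks(y_train, task_cfg)
            pool = [
                self._build_task(
                    train_idx[s], train_idx[q], feats, known=True, ranges=ranges
                )
                for s, q in pairs
            ]
            theta, log = gcn.meta_train(pool, meta_cfg, self.n_classes)

        return MetaGCNResults(
            model=self,
            theta=theta,
            se_params=se_params,
            ae_params=ae_params,
            features=feats,
            ranges=ranges,
            train_idx=train_idx,
            task_cfg=task_cfg,
            meta_cfg=meta_cfg,
            feature_log=fit_log,
            train_log=log,
            seed=seed,
        )

    # ------------------------------------------------------------------
    def _build_task(self, support_ids, query_ids, feats, known, ranges=None):
        if ranges is None:
            ranges = tasks.feature_ranges(self.phenotypes[support_ids])
        task = tasks.build_task(
            support_ids,
            query_ids,
            feats,
            self.y,
            self.phenotypes,
            self.adj_cfg.beta1,
            self.adj_cfg.beta2,
            ranges,
            rule=self.adj_cfg.rule,
            query_labels_known=known,
        )
        if self.ablation.no_ni:
            task.A = np.zeros_like(task.A)  # normalised adjacency becomes I
        return task

    def _fit_plain_gcn(self, feats, train_idx, meta_cfg):
        """Non-episodic baseline: one graph over the training subjects, plain
        gradient descent on the training cross-entropy."""
        ranges = tasks.feature_ranges(self.phenotypes[train_idx])
        A = tasks.build_adjacency(
            self.phenotypes[train_idx],
            self.adj_cfg.beta1,
            self.adj_cfg.beta2,
            ranges,
            rule=self.adj_cfg.rule,
        )
        if self.ablation.no_ni:
            A = np.zeros_like(A)
        A_hat = gcn.normalize_adjacency(A)
        Xg = feats[train_idx]
        labels = self.y[train_idx]
        mask = np.ones(train_idx.size, dtype=bool)
        rng = np.random.default_rng(meta_cfg.seed)
        drop_rng = np.random.default_rng(rng.integers(2**31))
        theta = gcn.init_gcn_params(feats.shape[1], meta_cfg.hidden, self.n_classes, rng)
        log = []
        p = meta_cfg.dropout
        for it in range(meta_cfg.iterations):
            masks = (
                gcn._dropout_masks(
                    drop_rng, train_idx.size, feats.shape[1], meta_cfg.hidden, p
                )
                if p > 0
                else None
            )
            loss, g, logits = gcn.loss_and_grad(
                theta, Xg, A_hat, labels, mask, p, masks
            )
            theta = [t - meta_cfg.alpha1 * gg for t, gg in zip(theta, g)]
            acc = float(np.mean(logits.argmax(axis=1) == labels))
            log.append({"iteration": it, "query_loss": float(loss), "query_acc": acc})
        return theta, log


@dataclass
class MetaGCNResults:
    """Fitted parameters + everything needed to predict and report."""

    model: MetaGCNModel
    theta: list[np.ndarray]
    se_params: SEParams | None
    ae_params: AEParams | None
    features: np.ndarray
    ranges: np.ndarray
    train_idx: np.ndarray
    task_cfg: TaskSamplingConfig
    meta_cfg: MetaConfig
    feature_log: dict
    train_log: list
    seed: int

    def predict(self, test_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predict labels and class probabilities for held-out subjects.

        Builds meta-testing tasks whose query sets partition ``test_idx``
        (balanced supports drawn from the training subjects), fine-tunes a
        copy of theta per task and reads off the query predictions.  Under
        ``no_meta`` the plain GCN is re-run on one graph containing training
        and test subjects.
        """
        test_idx = np.asarray(test_idx)
        if self.model.ablation.no_meta:
            return self._predict_plain(test_idx)
        y_train = self.model.y[self.train_idx]
        pairs = tasks.sample_test_tasks(
            y_train, test_idx, self.task_cfg, train_ids=self.train_idx
        )
        built = [
            self.model._build_task(s, q, self.features, known=False, ranges=self.ranges)
            for s, q in pairs
        ]
        preds = gcn.meta_test(self.theta, built, self.meta_cfg)
        labels = np.array([preds[int(i)][0] for i in test_idx])
        scores = np.stack([preds[int(i)][1] for i in test_idx])
        return labels, scores

    def _predict_plain(self, test_idx):
        nodes = np.concatenate([self.train_idx, test_idx])
        A = tasks.build_adjacency(
            self.model.phenotypes[nodes],
            self.model.adj_cfg.beta1,
            self.model.adj_cfg.beta2,
            self.ranges,
            rule=self.model.adj_cfg.rule,
        )
        if self.model.ablation.no_ni:
            A = np.zeros_like(A)
        A_hat = gcn.normalize_adjacency(A)
        logits = gcn.gcn_forward(self.features[nodes], A_hat, self.theta)
        q = slice(self.train_idx.size, None)
        probs = gcn.softmax(logits[q])
        return logits[q].argmax(axis=1), probs

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        m = self.model
        lines = [
            "Meta-GCN few-shot connectivity classifier",
            "=" * 57,
            f"variant:            {m.ablation.tag()}",
            f"subjects (train):   {self.train_idx.size} of {m.X.shape[0]}",
            f"classes:            {m.n_classes} {list(m.class_names)}",
            f"raw feature width:  {m.X.shape[1]}",
            f"GCN input width:    {self.features.shape[1]}",
            f"GCN hidden width:   {self.meta_cfg.hidden}",
            f"inner lr alpha1:    {self.meta_cfg.alpha1}",
            f"meta lr alpha2:     {self.meta_cfg.alpha2}",
            f"dropout:            {self.meta_cfg.dropout}",
            f"second-order MAML:  {self.meta_cfg.second_order and not m.ablation.no_meta}",
            f"seed:               {self.seed}",
        ]
        if self.feature_log:
            lines.append(
                "SE-AE val MSE:      "
                f"{self.feature_log['best_val_mse']:.5f} "
                f"(untrained {self.feature_log['init_val_mse']:.5f}, "
                f"epoch {self.feature_log['best_epoch']})"
            )
        if self.train_log:
            last = self.train_log[-1]
            lines.append(
                f"final train state:  query loss {last['query_loss']:.4f}, "
                f"query acc {last['query_acc']:.3f} "
                f"(iteration {last['iteration'] + 1})"
            )
        return "\n".join(lines)
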