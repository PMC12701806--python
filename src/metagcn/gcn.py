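"""Two-layer GCN with MAML-style meta-training, in plain NumPy.

The backbone is the standard spectral GCN layer

    X^(l+1) = delta( D~^{-1/2} (A + I) D~^{-1/2} X^(l) theta^(l) ),

two layers deep (ReLU after the first, raw logits after the second), with
inverted dropout on layer inputs during training.  The loss is cross-entropy
averaged over a boolean node mask, so support and query nodes share one graph
but never share a loss (transductive masking).

Meta-learning follows MAML: per task, inner gradient steps on the support
loss produce adapted parameters theta' = theta - alpha1 * grad; the meta
update descends the summed query losses at theta' with rate alpha2.  With
``second_order=True`` (the default) the meta-gradient includes the curvature
term, computed by propagating the query gradient backwards through each inner
step as v <- v - alpha1 * H(theta_j) v.  The Hessian-vector products use
complex-step differentiation of the hand-coded gradient function
(Im grad(theta + i*eps*v) / eps), which is exact to machine precision and
free of finite-difference cancellation; ReLU/dropout gates and the softmax
shift read only the real part, so the products match the almost-everywhere
Hessian of the piecewise-analytic loss.

All functions are pure: parameters in, new parameters out; every source of
randomness is an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tasks import MetaTask

logger = logging.getLogger(__name__)

_HVP_EPS = 1e-60


@dataclass(frozen=True)
class MetaConfig:
    """Meta-learning hyperparameters.

    alpha1 is the task-level (inner) learning rate, alpha2 the meta rate;
    dropout is applied at GCN layer inputs during training only.  Defaults
    alpha1=0.01, alpha2=0.003, dropout=0.5 follow the published settings;
    hidden width, batch size and iteration count are desk-scale choices.
    """

    alpha1: float = 0.01
    alpha2: float = 0.003
    inner_steps: int = 1
    finetune_steps: int = 5
    task_batch: int = 4
    iterations: int = 500
    dropout: float = 0.5
    hidden: int = 16
    second_order: bool = True
    meta_optimizer: str = "adam"  # "adam" or "sgd" (plain meta descent)
    seed: int = 0

    def validate(self) -> None:
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("learning rates must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.inner_steps < 1:
            raise ValueError("inner_steps must be >= 1")
        if self.finetune_steps < 0:
            raise ValueError("finetune_steps must be >= 0")
        if self.meta_optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown meta_optimizer {self.meta_optimizer!r}")


def init_gcn_params(
    d_in: int, hidden: int, n_classes: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Variance-scaled (Glorot) initialisation of the two layer matrices."""

    def glorot(n_in, n_out):
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    return [glorot(d_in, hidden), glorot(hidden, n_classes)]


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric renormalisation D~^{-1/2} (A + I) D~^{-1/2}.

    The self-loop guarantees every degree is >= 1, so the inverse square root
    is always defined; a zero adjacency maps to the identity.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    At = A + np.eye(A.shape[0])
    dinv = 1.0 / np.sqrt(At.sum(axis=1))
    return At * dinv[:, None] * dinv[None, :]


def _dropout_masks(
    rng: np.random.Generator, n: int, d_in: int, hidden: int, p: float
) -> list[np.ndarray] | None:
    if p <= 0:
        return None
    return [
        (rng.random((n, d_in)) >= p).astype(float),
        (rng.random((n, hidden)) >= p).astype(float),
    ]


def _forward(theta, X, A_hat, p, masks):
    """Forward pass caching intermediates; complex-safe (gates read .real)."""
    H0 = X if masks is None else X * masks[0] / (1.0 - p)
    Z1 = A_hat @ H0 @ theta[0]
    H1 = np.where(Z1.real > 0, Z1, 0.0)
    H1d = H1 if masks is None else H1 * masks[1] / (1.0 - p)
    logits = A_hat @ H1d @ theta[1]
    return logits, (H0, Z1, H1d)


def gcn_forward(
    X: np.ndarray,
    A_hat: np.ndarray,
    theta: list[np.ndarray],
    dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Logits of the two-layer GCN.  Dropout fires only when training."""
    X = np.asarray(X)
    if X.shape[1] != theta[0].shape[0] or theta[0].shape[1] != theta[1].shape[0]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, theta0 {theta[0].shape}, theta1 {theta[1].shape}"
        )
    if A_hat.shape[0] != X.shape[0]:
        raise ValueError("adjacency and feature matrix disagree on node count")
    masks = None
    if training and dropout > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        masks = _dropout_masks(rng, X.shape[0], X.shape[1], theta[0].shape[1], dropout)
    logits, _ = _forward(theta, X, A_hat, dropout, masks)
    return logits


def _log_softmax(logits):
    m = logits.real.max(axis=1, keepdims=True)
    shifted = logits - m
    lse = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return shifted - lse


def masked_ce_loss(
    logits: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> float | complex:
    """Cross-entropy averaged over the masked nodes (log-sum-exp stable)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("mask selects no nodes")
    lab = np.asarray(labels)[idx]
    if np.any(lab < 0):
        raise ValueError("masked nodes must have known labels")
    logp = _log_softmax(np.asarray(logits)[idx])
    picked = logp[np.arange(idx.size), lab]
    loss = -picked.mean()
    return loss if np.iscomplexobj(logits) else float(loss)


def loss_and_grad(theta, X, A_hat, labels, mask, p=0.0, masks=None):
    """Masked CE loss, its gradient w.r.t. both layer matrices, and logits.

    Hand-derived backprop through the two GCN layers; works unchanged on
    complex inputs, which is what the complex-step Hessian products exploit.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("mask selects no nodes")
    logits, (H0, Z1, H1d) = _forward(theta, X, A_hat, p, masks)
    logp = _log_softmax(logits[idx])
    lab = np.asarray(labels)[idx]
    loss = -logp[np.arange(idx.size), lab].mean()
    G = np.zeros_like(logits)
    probs = np.exp(logp)
    probs[np.arange(idx.size), lab] -= 1.0
    G[idx] = probs / idx.size
    AG = A_hat @ G  # A_hat is symmetric
    dtheta1 = H1d.T @ AG
    dH1d = AG @ theta[1].T
    dH1 = dH1d if masks is None else dH1d * masks[1] / (1.0 - p)
    dZ1 = np.where(Z1.real > 0, dH1, 0.0)
    AdZ1 = A_hat @ dZ1
    dtheta0 = H0.T @ AdZ1
    if not np.iscomplexobj(logits):
        loss = float(loss)
    return loss, [dtheta0, dtheta1], logits


def _hvp(theta, v, X, A_hat, labels, mask, p, masks):
    """Hessian-vector product of the masked loss via complex-step on the
    analytic gradient: Im grad(theta + i*eps*v) / eps."""
    thc = [t.astype(complex) + 1j * _HVP_EPS * w for t, w in zip(theta, v)]
    _, g, _ = loss_and_grad(thc, X, A_hat, labels, mask, p, masks)
    return [gg.imag / _HVP_EPS for gg in g]


def inner_update(
    theta: list[np.ndarray],
    task: MetaTask,
    cfg: MetaConfig,
    A_hat: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    training: bool = False,
    steps: int | None = None,
    return_trajectory: bool = False,
):
    """Task-level adaptation theta' = theta - alpha1 * grad, repeated.

    Pure: ``theta`` is never modified.  Dropout is sampled only when
    ``training`` is True (and then requires ``rng``); evaluation-mode calls
    are fully deterministic.  With ``return_trajectory`` the per-step
    (theta_j, masks_j) pairs are also returned so the meta-update can
    backpropagate through the adaptation.
    """
    if not task.support_mask.any():
        raise ValueError("task has an empty support set")
    if np.any(task.labels[task.support_mask] < 0):
        raise ValueError("support nodes must carry labels")
    if A_hat is None:
        A_hat = normalize_adjacency(task.A)
    p = cfg.dropout if training else 0.0
    n_steps = cfg.inner_steps if steps is None else steps
    th = [t.copy() for t in theta]
    traj = []
    for _ in range(n_steps):
        masks = (
            _dropout_masks(rng, task.n_nodes, th[0].shape[0], th[0].shape[1], p)
            if (training and p > 0)
            else None
        )
        _, g, _ = loss_and_grad(
            th, task.X, A_hat, task.labels, task.support_mask, p, masks
        )
        traj.append(([t.copy() for t in th], masks))
        th = [t - cfg.alpha1 * gg for t, gg in zip(th, g)]
    if return_trajectory:
        return th, traj
    return th


def meta_gradient(
    theta: list[np.ndarray],
    tasks: list[MetaTask],
    cfg: MetaConfig,
    A_hats: list[np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Meta-gradient sum_i grad_theta L_query_i(theta'_i) over a task batch.

    With ``cfg.second_order`` the gradient flows through the inner steps
    (reverse accumulation of (I - alpha1 H) factors); otherwise the inner
    adaptation is treated as constant (first-order MAML).  Also returns a
    batch log (mean query loss and accuracy under the adapted parameters).
    """
    if not tasks:
        raise ValueError("task batch is empty")
    cfg.validate()
    training = cfg.dropout > 0 and rng is not None
    if A_hats is None:
        A_hats = [normalize_adjacency(t.A) for t in tasks]
    p = cfg.dropout if training else 0.0
    total = [np.zeros_like(t) for t in theta]
    qlosses, qaccs = [], []
    for task, A_hat in zip(tasks, A_hats):
        if not task.query_mask.any() or np.any(task.labels[task.query_mask] < 0):
            raise ValueError("meta-training tasks need labeled query nodes")
        th_ad, traj = inner_update(
            theta,
            task,
            cfg,
            A_hat=A_hat,
            rng=rng,
            training=training,
            return_trajectory=True,
        )
        qmasks = (
            _dropout_masks(rng, task.n_nodes, theta[0].shape[0], theta[0].shape[1], p)
            if (training and p > 0)
            else None
        )
        qloss, gq, logits = loss_and_grad(
            th_ad, task.X, A_hat, task.labels, task.query_mask, p, qmasks
        )
        v = gq
        if cfg.second_order:
            for th_j, masks_j in reversed(traj):
                hv = _hvp(
                    th_j, v, task.X, A_hat, task.labels, task.support_mask, p, masks_j
                )
                v = [w - cfg.alpha1 * h for w, h in zip(v, hv)]
        total = [a + w for a, w in zip(total, v)]
        qlosses.append(qloss)
        pred = logits[task.query_mask].argmax(axis=1)
        qaccs.append(float(np.mean(pred == task.labels[task.query_mask])))
    return total, {
        "query_loss": float(np.mean(qlosses)),
        "query_acc": float(np.mean(qaccs)),
    }


def meta_update(
    theta: list[np.ndarray],
    tasks: list[MetaTask],
    cfg: MetaConfig,
    A_hats: list[np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], dict]:
    """One plain meta-descent step theta <- theta - alpha2 * meta-gradient.

    This is the textbook MAML outer update; :func:`meta_train` wraps it in an
    Adam meta-optimizer by default, which is how MAML is trained in practice.
    Pure: returns fresh parameter arrays.
    """
    g, stats = meta_gradient(theta, tasks, cfg, A_hats=A_hats, rng=rng)
    return [t - cfg.alpha2 * gg for t, gg in zip(theta, g)], stats


def meta_train(
    tasks: list[MetaTask],
    cfg: MetaConfig,
    n_classes: int,
    d_in: int | None = None,
    log_every: int = 50,
) -> tuple[list[np.ndarray], list[dict]]:
    """Full meta-training loop over a pool of pre-built tasks.

    Each iteration samples ``cfg.task_batch`` tasks (with replacement) from
    the pool and applies one meta update.  Seeded and bit-reproducible.
    """
    if not tasks:
        raise ValueError("no meta-training tasks provided")
    cfg.validate()
    if d_in is None:
        d_in = tasks[0].X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    theta = init_gcn_params(d_in, cfg.hidden, n_classes, rng)
    A_hats = [normalize_adjacency(t.A) for t in tasks]
    opt = None
    if cfg.meta_optimizer == "adam":
        from .features import _Adam

        theta = [t.copy() for t in theta]
        opt = _Adam(theta, cfg.alpha2)
    log = []
    for it in range(cfg.iterations):
        pick = rng.integers(0, len(tasks), size=cfg.task_batch)
        batch = [tasks[i] for i in pick]
        batch_A = [A_hats[i] for i in pick]
        if opt is None:
            theta, stats = meta_update(
                theta,
                batch,
                cfg,
                A_hats=batch_A,
                rng=drop_rng if cfg.dropout > 0 else None,
            )
        else:
            g, stats = meta_gradient(
                theta,
                batch,
                cfg,
                A_hats=batch_A,
                rng=drop_rng if cfg.dropout > 0 else None,
            )
            opt.step(theta, g)
        log.append({"iteration": it, **stats})
        if log_every and (it + 1) % log_every == 0:
            logger.info(
                "iter %d: query loss %.4f acc %.3f",
                it + 1,
                stats["query_loss"],
                stats["query_acc"],
            )
    return theta, log


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(_log_softmax(logits))


def meta_test(
    theta: list[np.ndarray],
    test_tasks: list[MetaTask],
    cfg: MetaConfig,
) -> dict[int, tuple[int, np.ndarray]]:
    """Fine-tune a copy of theta per task and predict its query nodes.

    Runs ``cfg.finetune_steps`` support-set gradient steps with dropout off
    (evaluation mode), then assigns argmax-softmax labels to the query nodes.
    Returns {subject index: (predicted class, class probabilities)}; theta is
    never mutated and every test subject appears exactly once provided the
    tasks came from :func:`tasks.sample_test_tasks`.
    """
    cfg.validate()
    out: dict[int, tuple[int, np.ndarray]] = {}
    for task in test_tasks:
        if not task.query_mask.any():
            logger.info("skipping meta-test task with empty query set")
            continue
        A_hat = normalize_adjacency(task.A)
        th = (
            inner_update(theta, task, cfg, A_hat=A_hat, steps=cfg.finetune_steps)
            if cfg.finetune_steps > 0
            else [t.copy() for t in theta]
        )
        logits = gcn_forward(task.X, A_hat, th, training=False)
        probs = softmax(logits)
        for pos in np.flatnonzero(task.query_mask):
            sid = int(task.node_ids[pos])
            if sid in out:
                raise ValueError(f"subject {sid} predicted twice")
            out[sid] = (_argmax_tiebreak(probs[pos], cfg.seed, sid), probs[pos])
    return out


def _argmax_tiebreak(scores: np.ndarray, seed: int, sid: int) -> int:
    """Argmax with exact ties broken at random (seeded per subject).

    A degenerate network (e.g. a fully dead ReLU layer) emits identical
    scores for every class; a plain argmax would then always return class 0,
    silently biasing no-signal predictions toward the lowest class index.
    """
    top = scores.max()
    tied = np.flatnonzero(scores >= top - 1e-12)
    if tied.size == 1:
        return int(tied[0])
    rng = np.random.default_rng((seed % (2**31), sid))
    return int(rng.choice(tied))
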