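"""Squeeze-and-excitation weighting and autoencoder compression of
connectivity features.

The raw feature of a subject is the flattened upper triangle of its
functional-connectivity matrix, x_i in R^d with d = n(n-1)/2.  Before graph
classification the features pass through two stages:

1. An SE (squeeze-and-excitation) block adapted to vectors: a *squeeze* step
   averages the features over subjects into a global vector z (one value per
   connection), an *excitation* step maps z through a bottleneck MLP to a
   weight vector s = sigmoid(W2 relu(W1 z)) in (0,1)^d, and a *rescale* step
   multiplies every subject's features elementwise by s.  One s is shared by
   all subjects.
2. A two-layer autoencoder compresses the rescaled features from d to
   d_hat << d; only the encoder half is kept for downstream use.

Both stages are trained jointly and unsupervised: the pipeline
x -> rescale -> encoder -> decoder -> x_rec minimises the mean squared
reconstruction error against the raw x, and the parameter snapshot with the
lowest validation MSE is returned.  The squeeze vector z is computed from the
training subjects only and frozen, so validation/test subjects never influence
the learned weights.

Everything here is plain NumPy with hand-derived gradients; the networks are
small dense MLPs and full-batch Adam is entirely adequate at cohort scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def flatten_upper_triangle(M: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Flatten the strict upper triangle of a symmetric matrix, row-major.

    Entries M[i, j] with i < j are returned with i ascending and, within each
    row, j ascending — the canonical vectorisation of a connectivity matrix.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    asym = np.max(np.abs(M - M.T)) if M.size else 0.0
    if asym > tol:
        raise ValueError(f"matrix is asymmetric (max |M - M.T| = {asym:.3g} > {tol:g})")
    return M[np.triu_indices(M.shape[0], k=1)]


def squeeze(X: np.ndarray) -> np.ndarray:
    """Global average over subjects: z_j = mean_i X[i, j]."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError(f"need a non-empty N x d matrix, got shape {X.shape}")
    return X.mean(axis=0)


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


@dataclass
class SEParams:
    """Excitation weights W1 (d/r x d), W2 (d x d/r) plus the frozen squeeze
    vector z they are applied to."""

    W1: np.ndarray
    W2: np.ndarray
    r: int
    z: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.W1.shape[1]


def excitation(z: np.ndarray, params: SEParams) -> np.ndarray:
    """s = sigmoid(W2 relu(W1 z)); every entry lies strictly in (0, 1)."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.shape[0] != params.W1.shape[1]:
        raise ValueError(
            f"z has length {z.shape}, excitation expects {params.W1.shape[1]}"
        )
    hidden = np.maximum(params.W1 @ z, 0.0)
    return _sigmoid(params.W2 @ hidden)


def rescale(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Elementwise reweighting x~_i = s * x_i applied to every row."""
    X = np.asarray(X)
    s = np.asarray(s)
    if X.ndim != 2 or s.ndim != 1 or X.shape[1] != s.shape[0]:
        raise ValueError(
            f"shape mismatch: X is {X.shape}, s has length {s.shape}"
        )
    return X * s


@dataclass
class AEParams:
    """Two-layer encoder (d -> h -> d_hat) and decoder (d_hat -> h -> d)."""

    We1: np.ndarray
    be1: np.ndarray
    We2: np.ndarray
    be2: np.ndarray
    Wd1: np.ndarray
    bd1: np.ndarray
    Wd2: np.ndarray
    bd2: np.ndarray
    activation: str = "relu"

    @property
    def latent_dim(self) -> int:
        return self.We2.shape[1]

    @property
    def dim(self) -> int:
        return self.We1.shape[0]


@dataclass(frozen=True)
class SEAEConfig:
    """Hyperparameters of the joint SE + autoencoder fit.

    r is the SE bottleneck reduction rate; hidden/latent are the AE widths
    (latent is d_hat); recon_target chooses whether the reconstruction loss
    compares against the raw features (default) or the SE-rescaled ones;
    se_enabled=False bypasses the SE block (weights fixed at s = 1), which is
    the "-SE" ablation.
    """

    r: int = 16
    hidden: int = 128
    latent: int = 64
    epochs: int = 120
    lr: float = 1e-3
    seed: int = 0
    recon_target: str = "raw"  # or "rescaled"
    se_enabled: bool = True


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _forward_se_ae(
    X: np.ndarray, se: SEParams, ae: AEParams, se_enabled: bool
) -> dict:
    if se_enabled:
        v = se.W1 @ se.z
        a = np.maximum(v, 0.0)
        u = se.W2 @ a
        s = _sigmoid(u)
    else:
        v = a = u = None
        s = np.ones(X.shape[1])
    Xt = X * s
    Ze1 = Xt @ ae.We1 + ae.be1
    E1 = np.maximum(Ze1, 0.0)
    Lat = E1 @ ae.We2 + ae.be2
    Zd1 = Lat @ ae.Wd1 + ae.bd1
    D1 = np.maximum(Zd1, 0.0)
    R = D1 @ ae.Wd2 + ae.bd2
    return dict(v=v, a=a, u=u, s=s, Xt=Xt, Ze1=Ze1, E1=E1, Lat=Lat, Zd1=Zd1, D1=D1, R=R)


def _recon_mse(R: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((R - target) ** 2))


def fit_se_ae(
    X_train: np.ndarray,
    X_val: np.ndarray,
    config: SEAEConfig = SEAEConfig(),
) -> tuple[SEParams, AEParams, dict]:
    """Jointly train the SE block and autoencoder, unsupervised.

    Returns the parameter snapshot with the lowest validation reconstruction
    MSE, plus a log with per-epoch train/validation MSE, the untrained
    validation MSE and the selected epoch.  Fully deterministic for a fixed
    config (seed included).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] == 0:
        raise ValueError("X_train must be a non-empty N x d matrix")
    if X_val.ndim != 2 or X_val.shape[0] == 0:
        raise ValueError("validation set is empty")
    d = X_train.shape[1]
    if X_val.shape[1] != d:
        raise ValueError(f"X_val width {X_val.shape[1]} != X_train width {d}")
    if config.latent >= d:
        raise ValueError(
            f"latent width d_hat={config.latent} must be < d={d} (compression required)"
        )
    if config.recon_target not in ("raw", "rescaled"):
        raise ValueError(f"unknown recon_target {config.recon_target!r}")

    rng = np.random.default_rng(config.seed)
    hw = max(1, d // config.r)
    h, dh = config.hidden, config.latent
    se = SEParams(
        W1=_glorot(rng, hw, d).reshape(hw, d),
        W2=_glorot(rng, d, hw).reshape(d, hw),
        r=config.r,
        z=squeeze(X_train),
    )
    ae = AEParams(
        We1=_glorot(rng, d, h),
        be1=np.zeros(h),
        We2=_glorot(rng, h, dh),
        be2=np.zeros(dh),
        Wd1=_glorot(rng, dh, h),
        bd1=np.zeros(h),
        Wd2=_glorot(rng, h, d),
        bd2=np.zeros(d),
    )

    def val_mse(se_p: SEParams, ae_p: AEParams) -> float:
        cache = _forward_se_ae(X_val, se_p, ae_p, config.se_enabled)
        target = X_val if config.recon_target == "raw" else cache["Xt"]
        return _recon_mse(cache["R"], target)

    init_val = val_mse(se, ae)
    params = [ae.We1, ae.be1, ae.We2, ae.be2, ae.Wd1, ae.bd1, ae.Wd2, ae.bd2]
    if config.se_enabled:
        params = [se.W1, se.W2] + params
    opt = _Adam(params, config.lr)

    N = X_train.shape[0]
    best = (init_val, -1, _snapshot(se, ae))
    log = {"train_mse": [], "val_mse": [], "init_val_mse": init_val}
    for epoch in range(config.epochs):
        cache = _forward_se_ae(X_train, se, ae, config.se_enabled)
        target = X_train if config.recon_target == "raw" else cache["Xt"]
        R = cache["R"]
        loss = _recon_mse(R, target)
        dR = 2.0 * (R - target) / R.size
        # decoder
        dWd2 = cache["D1"].T @ dR
        dbd2 = dR.sum(axis=0)
        dD1 = dR @ ae.Wd2.T
        dZd1 = dD1 * (cache["Zd1"] > 0)
        dWd1 = cache["Lat"].T @ dZd1
        dbd1 = dZd1.sum(axis=0)
        dLat = dZd1 @ ae.Wd1.T
        # encoder
        dWe2 = cache["E1"].T @ dLat
        dbe2 = dLat.sum(axis=0)
        dE1 = dLat @ ae.We2.T
        dZe1 = dE1 * (cache["Ze1"] > 0)
        dWe1 = cache["Xt"].T @ dZe1
        dbe1 = dZe1.sum(axis=0)
        grads = [dWe1, dbe1, dWe2, dbe2, dWd1, dbd1, dWd2, dbd2]
        if config.se_enabled:
            dXt = dZe1 @ ae.We1.T
            ds = (dXt * X_train).sum(axis=0)
            if config.recon_target == "rescaled":
                # the target X*s itself moves with s: d(loss)/ds -= dR . x
                ds -= (dR * X_train).sum(axis=0)
            s = cache["s"]
            du = ds * s * (1.0 - s)
            dW2 = np.outer(du, cache["a"])
            da = se.W2.T @ du
            dv = da * (cache["v"] > 0)
            dW1 = np.outer(dv, se.z)
            grads = [dW1, dW2] + grads
        opt.step(params, grads)
        v = val_mse(se, ae)
        log["train_mse"].append(loss)
        log["val_mse"].append(v)
        if v < best[0]:
            best = (v, epoch, _snapshot(se, ae))
    best_val, best_epoch, (se_best, ae_best) = best
    log["best_val_mse"] = best_val
    log["best_epoch"] = best_epoch
    if best_epoch < 0:
        logger.warning("SE-AE training never improved on the untrained model")
    return se_best, ae_best, log


def _snapshot(se: SEParams, ae: AEParams) -> tuple[SEParams, AEParams]:
    return (
        SEParams(W1=se.W1.copy(), W2=se.W2.copy(), r=se.r, z=None if se.z is None else se.z.copy()),
        AEParams(
            We1=ae.We1.copy(),
            be1=ae.be1.copy(),
            We2=ae.We2.copy(),
            be2=ae.be2.copy(),
            Wd1=ae.Wd1.copy(),
            bd1=ae.bd1.copy(),
            Wd2=ae.Wd2.copy(),
            bd2=ae.bd2.copy(),
            activation=ae.activation,
        ),
    )


def encode(
    X: np.ndarray,
    se: SEParams,
    ae: AEParams,
    se_enabled: bool = True,
) -> np.ndarray:
    """Compress raw features to width d_hat using trained SE + encoder.

    The excitation weights are applied to the *stored* squeeze vector (frozen
    from the training subjects), so encoding is deterministic and independent
    of which subjects are passed in.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != ae.dim:
        raise ValueError(f"X has shape {X.shape}, encoder expects width {ae.dim}")
    if se_enabled:
        if se.z is None:
            raise ValueError("SEParams.z is unset; fit_se_ae must be run first")
        s = excitation(se.z, se)
        Xt = rescale(X, s)
    else:
        Xt = X
    E1 = np.maximum(Xt @ ae.We1 + ae.be1, 0.0)
    return E1 @ ae.We2 + ae.be2
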