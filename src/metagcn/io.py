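"""Archives for trained parameters (NumPy .npz, self-describing).

Two archive kinds: a feature-parameter archive holding the trained SE block
and autoencoder, and a model archive additionally holding the meta-learned
GCN parameters, the frozen phenotype ranges, the encoded features and the
training subject indices — everything ``MetaGCNResults.predict`` needs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .features import AEParams, SEParams
from .model import MetaGCNModel, MetaGCNResults

_AE_FIELDS = ("We1", "be1", "We2", "be2", "Wd1", "bd1", "Wd2", "bd2")


def save_feature_params(
    se: SEParams, ae: AEParams, path: str | Path, extra: dict | None = None
) -> None:
    arrays = {f"ae_{k}": getattr(ae, k) for k in _AE_FIELDS}
    arrays.update(se_W1=se.W1, se_W2=se.W2, se_z=se.z)
    meta = {"se_r": se.r, "ae_activation": ae.activation, **(extra or {})}
    np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)


def load_feature_params(path: str | Path) -> tuple[SEParams, AEParams, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        se = SEParams(W1=z["se_W1"], W2=z["se_W2"], r=int(meta["se_r"]), z=z["se_z"])
        ae = AEParams(
            **{k: z[f"ae_{k}"] for k in _AE_FIELDS},
            activation=meta.get("ae_activation", "relu"),
        )
    return se, ae, meta


def save_model(res: MetaGCNResults, path: str | Path) -> None:
    arrays = {
        "theta0": res.theta[0],
        "theta1": res.theta[1],
        "features": res.features,
        "ranges": res.ranges,
        "train_idx": res.train_idx,
    }
    if res.se_params is not None:
        arrays.update(se_W1=res.se_params.W1, se_W2=res.se_params.W2, se_z=res.se_params.z)
        arrays.update({f"ae_{k}": getattr(res.ae_params, k) for k in _AE_FIELDS})
    meta = {
        "seed": res.seed,
        "n_classes": res.model.n_classes,
        "class_names": list(res.model.class_names),
        "task_cfg": dataclasses.asdict(res.task_cfg),
        "meta_cfg": dataclasses.asdict(res.meta_cfg),
        "adj_cfg": dataclasses.asdict(res.model.adj_cfg),
        "ablation": dataclasses.asdict(res.model.ablation),
        "se_r": None if res.se_params is None else res.se_params.r,
    }
    np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)


def load_model(model: MetaGCNModel, path: str | Path) -> MetaGCNResults:
    """Rehydrate a results object against the cohort it was trained on."""
    from .gcn import MetaConfig
    from .tasks import TaskSamplingConfig

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        se = ae = None
        if "se_W1" in z:
            se = SEParams(
                W1=z["se_W1"], W2=z["se_W2"], r=int(meta["se_r"]), z=z["se_z"]
            )
            ae = AEParams(**{k: z[f"ae_{k}"] for k in _AE_FIELDS})
        res = MetaGCNResults(
            model=model,
            theta=[z["theta0"], z["theta1"]],
            se_params=se,
            ae_params=ae,
            features=z["features"],
            ranges=z["ranges"],
            train_idx=z["train_idx"],
            task_cfg=TaskSamplingConfig(**meta["task_cfg"]),
            meta_cfg=MetaConfig(**meta["meta_cfg"]),
            feature_log={},
            train_log=[],
            seed=int(meta["seed"]),
        )
    if model.n_classes != meta["n_classes"]:
        raise ValueError("model archive and cohort disagree on the class count")
    return res
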