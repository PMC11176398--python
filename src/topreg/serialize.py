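"""JSON model containers with deterministic round-trips.

Models are small (B is (K+1)×K), so arrays are stored inline as lists;
the container records the model kind, coefficients, noise parameters,
anchor ids/activities and config needed to reproduce predictions.
"""

from __future__ import annotations

import json

import numpy as np

from .ensemble import EnsembleConfig, EnsembleModel
from .multivariate import MultivariateTRModel
from .univariate import UnivariateTRModel


def _arr(a):
    return np.asarray(a).tolist()


def model_to_dict(model) -> dict:
    if isinstance(model, UnivariateTRModel):
        return {
            "kind": "univariate",
            "B": _arr(model.B),
            "sigma2": model.sigma2,
            "mode": model.mode,
            "beta": model.beta,
            "eps": model.eps,
            "anchor_indices": _arr(model.anchor_indices),
            "anchor_activities": _arr(model.anchor_activities),
            "gram_inv": [_arr(g) for g in model.gram_inv],
            "n_rows": model.n_rows,
            "rss": model.rss,
            "tss": model.tss,
        }
    if isinstance(model, MultivariateTRModel):
        return {
            "kind": "multivariate",
            "B": _arr(model.B),
            "Sigma": _arr(model.Sigma),
            "anchor_activities": _arr(model.anchor_activities),
            "gram_inv": _arr(model.gram_inv),
            "n_obs": model.n_obs,
            "distance_power": model.distance_power,
            "eps": model.eps,
            "anchor_indices": _arr(model.anchor_indices)
            if model.anchor_indices is not None
            else None,
        }
    if isinstance(model, EnsembleModel):
        return {
            "kind": "ensemble",
            "fractions": _arr(model.fractions),
            "config": vars(model.config) | {"clip": list(model.config.clip)},
            "members": [model_to_dict(m) for m in model.members],
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(d: dict):
    kind = d["kind"]
    if kind == "univariate":
        return UnivariateTRModel(
            B=np.asarray(d["B"], dtype=float),
            sigma2=float(d["sigma2"]),
            mode=d["mode"],
            beta=None if d["beta"] is None else float(d["beta"]),
            eps=float(d["eps"]),
            anchor_indices=np.asarray(d["anchor_indices"], dtype=int),
            anchor_activities=np.asarray(d["anchor_activities"], dtype=float),
            gram_inv=[np.asarray(g, dtype=float) for g in d["gram_inv"]],
            n_rows=int(d["n_rows"]),
            rss=float(d["rss"]),
            tss=float(d["tss"]),
        )
    if kind == "multivariate":
        anchors = (
            np.asarray(d["anchor_indices"], dtype=int)
            if d.get("anchor_indices") is not None
            else None
        )
        return MultivariateTRModel(
            B=np.asarray(d["B"], dtype=float),
            Sigma=np.asarray(d["Sigma"], dtype=float),
            anchor_activities=np.asarray(d["anchor_activities"], dtype=float),
            gram_inv=np.asarray(d["gram_inv"], dtype=float),
            n_obs=int(d["n_obs"]),
            distance_power=int(d["distance_power"]),
            eps=float(d["eps"]),
            anchor_indices=anchors,
        )
    if kind == "ensemble":
        cfg_d = dict(d["config"])
        cfg_d["clip"] = tuple(cfg_d["clip"])
        cfg = EnsembleConfig(**cfg_d)
        return EnsembleModel(
            members=[model_from_dict(m) for m in d["members"]],
            fractions=np.asarray(d["fractions"], dtype=float),
            config=cfg,
        )
    raise ValueError(f"unknown model kind {kind!r}")


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
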