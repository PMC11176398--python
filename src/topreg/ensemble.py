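"""Ensemble topological regression.

Samples t anchor sets independently, with anchor fractions drawn from
N(μ_k, σ_k²) and clipped into [30%, 90%], fits one univariate TR model
per set on the shared training distance matrix (each member just
column-samples it), and averages the member response predictions.
Defaults t=15, μ_k=0.6, σ_k²=0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import TopregError
from .univariate import MonteCarloConfig, UnivariateTRModel, fit_tr, predict


@dataclass(frozen=True)
class EnsembleConfig:
    t: int = 15
    mu_k: float = 0.6
    sigma2_k: float = 0.2
    clip: tuple[float, float] = (0.30, 0.90)
    seed: int = 0
    mode: str = "gaussian_kernel"
    max_anchors: int = 2000

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not 0.0 < self.mu_k < 1.0:
            raise ValueError("mu_k must be in (0, 1)")
        if self.sigma2_k < 0.0:
            raise ValueError("sigma2_k must be nonnegative")


@dataclass
class EnsembleModel:
    members: list[UnivariateTRModel]
    fractions: np.ndarray
    config: EnsembleConfig

    @property
    def t(self) -> int:
        return len(self.members)


def sample_fractions(cfg: EnsembleConfig) -> np.ndarray:
    """t anchor fractions from N(μ_k, σ_k²), clipped into [0.30, 0.90]."""
    rng = np.random.default_rng(cfg.seed)
    draws = rng.normal(cfg.mu_k, np.sqrt(cfg.sigma2_k), size=cfg.t)
    return np.clip(draws, cfg.clip[0], cfg.clip[1])


def fit_ensemble(
    dist_design: np.ndarray,
    y: np.ndarray,
    cfg: EnsembleConfig = EnsembleConfig(),
) -> EnsembleModel:
    """Fit t univariate TR members with independently sampled anchor sets.

    The full training distance design is computed once by the caller and
    column-sampled per member.  Member seeds are spawned deterministically
    from ``cfg.seed``; a member fit failure is re-raised with its index.
    """
    y = np.asarray(y, dtype=float)
    fractions = sample_fractions(cfg)
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(cfg.seed).spawn(cfg.t)
    ]
    members = []
    for i, (frac, seed_i) in enumerate(zip(fractions, child_seeds)):
        try:
            members.append(
                fit_tr(
                    dist_design,
                    y,
                    anchor_fraction=float(frac),
                    max_anchors=cfg.max_anchors,
                    mode=cfg.mode,
                    seed=seed_i,
                )
            )
        except Exception as exc:  # noqa: BLE001 - annotate member index
            raise TopregError(f"ensemble member {i} failed to fit: {exc}") from exc
    return EnsembleModel(members=members, fractions=fractions, config=cfg)


def predict_ensemble(
    model: EnsembleModel,
    d_query_to_train: np.ndarray,
    cfg: MonteCarloConfig | None = None,
) -> np.ndarray:
    """Unweighted mean of member predictions.

    ``d_query_to_train`` holds squared distances from each query to every
    training molecule; each member slices its own anchor columns.
    """
    rows = np.atleast_2d(np.asarray(d_query_to_train, dtype=float))
    preds = np.zeros((model.t, len(rows)))
    for i, member in enumerate(model.members):
        preds[i] = predict(member, rows[:, member.anchor_indices], cfg=cfg)
    return preds.mean(axis=0)
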