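"""Synthetic data generators.

Two kinds of fixtures:

* :func:`simulate_tr_data` draws data exactly from the TR generative
  model — squared chemical distances from a squared Beta(2,2) (mimicking
  squared Tanimoto distances in [0,1]), log-weights linear in the
  distances plus Gaussian noise, anchor activities uniform on a
  pChEMBL-like range, and neighborhood activities via the normalized
  weighted mean.  Used for parameter-recovery and coverage tests.

* :func:`simulate_landscape` builds fingerprint-like clustered landscapes
  with planted activity cliffs: each cluster has a random template
  bit-set, members are bit-flipped copies (high within-cluster Tanimoto
  similarity), activities are the cluster mean plus small noise, and a
  few designated cliff molecules are offset by Δ — structurally ordinary
  members whose potency jumps, the activity-cliff phenomenon.  Fingerprints
  are injected directly so the whole TR stack is testable without any
  chemistry toolkit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemio import Dataset, MoleculeRecord


@dataclass
class GenerativeSpec:
    """Sizes, coefficients and noise of the TR generative model."""

    N: int
    K: int
    B_true: np.ndarray
    sigma: float | np.ndarray = 0.5
    y_anchor_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        self.B_true = np.asarray(self.B_true, dtype=float)
        if self.B_true.shape != (self.K + 1, self.K):
            raise ValueError(f"B_true must be (K+1)xK = {(self.K + 1, self.K)}")


@dataclass
class SimulatedTRData:
    D_X: np.ndarray
    W_tilde: np.ndarray
    y_anchor: np.ndarray
    y_neigh: np.ndarray
    spec: GenerativeSpec


def random_coefficients(
    K: int, seed: int = 0, intercept_scale: float = 0.5, slope_scale: float = 1.0
) -> np.ndarray:
    """A plausible (K+1)×K coefficient matrix for simulations.

    Slopes center on −1 (weights tend to decay with chemical distance,
    as in inverse-distance weighting) with unit-order spread, so the
    anchor-specific sign flexibility of TR is still exercised.
    """
    rng = np.random.default_rng(seed)
    B = np.empty((K + 1, K))
    B[0] = rng.normal(0.0, intercept_scale, size=K)
    B[1:] = rng.normal(-1.0, slope_scale, size=(K, K))
    return B


def simulate_tr_data(spec: GenerativeSpec) -> SimulatedTRData:
    """Draw (D_X, W̃, Y_anchor, Y_neigh) from the TR generative model.

    W̃ = [1, D_X]·B_true + noise with noise either N(0, σ²) iid (scalar
    ``sigma``) or N_K(0, Σ) per row (matrix ``sigma``); Y_neigh is the
    normalized weighted mean of anchor activities under W = e^W̃.
    """
    rng = np.random.default_rng(spec.seed)
    D = rng.beta(2.0, 2.0, size=(spec.N, spec.K)) ** 2
    X = np.column_stack([np.ones(spec.N), D])
    mean = X @ spec.B_true
    if np.ndim(spec.sigma) == 0:
        noise = rng.normal(0.0, float(spec.sigma), size=(spec.N, spec.K))
    else:
        Sigma = np.asarray(spec.sigma, dtype=float)
        noise = rng.multivariate_normal(np.zeros(spec.K), Sigma, size=spec.N)
    W_tilde = mean + noise
    y_anchor = rng.uniform(*spec.y_anchor_range, size=spec.K)
    # stable normalized weighted mean on the log scale
    lw = W_tilde - W_tilde.max(axis=1, keepdims=True)
    W = np.exp(lw)
    y_neigh = (W @ y_anchor) / W.sum(axis=1)
    return SimulatedTRData(D_X=D, W_tilde=W_tilde, y_anchor=y_anchor, y_neigh=y_neigh, spec=spec)


@dataclass
class LandscapeSpec:
    """Clustered fingerprint landscape with planted activity cliffs."""

    n_clusters: int = 5
    cluster_size: int = 40
    nbits: int = 512
    template_density: float = 0.12
    flip_rate: float = 0.01
    activity_means: tuple[float, ...] | None = None
    cliffs_per_cluster: int = 4
    delta: float = 3.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.cliffs_per_cluster > 0 and self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if not 0.0 <= self.flip_rate < 1.0:
            raise ValueError("flip_rate must be in [0, 1)")


def simulate_landscape(spec: LandscapeSpec) -> tuple[Dataset, dict]:
    """Generate a cliff landscape as a fingerprint-injected Dataset.

    Returns the dataset and a ground-truth dict (cluster labels, cliff
    flags, cluster means) for recovery and graph tests.
    """
    rng = np.random.default_rng(spec.seed)
    means = (
        np.asarray(spec.activity_means, dtype=float)
        if spec.activity_means is not None
        else np.linspace(4.5, 9.0, spec.n_clusters)
    )
    records: list[MoleculeRecord] = []
    labels, cliff_flags = [], []
    for c in range(spec.n_clusters):
        template = rng.random(spec.nbits) < spec.template_density
        cliff_members = rng.choice(
            spec.cluster_size, size=min(spec.cliffs_per_cluster, spec.cluster_size), replace=False
        )
        for m in range(spec.cluster_size):
            flips = rng.random(spec.nbits) < spec.flip_rate
            bits = np.flatnonzero(template ^ flips)
            is_cliff = m in cliff_members
            activity = means[c] + rng.normal(0.0, spec.noise_sd)
            if is_cliff:
                activity += spec.delta
            records.append(
                MoleculeRecord(
                    id=f"c{c}_m{m}",
                    smiles=None,
                    fingerprint=frozenset(int(b) for b in bits),
                    activity=float(activity),
                )
            )
            labels.append(c)
            cliff_flags.append(bool(is_cliff))
    ds = Dataset(records=records, nbits=spec.nbits, provenance="synthetic landscape")
    truth = {
        "cluster": labels,
        "is_cliff": cliff_flags,
        "cluster_means": means.tolist(),
        "delta": spec.delta,
        "seed": spec.seed,
    }
    return ds, truth


def write_landscape(ds: Dataset, truth: dict, csv_path, truth_path=None) -> None:
    """Write the landscape as the fingerprint-table CSV schema plus a
    sidecar JSON of ground-truth parameters."""
    rows = [
        {
            "id": r.id,
            "fingerprint": ";".join(str(b) for b in sorted(r.fingerprint)),
            "activity": r.activity,
        }
        for r in ds.records
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
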