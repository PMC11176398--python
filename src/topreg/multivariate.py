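"""Multivariate topological regression (TR*).

The training set is partitioned into K *anchor* molecules and N
*neighborhood-training* molecules, disjoint, with K < N.  Each
neighborhood molecule m contributes one row of log nearest-neighbor
weights W̃_{·,m} (extracted from response-space distances) which is
regressed, as a K-variate observation, on the row of squared
chemical-space distances from m to the K anchors:

    W̃_{j,m} = b_{0j} + Σ_l b_{lj} d²_{l,m;X} + ε_j,   ε ~ N_K(0, Σ).

The MLE is column-wise OLS with a shared design; Σ̂ is the residual
cross-product divided by N.  Because weights are log-normal on the natural
scale, predictions apply the log-normal mean correction
E(W) = exp(μ + Σ_jj/2), with the covariance sandwich
Var(W) = diag(E W)(e^Σ − 11ᵀ)diag(E W), and parametric-bootstrap
prediction intervals propagate coefficient and residual uncertainty
through the exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import SingularFitError, TooFewAnchorsError

DEFAULT_EPS = 1e-6


@dataclass(frozen=True)
class AnchorPartition:
    """Disjoint anchor / neighborhood-training index sets (TR*)."""

    anchor_indices: tuple[int, ...]
    neighborhood_indices: tuple[int, ...]
    seed: int = 0

    def __post_init__(self):
        a, n = set(self.anchor_indices), set(self.neighborhood_indices)
        if a & n:
            raise ValueError("anchor and neighborhood sets must be disjoint")
        if not len(self.anchor_indices) < len(self.neighborhood_indices):
            raise ValueError("need fewer anchors than neighborhood points")

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_indices)


def make_partition(
    n: int, anchor_fraction: float = 0.2, seed: int = 0
) -> AnchorPartition:
    """Uniform random disjoint split; 20% anchors by default."""
    rng = np.random.default_rng(seed)
    k = max(2, int(round(anchor_fraction * n)))
    if k >= n - k:
        raise TooFewAnchorsError(
            f"anchor_fraction={anchor_fraction} leaves no valid disjoint split of {n}"
        )
    perm = rng.permutation(n)
    return AnchorPartition(
        anchor_indices=tuple(int(i) for i in perm[:k]),
        neighborhood_indices=tuple(int(i) for i in perm[k:]),
        seed=seed,
    )


def extract_weights_inverse_distance(
    y_neigh: np.ndarray, y_anchor: np.ndarray, eps: float = DEFAULT_EPS
) -> np.ndarray:
    """Log-weight matrix W̃, entry (j,l) = log 1/((Y*_l − Y_j)² + eps).

    Inverse squared response-space distance weighting; ``eps`` guards exact
    response ties (log-weights must stay finite).
    """
    d2 = (np.asarray(y_anchor)[None, :] - np.asarray(y_neigh)[:, None]) ** 2
    return -np.log(d2 + eps)


@dataclass
class MultivariateTRModel:
    """Fitted TR* parameters.

    B is (K+1)×K: intercept row b_{0j} on top, slope rows b_{lj} below.
    Sigma is the K×K MLE residual covariance.  ``gram_inv`` is
    ([1,D]ᵀ[1,D])⁻¹, kept for the parametric bootstrap.
    """

    B: np.ndarray
    Sigma: np.ndarray
    anchor_activities: np.ndarray
    gram_inv: np.ndarray
    n_obs: int
    partition: AnchorPartition | None = None
    anchor_indices: np.ndarray | None = None
    distance_power: int = 2
    eps: float = DEFAULT_EPS

    @property
    def n_anchors(self) -> int:
        return self.B.shape[1]


@dataclass
class WeightPrediction:
    """Predicted positive weights with covariance and optional intervals."""

    mean_weights: np.ndarray
    covariance: np.ndarray
    interval_lo: np.ndarray | None = None
    interval_hi: np.ndarray | None = None


def _check_design(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending anchors via pivoted QR: dependent columns get
        # the smallest |R| diagonal entries
        import scipy.linalg

        _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(int(piv[i]) - 1 for i in range(rank, X.shape[1]))
        raise SingularFitError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear anchor columns: {bad}",
            anchors=[b for b in bad if b >= 0],
        )


def fit_multivariate(
    W_tilde: np.ndarray,
    D: np.ndarray,
    anchor_activities: np.ndarray | None = None,
    partition: AnchorPartition | None = None,
) -> MultivariateTRModel:
    """Column-wise OLS of the N×K log-weight matrix on [1, D].

    Returns B̂ ((K+1)×K) and the MLE residual covariance Σ̂ = RᵀR/N.
    Raises :class:`SingularFitError` for a rank-deficient design, naming
    the collinear anchor columns.
    """
    W_tilde = np.asarray(W_tilde, dtype=float)
    D = np.asarray(D, dtype=float)
    n, k = W_tilde.shape
    if D.shape != (n, k):
        raise ValueError(f"shape mismatch: W̃ {W_tilde.shape}, D {D.shape}")
    if n <= k + 1:
        raise ValueError(f"need N > K+1 rows (got N={n}, K={k})")
    X = np.column_stack([np.ones(n), D])
    _check_design(X)
    B, *_ = np.linalg.lstsq(X, W_tilde, rcond=None)
    resid = W_tilde - X @ B
    Sigma = resid.T @ resid / n
    gram_inv = np.linalg.inv(X.T @ X)
    if anchor_activities is None:
        anchor_activities = np.full(k, np.nan)
    return MultivariateTRModel(
        B=B,
        Sigma=Sigma,
        anchor_activities=np.asarray(anchor_activities, dtype=float),
        gram_inv=gram_inv,
        n_obs=n,
        partition=partition,
    )


def lognormal_mean_correction(mu: float, sigma2: float) -> float:
    """E(e^Z) for Z ~ N(mu, sigma2): exp(mu + sigma2/2).

    Exponentiating a predicted log-weight alone underestimates E(W) by
    Jensen's inequality; this is the exact log-normal mean.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    return float(np.exp(mu + sigma2 / 2.0))


def predict_weights(model: MultivariateTRModel, d_query: np.ndarray) -> WeightPrediction:
    """Bias-corrected weight predictions with log-normal covariance.

    μ̂ = [1, d²_query]·B̂;  Ŵ_j = exp(μ̂_j + Σ̂_jj/2);
    Var(Ŵ) = diag(Ŵ)(e^Σ̂ − 11ᵀ)diag(Ŵ) with e^Σ̂ elementwise.
    """
    d_query = np.asarray(d_query, dtype=float)
    if d_query.shape != (model.n_anchors,):
        raise ValueError(f"d_query must have length {model.n_anchors}")
    x = np.concatenate([[1.0], d_query])
    mu = x @ model.B
    w = np.exp(mu + np.diag(model.Sigma) / 2.0)
    cov = np.outer(w, w) * (np.exp(model.Sigma) - 1.0)
    return WeightPrediction(mean_weights=w, covariance=cov)


def _sigma_factor(Sigma: np.ndarray) -> np.ndarray:
    """Matrix square root robust to PSD-but-singular Σ̂."""
    vals, vecs = np.linalg.eigh(Sigma)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def bootstrap_prediction_interval(
    model: MultivariateTRModel,
    d_query: np.ndarray,
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
    sample_coefficients: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric-bootstrap pointwise prediction interval per anchor.

    Draws coefficient replicates from the asymptotic normal of B̂
    (vec-covariance Σ̂ ⊗ (XᵀX)⁻¹), adds residual noise from N(0, Σ̂), and
    exponentiates; returns the empirical (1−level)/2 and 1−(1−level)/2
    quantiles of the weight replicates.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    rng = np.random.default_rng(seed)
    d_query = np.asarray(d_query, dtype=float)
    x = np.concatenate([[1.0], d_query])
    k = model.n_anchors
    ls = _sigma_factor(model.Sigma)
    mu = x @ model.B
    if sample_coefficients:
        lg = np.linalg.cholesky(
            model.gram_inv + 1e-12 * np.eye(model.gram_inv.shape[0])
        )
        # E = L_G Z L_Σᵀ has vec-covariance Σ ⊗ G
        z = rng.standard_normal((reps, k + 1, k))
        mu_rep = mu + np.einsum("j,jl,rlm->rm", x, lg, z @ ls.T)
    else:
        mu_rep = np.tile(mu, (reps, 1))
    eps = rng.standard_normal((reps, k)) @ ls.T
    w_rep = np.exp(mu_rep + eps)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(w_rep, alpha, axis=0)
    hi = np.quantile(w_rep, 1.0 - alpha, axis=0)
    return lo, hi


def predict_response(
    weights: WeightPrediction | np.ndarray,
    y_anchor: np.ndarray,
    normalized: bool = True,
) -> float:
    """Weighted combination of anchor activities.

    Normalized (default): Ŷ = Σ Ŵ_l Y*_l / Σ Ŵ_l, guaranteed inside
    [min Y*, max Y*].  Unnormalized: the raw linear combination.
    """
    w = weights.mean_weights if isinstance(weights, WeightPrediction) else np.asarray(weights)
    y_anchor = np.asarray(y_anchor, dtype=float)
    if normalized:
        return float(np.dot(w, y_anchor) / np.sum(w))
    return float(np.dot(w, y_anchor))


def fit_tr_star(
    dist_design: np.ndarray,
    y: np.ndarray,
    anchor_fraction: float = 0.2,
    seed: int = 0,
    eps: float = DEFAULT_EPS,
) -> MultivariateTRModel:
    """Fit TR* from a full N×N squared-distance design and activities.

    Samples a disjoint anchor/neighborhood partition (20% anchors by
    default, uniform without replacement) and fits the multivariate model.
    """
    y = np.asarray(y, dtype=float)
    part = make_partition(len(y), anchor_fraction=anchor_fraction, seed=seed)
    a = list(part.anchor_indices)
    nb = list(part.neighborhood_indices)
    w_tilde = extract_weights_inverse_distance(y[nb], y[a], eps=eps)
    D = np.asarray(dist_design)[np.ix_(nb, a)]
    model = fit_multivariate(w_tilde, D, anchor_activities=y[a], partition=part)
    model.anchor_indices = np.asarray(a, dtype=int)
    model.eps = eps
    return model


def predict_tr_star(
    model: MultivariateTRModel,
    d_query_rows: np.ndarray,
    normalized: bool = True,
) -> np.ndarray:
    """Predict responses for query rows of squared distances to the anchors."""
    d_query_rows = np.atleast_2d(np.asarray(d_query_rows, dtype=float))
    out = np.empty(len(d_query_rows))
    for i, row in enumerate(d_query_rows):
        wp = predict_weights(model, row)
        out[i] = predict_response(wp, model.anchor_activities, normalized=normalized)
    return out
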