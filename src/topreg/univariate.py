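"""Univariate topological regression (TR).

Drops the disjointness requirement of TR*: K anchors are drawn from the
training set itself and every anchor/non-anchor pair contributes one
stacked least-squares equation, plus one equation per unordered
anchor-anchor pair (the weight matrix is symmetric, so each pair appears
once) — K(N−K) + K(K−1)/2 rows in total.  Each row regresses its target
on [1, d²_{·}] and is routed to the coefficient column of its anchor, so
the fit is a per-column least squares with a pooled iid N(0, σ²) error.

Two weighting modes:

* ``inverse_distance`` — targets are log W = −log(d²_Y + eps); predicted
  weights get the log-normal mean correction exp(μ̂ + σ̂²/2).
* ``gaussian_kernel`` (the packaged default) — weights are Gaussian
  kernels W = exp(−β d²_Y); targets are log d²_Y, the fitted μ̂ is the
  mean log squared response distance, and E(W) is the Laplace transform
  of a log-normal, estimated by Monte Carlo:
  (1/R) Σ_r exp(−β̂ d²⁽ʳ⁾ e^{μ̂}),  d²⁽ʳ⁾ ~ lognormal(0, σ̂²).

The kernel bandwidth β̂ is chosen by leave-one-out cross-validation of a
Gaussian-kernel weighted-mean predictor in the response space, the
standard geographically-weighted-regression bandwidth criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import t as t_dist

from .exceptions import SingularFitError, TooFewAnchorsError
from .multivariate import DEFAULT_EPS, predict_response

#: raw Monte-Carlo averaging underflows / misses the tail beyond this
LARGE_BETA_MU = 50.0


@dataclass(frozen=True)
class MonteCarloConfig:
    """Replicate count and seed for the Laplace-transform estimator."""

    R: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.R < 1000:
            raise ValueError("MonteCarloConfig.R must be at least 1000")


@dataclass
class StackedDesign:
    """The stacked equation system of univariate TR.

    ``targets[i]`` is regressed on ``[1, X[i]]`` using the coefficient
    column ``col_index[i]``; ``pairs[i]`` records the (anchor, point)
    source indices.  Row count is K(N−K) + K(K−1)/2 when built from a
    training set, or N·K when built from a dense weight matrix.
    """

    targets: np.ndarray
    X: np.ndarray
    col_index: np.ndarray
    pairs: list[tuple[int, int]]
    n_anchors: int
    mode: str = "inverse_distance"

    def __len__(self) -> int:
        return len(self.targets)

    @classmethod
    def from_weight_matrix(cls, W_tilde: np.ndarray, D: np.ndarray) -> "StackedDesign":
        """Stack a dense N×K log-weight matrix against a shared design.

        Every entry (m, l) becomes one equation routed to column l with
        predictor row D[m].  Used for data drawn from the generative model,
        where the log-weights are observed directly.
        """
        W_tilde = np.asarray(W_tilde, dtype=float)
        D = np.asarray(D, dtype=float)
        n, k = W_tilde.shape
        targets = W_tilde.ravel(order="C")
        X = np.repeat(D, k, axis=0)
        col = np.tile(np.arange(k), n)
        pairs = [(l, m) for m in range(n) for l in range(k)]
        return cls(targets=targets, X=X, col_index=col, pairs=pairs, n_anchors=k)


def build_stacked_design(
    dist_design: np.ndarray,
    y: np.ndarray,
    anchor_indices,
    mode: str = "gaussian_kernel",
    eps: float = DEFAULT_EPS,
) -> StackedDesign:
    """Stacked equations from a full N×N squared-distance design.

    Anchor/non-anchor pairs contribute K(N−K) rows; unordered anchor
    pairs contribute K(K−1)/2 rows, each routed to the column of the
    larger anchor position (the observed point is the smaller one).
    Targets: −log(d²_Y+eps) in inverse-distance mode, +log(d²_Y+eps) in
    Gaussian-kernel mode.
    """
    if mode not in ("inverse_distance", "gaussian_kernel"):
        raise ValueError(f"unknown mode {mode!r}")
    anchors = [int(a) for a in anchor_indices]
    k = len(anchors)
    if k < 2:
        raise TooFewAnchorsError(f"need at least 2 anchors, got {k}")
    dist_design = np.asarray(dist_design, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    others = [i for i in range(n) if i not in set(anchors)]

    sign = -1.0 if mode == "inverse_distance" else 1.0
    rows_x, targets, cols, pairs = [], [], [], []
    for pos, a in enumerate(anchors):
        d2y = (y[a] - y[others]) ** 2
        targets.append(sign * np.log(d2y + eps))
        rows_x.append(dist_design[np.ix_(others, anchors)])
        cols.append(np.full(len(others), pos))
        pairs.extend((a, m) for m in others)
    # anchor-anchor triangle: pair (a_p, a_q), p > q, routed to column p,
    # observed from the smaller-position anchor q
    for p in range(1, k):
        for q in range(p):
            a, b = anchors[p], anchors[q]
            d2y = (y[a] - y[b]) ** 2
            targets.append([sign * np.log(d2y + eps)])
            rows_x.append(dist_design[b, anchors][None, :])
            cols.append([p])
            pairs.append((a, b))
    return StackedDesign(
        targets=np.concatenate([np.atleast_1d(t) for t in targets]),
        X=np.vstack(rows_x),
        col_index=np.concatenate([np.atleast_1d(c) for c in cols]).astype(int),
        pairs=pairs,
        n_anchors=k,
        mode=mode,
    )


@dataclass
class UnivariateTRModel:
    """Fitted univariate TR parameters.

    B is (K+1)×K as in the multivariate construction; sigma2 is the
    pooled residual variance of the stacked fit.  ``beta`` is the Gaussian
    kernel bandwidth (gaussian mode only).  Per-column Gram inverses are
    kept for analytic prediction intervals.
    """

    B: np.ndarray
    sigma2: float
    mode: str
    anchor_indices: np.ndarray
    anchor_activities: np.ndarray
    beta: float | None = None
    eps: float = DEFAULT_EPS
    gram_inv: list[np.ndarray] = field(default_factory=list)
    n_rows: int = 0
    rss: float = 0.0
    tss: float = 0.0

    @property
    def n_anchors(self) -> int:
        return self.B.shape[1]

    @property
    def df_resid(self) -> int:
        return max(self.n_rows - self.n_anchors * (self.n_anchors + 1), 1)


def fit_univariate(design: StackedDesign) -> UnivariateTRModel:
    """Per-column least squares over the stacked rows.

    Each row contributes to exactly one column's fit; σ̂² is the pooled
    residual sum of squares over the total row count (MLE).  The stored
    TSS is per-column centered, so an intercept-only fit has R² = 0.
    """
    k = design.n_anchors
    if len(design) <= k + 1:
        raise ValueError("too few stacked rows for the number of anchors")
    # collinear anchor columns (e.g. duplicated anchors) make every
    # column fit ill-posed; detect once on the full stacked design
    X_all = np.column_stack([np.ones(len(design)), design.X])
    rank_all = np.linalg.matrix_rank(X_all)
    if rank_all < k + 1:
        import scipy.linalg

        _, _, piv = scipy.linalg.qr(X_all, mode="economic", pivoting=True)
        bad = sorted(int(piv[i]) - 1 for i in range(rank_all, k + 1))
        raise SingularFitError(
            f"singular stacked design; collinear anchor columns: "
            f"{[b for b in bad if b >= 0]}",
            anchors=[b for b in bad if b >= 0],
        )
    B = np.zeros((k + 1, k))
    gram_inv: list[np.ndarray] = []
    rss = 0.0
    tss = 0.0
    for j in range(k):
        sel = design.col_index == j
        Xj = np.column_stack([np.ones(sel.sum()), design.X[sel]])
        tj = design.targets[sel]
        # minimum-norm least squares: a column system with fewer rows
        # than K+1 coefficients is legitimately underdetermined at large
        # anchor fractions and interpolates (the overfitting regime the
        # ensemble averages away)
        coef, _, _, _ = np.linalg.lstsq(Xj, tj, rcond=None)
        B[:, j] = coef
        resid = tj - Xj @ coef
        rss += float(resid @ resid)
        centered = tj - tj.mean()
        tss += float(centered @ centered)
        gram_inv.append(np.linalg.pinv(Xj.T @ Xj))
    return UnivariateTRModel(
        B=B,
        sigma2=rss / len(design),
        mode=design.mode,
        anchor_indices=np.array([], dtype=int),
        anchor_activities=np.full(k, np.nan),
        gram_inv=gram_inv,
        n_rows=len(design),
        rss=rss,
        tss=tss,
    )


def default_beta_grid(d2_y: np.ndarray, size: int = 32) -> np.ndarray:
    """Log-spaced bandwidth grid [1e−2, 1e2] scaled by 1/median(d²_Y)."""
    off = d2_y[~np.eye(len(d2_y), dtype=bool)] if d2_y.ndim == 2 else d2_y
    med = float(np.median(off))
    scale = 1.0 / med if med > 0 else 1.0
    return np.logspace(-2, 2, size) * scale


def estimate_beta(y: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Gaussian-kernel bandwidth by leave-one-out CV in the response space.

    Minimizes Σ_i (Y_i − Ŷ_i)² where Ŷ_i is the kernel weighted mean of
    the other responses with weights exp(−β d²_{ij;Y}).  Ties break toward
    the smallest β (the smoother model).  Constant responses make the
    criterion degenerate: the grid minimum is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 training points to estimate beta")
    d2 = (y[:, None] - y[None, :]) ** 2
    if grid is None:
        grid = default_beta_grid(d2)
    grid = np.asarray(grid, dtype=float)
    if np.ptp(y) == 0.0:
        warnings.warn("constant responses: beta is unidentifiable, returning grid minimum")
        return float(grid.min())
    mask = ~np.eye(len(y), dtype=bool)
    errors = np.empty(len(grid))
    for g, beta in enumerate(grid):
        # stabilized softmax row-wise over j != i
        logw = np.where(mask, -beta * d2, -np.inf)
        logw = logw - logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        yhat = (w * y[None, :]).sum(axis=1) / w.sum(axis=1)
        errors[g] = float(((y - yhat) ** 2).sum())
    return float(grid[int(np.argmin(errors))])


def mc_estimate_expected_weight(
    mu_hat: float,
    sigma2_hat: float,
    beta_hat: float,
    cfg: MonteCarloConfig = MonteCarloConfig(),
) -> float:
    """Monte-Carlo Laplace transform of the log-normal: E exp(−β d²_Y).

    Draws d²⁽ʳ⁾ ~ lognormal(0, σ̂²) and averages exp(−β̂ d²⁽ʳ⁾ e^{μ̂});
    equals exp(−β̂ e^{μ̂}) exactly when σ̂² = 0 and 1 when β̂ = 0.  For
    β̂ e^{μ̂} > 50 the raw average cannot resolve the tail, so a
    deterministic point-mass evaluation at the mode of the effective
    log-normal, exp(−β̂ e^{μ̂ − σ̂²}), is returned with a warning.
    """
    if beta_hat < 0 or sigma2_hat < 0:
        raise ValueError("beta and sigma2 must be nonnegative")
    if beta_hat == 0.0:
        return 1.0
    scale = beta_hat * np.exp(mu_hat)
    if sigma2_hat == 0.0:
        return float(np.exp(-scale))
    if scale > LARGE_BETA_MU:
        warnings.warn(
            "beta*exp(mu) > 50: falling back to point-mass approximation of "
            "the log-normal Laplace transform"
        )
        return float(np.exp(-beta_hat * np.exp(mu_hat - sigma2_hat)))
    rng = np.random.default_rng(cfg.seed)
    d2 = np.exp(rng.normal(0.0, np.sqrt(sigma2_hat), size=cfg.R))
    return float(np.exp(logsumexp(-scale * d2) - np.log(cfg.R)))


def _log_weights(
    model: UnivariateTRModel,
    d_query: np.ndarray,
    cfg: MonteCarloConfig | None,
) -> np.ndarray:
    """Log predicted weights for one query row (numerically stable)."""
    x = np.concatenate([[1.0], d_query])
    mu = x @ model.B
    if model.mode == "inverse_distance":
        return mu + model.sigma2 / 2.0
    if model.beta is None:
        raise ValueError("gaussian_kernel model has no fitted beta")
    if model.sigma2 == 0.0:
        return -model.beta * np.exp(mu)
    cfg = cfg or MonteCarloConfig()
    with np.errstate(over="ignore"):
        scale = model.beta * np.exp(mu)
    out = np.empty_like(mu)
    big = scale > LARGE_BETA_MU
    if np.any(big):
        with np.errstate(over="ignore"):
            # -inf log-weight is the correct limit for extreme mu
            out[big] = -model.beta * np.exp(mu[big] - model.sigma2)
    if np.any(~big):
        rng = np.random.default_rng(cfg.seed)
        d2 = np.exp(rng.normal(0.0, np.sqrt(model.sigma2), size=cfg.R))
        expo = -scale[~big, None] * d2[None, :]
        out[~big] = logsumexp(expo, axis=1) - np.log(cfg.R)
    return out


def predict(
    model: UnivariateTRModel,
    d_query: np.ndarray,
    cfg: MonteCarloConfig | None = None,
    normalized: bool = True,
) -> float | np.ndarray:
    """Predict the response for query rows of squared anchor distances.

    Inverse-distance mode applies the log-normal mean correction; Gaussian
    mode uses the Monte-Carlo Laplace estimator per anchor (one shared set
    of R draws per query).  The normalized prediction is a softmax over
    log-weights, hence always within the anchor activity range.
    """
    d = np.asarray(d_query, dtype=float)
    single = d.ndim == 1
    rows = np.atleast_2d(d)
    out = np.empty(len(rows))
    for i, row in enumerate(rows):
        lw = _log_weights(model, row, cfg)
        if normalized:
            p = np.exp(lw - logsumexp(lw))
            out[i] = float(p @ model.anchor_activities)
        else:
            out[i] = float(np.exp(lw) @ model.anchor_activities)
    return float(out[0]) if single else out


def predicted_log_weights(
    model: UnivariateTRModel, d_query_rows: np.ndarray
) -> np.ndarray:
    """Mean-structure ranking surrogate for neighbor graphs.

    In inverse-distance mode this is μ̂ + σ̂²/2 = log E(W); in Gaussian
    mode E(W) is strictly decreasing in μ̂, so −μ̂ ranks anchors exactly
    as the Monte-Carlo weights do, without sampling noise.
    """
    rows = np.atleast_2d(np.asarray(d_query_rows, dtype=float))
    X = np.column_stack([np.ones(len(rows)), rows])
    mu = X @ model.B
    if model.mode == "inverse_distance":
        return mu + model.sigma2 / 2.0
    return -mu


def prediction_interval(
    model: UnivariateTRModel,
    x_rows: np.ndarray,
    col_index: np.ndarray,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic prediction interval for stacked log-scale targets.

    For a row with predictors x routed to column j the interval is
    μ̂ ± t_{α/2} σ̂ √(1 + xᵀ(X_jᵀX_j)⁻¹x) with pooled σ̂² and pooled
    residual degrees of freedom.  Exponentiate the bounds for intervals on
    the natural-scale weights (monotone transform).
    """
    rows = np.atleast_2d(np.asarray(x_rows, dtype=float))
    col_index = np.atleast_1d(np.asarray(col_index, dtype=int))
    X = np.column_stack([np.ones(len(rows)), rows])
    sig = np.sqrt(model.sigma2)
    tq = t_dist.ppf(1.0 - (1.0 - level) / 2.0, df=max(model.df_resid, 1))
    lo = np.empty(len(rows))
    hi = np.empty(len(rows))
    for i, (x, j) in enumerate(zip(X, col_index)):
        mu = float(x @ model.B[:, j])
        h = float(x @ model.gram_inv[j] @ x)
        half = tq * sig * np.sqrt(1.0 + h)
        lo[i], hi[i] = mu - half, mu + half
    return lo, hi


def fit_tr(
    dist_design: np.ndarray,
    y: np.ndarray,
    anchor_fraction: float = 0.5,
    max_anchors: int = 2000,
    mode: str = "gaussian_kernel",
    seed: int = 0,
    eps: float = DEFAULT_EPS,
    anchor_indices=None,
) -> UnivariateTRModel:
    """Fit univariate TR end-to-end from a squared-distance design.

    Anchors default to 50% of the training set, capped at 2000, sampled
    uniformly without replacement.  In Gaussian mode the bandwidth β̂ is
    estimated by LOO-CV in the response space before the stacked fit.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if anchor_indices is None:
        rng = np.random.default_rng(seed)
        k = min(max(2, int(round(anchor_fraction * n))), max_anchors, n - 1)
        anchor_indices = np.sort(rng.choice(n, size=k, replace=False))
    anchor_indices = np.asarray(anchor_indices, dtype=int)
    # molecules with identical fingerprints yield exactly duplicate
    # distance columns; keep the first of each duplicate anchor group
    cols = np.asarray(dist_design)[:, anchor_indices]
    _, keep = np.unique(cols.round(12), axis=1, return_index=True)
    if len(keep) < len(anchor_indices):
        anchor_indices = np.sort(anchor_indices[np.sort(keep)])
    design = build_stacked_design(dist_design, y, anchor_indices, mode=mode, eps=eps)
    model = fit_univariate(design)
    model.anchor_indices = anchor_indices
    model.anchor_activities = y[anchor_indices]
    model.eps = eps
    if mode == "gaussian_kernel":
        model.beta = estimate_beta(y)
    return model
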