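"""Splitting, predictive metrics, goodness-of-fit and model selection.

Random 5-fold cross-validation and Murcko-scaffold holdout splitting;
Spearman ρ and NRMSE as the headline predictive metrics; training R² and
prediction-interval coverage as goodness-of-fit diagnostics of the
stacked weight regression; AIC/BIC over nested anchor sets for choosing
the anchor count.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .chemio import Dataset
from .exceptions import CannotSplitError, ConfigurationError
from .univariate import (
    StackedDesign,
    UnivariateTRModel,
    build_stacked_design,
    fit_univariate,
    prediction_interval,
)


def random_cv_split(n: int, n_folds: int = 5, seed: int = 0):
    """Seeded disjoint folds covering all indices.

    Yields (train_idx, test_idx) pairs; 5 folds of 80/20 by default.
    """
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} records, got {n}")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def murcko_scaffold(smiles: str) -> str:
    from rdkit.Chem.Scaffolds import MurckoScaffold

    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)


def scaffold_split(
    ds: Dataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Murcko-scaffold-disjoint holdout split.

    Groups molecules by Bemis–Murcko scaffold SMILES and fills the train
    partition greedily from the largest scaffold group until only the
    test budget remains; no scaffold string appears on both sides.  The
    seed shuffles the order among equal-size groups.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(ds.records):
        if rec.smiles is None:
            raise CannotSplitError("scaffold split requires SMILES records")
        groups.setdefault(murcko_scaffold(rec.smiles), []).append(i)
    if len(groups) < 2:
        raise CannotSplitError("all molecules share a single Murcko scaffold")
    rng = np.random.default_rng(seed)
    keys = list(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda s: -len(groups[s]))  # stable: seed-shuffled within size ties
    n = len(ds)
    train_target = n - int(round(test_fraction * n))
    train_idx, test_idx = [], []
    for key in keys:
        members = groups[key]
        if len(train_idx) + len(members) <= train_target:
            train_idx.extend(members)
        else:
            test_idx.extend(members)
    if not test_idx:
        test_idx.extend(groups[keys[-1]])
        train_idx = [i for i in train_idx if i not in set(test_idx)]
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def spearman_rho(y_true, y_pred) -> float:
    """Spearman rank correlation (average ranks on ties); NaN when an
    argument is constant (undefined), with a warning."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        warnings.warn("constant input: Spearman rho undefined, returning NaN")
        return float("nan")
    return float(stats.spearmanr(y_true, y_pred).statistic)


def nrmse(y_true, y_pred, norm: str = "std") -> float:
    """Root-mean-square error normalized by a spread statistic of y_true.

    ``norm`` ∈ {"std", "range", "mean"}; population std by default, so a
    constant mean predictor scores exactly 1.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if norm == "std":
        denom = float(np.std(y_true))
    elif norm == "range":
        denom = float(np.ptp(y_true))
    elif norm == "mean":
        denom = float(np.mean(y_true))
    else:
        raise ConfigurationError(f"unknown nrmse norm {norm!r}")
    if denom == 0:
        raise ZeroDivisionError("y_true spread is zero; NRMSE undefined")
    return rmse / denom


def training_r2(model: UnivariateTRModel) -> float:
    """1 − RSS/TSS of the stacked fit (TSS per-column centered)."""
    if model.tss == 0:
        return 1.0 if model.rss == 0 else float("nan")
    return 1.0 - model.rss / model.tss


def pi_coverage(
    model: UnivariateTRModel,
    x_rows: np.ndarray,
    col_index: np.ndarray,
    targets: np.ndarray,
    level: float = 0.95,
) -> float:
    """Fraction of held-out stacked targets inside their analytic
    prediction intervals (log scale; equivalent to coverage of the
    natural-scale weights under the monotone exp transform)."""
    lo, hi = prediction_interval(model, x_rows, col_index, level=level)
    t = np.asarray(targets, dtype=float)
    return float(np.mean((t >= lo) & (t <= hi)))


def knn_predict(
    sim_query_to_train: np.ndarray, y_train: np.ndarray, k: int = 5
) -> np.ndarray:
    """Plain chemical-space KNN baseline: mean activity of the k most
    Tanimoto-similar training molecules."""
    rows = np.atleast_2d(np.asarray(sim_query_to_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float)
    idx = np.argsort(-rows, axis=1)[:, :k]
    return y_train[idx].mean(axis=1)


def select_anchor_count(
    dist_design: np.ndarray,
    y: np.ndarray,
    candidates,
    mode: str = "inverse_distance",
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the anchor count by information criteria over nested sets.

    A master permutation is drawn once; candidate K uses its first K
    indices as anchors, giving a nested model sequence.  Each fit's
    Gaussian stacked-residual likelihood gives AIC = 2p − 2logL and
    BIC = p·log(n_rows) − 2logL with p = K(K+1) coefficients + 1
    variance.  Returns the BIC-argmin K and the full table.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    rows = []
    for k in sorted(int(k) for k in candidates):
        anchors = np.sort(perm[:k])
        design = build_stacked_design(dist_design, y, anchors, mode=mode)
        model = fit_univariate(design)
        n_rows = len(design)
        sigma2 = max(model.rss / n_rows, 1e-300)
        loglik = -0.5 * n_rows * (np.log(2.0 * np.pi * sigma2) + 1.0)
        p = k * (k + 1) + 1
        rows.append(
            {
                "K": k,
                "n_rows": n_rows,
                "loglik": loglik,
                "aic": 2.0 * p - 2.0 * loglik,
                "bic": p * np.log(n_rows) - 2.0 * loglik,
            }
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["bic"].idxmin(), "K"])
    return best, table


def information_criteria(design: StackedDesign) -> dict:
    """AIC/BIC of one stacked fit under the iid Gaussian likelihood."""
    model = fit_univariate(design)
    n = len(design)
    sigma2 = max(model.rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    k = design.n_anchors
    p = k * (k + 1) + 1
    return {
        "loglik": loglik,
        "aic": 2.0 * p - 2.0 * loglik,
        "bic": p * np.log(n) - 2.0 * loglik,
    }
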