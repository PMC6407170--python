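"""Genotype imputation: mean-dosage ("naive") and iterative Random Forest.

Both imputers return continuous dosages in [0, 2] — missing calls are not
rounded back to {0, 1, 2} — and never touch observed entries.

The Random-Forest scheme follows the missForest recipe adapted to marker
matrices: initialize with the column means, visit markers in decreasing
order of missingness, and for each regress its observed dosages on its
most-correlated companion markers (current completed values), predicting
the missing ones; sweep until the imputed values stop moving.  Predictor
preselection (``rf_k_predictors`` top-|r| markers per target) bounds the
cost at large marker counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .datatypes import MarkerMatrix

__all__ = [
    "ImputationSpec",
    "impute_naive",
    "impute_random_forest",
    "imputation_error",
    "impute",
]

_METHODS = ("naive", "random_forest")


@dataclass(frozen=True)
class ImputationSpec:
    method: str = "naive"
    rf_n_trees: int = 100
    rf_max_iter: int = 5
    rf_k_predictors: int = 30
    rf_tolerance: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.rf_n_trees < 1 or self.rf_k_predictors < 1:
            raise ValueError("rf_n_trees and rf_k_predictors must be positive")
        if self.rf_max_iter < 0:
            raise ValueError("rf_max_iter must be >= 0")
        if self.rf_tolerance <= 0:
            raise ValueError("rf_tolerance must be positive")


def _check_imputable(m: MarkerMatrix) -> np.ndarray:
    mask = m.missing_mask
    dead = np.flatnonzero(mask.all(axis=0))
    if dead.size:
        raise ValueError(
            f"markers with zero non-missing calls cannot be imputed: "
            f"{list(m.marker_ids[dead[:5]])}"
        )
    return mask


def impute_naive(m: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing call with its marker's mean observed dosage."""
    mask = _check_imputable(m)
    out = m.copy()
    if not mask.any():
        return out
    col_means = np.nanmean(m.dosages, axis=0)
    out.dosages[mask] = np.broadcast_to(col_means, m.dosages.shape)[mask]
    out.meta.update({"imputation": {"method": "naive"}})
    return out


def impute_random_forest(m: MarkerMatrix, spec: ImputationSpec) -> MarkerMatrix:
    """missForest-style iterative Random-Forest imputation.

    Metadata (iterations used, convergence flag, final mean squared
    change) is recorded under ``result.meta["imputation"]``.
    """
    mask = _check_imputable(m)
    out = impute_naive(m)
    n, p = m.dosages.shape
    cols_missing = np.flatnonzero(mask.any(axis=0))
    if cols_missing.size == 0 or spec.rf_max_iter == 0 or p < 2:
        out.meta["imputation"] = {
            "method": "random_forest",
            "iterations": 0,
            "converged": True,
            "seed": spec.seed,
        }
        return out

    # visit order: most missing first (missForest convention)
    n_miss = mask.sum(axis=0)
    order = cols_missing[np.argsort(-n_miss[cols_missing], kind="stable")]

    # predictor preselection from the naive-initialized completion;
    # zero-variance columns get correlation 0
    X = out.dosages
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z[:, sd == 0] = 0.0
    corr = (Z.T @ Z) / n
    np.fill_diagonal(corr, 0.0)
    k = min(spec.rf_k_predictors, p - 1)
    predictors = {
        j: np.argsort(-np.abs(corr[j]), kind="stable")[:k] for j in order
    }

    root = np.random.SeedSequence(spec.seed)
    total_masked = int(mask.sum())
    converged = False
    msc = np.inf
    it = 0
    for it in range(1, spec.rf_max_iter + 1):
        delta = 0.0
        for j in order:
            obs = ~mask[:, j]
            mis = mask[:, j]
            preds = predictors[j]
            rf_seed = int(
                np.random.SeedSequence([spec.seed, it, int(j)]).generate_state(1)[0]
                % 2**31
            )
            rf = RandomForestRegressor(
                n_estimators=spec.rf_n_trees,
                max_features="sqrt",
                min_samples_leaf=3,
                random_state=rf_seed,
                n_jobs=1,
            )
            rf.fit(X[np.ix_(obs, preds)], X[obs, j])
            new = np.clip(rf.predict(X[np.ix_(mis, preds)]), 0.0, 2.0)
            delta += float(np.sum((new - X[mis, j]) ** 2))
            X[mis, j] = new
        msc = delta / total_masked
        if msc < spec.rf_tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Random-Forest imputation did not converge in {spec.rf_max_iter} "
            f"sweeps (mean squared change {msc:.3e}); returning last iterate",
            stacklevel=2,
        )
    out.meta["imputation"] = {
        "method": "random_forest",
        "iterations": it,
        "converged": converged,
        "mean_squared_change": msc,
        "seed": spec.seed,
    }
    # observed entries were never written; assert the contract cheaply
    assert np.array_equal(out.dosages[~mask], m.dosages[~mask])
    return out


def impute(m: MarkerMatrix, spec: ImputationSpec) -> MarkerMatrix:
    """Dispatch on ``spec.method``."""
    if spec.method == "naive":
        return impute_naive(m)
    return impute_random_forest(m, spec)


def imputation_error(
    truth: MarkerMatrix | np.ndarray,
    imputed: MarkerMatrix | np.ndarray,
    mask: np.ndarray,
) -> float:
    """RMSE between true and imputed dosages over the masked entries only."""
    t = truth.dosages if isinstance(truth, MarkerMatrix) else np.asarray(truth, float)
    x = imputed.dosages if isinstance(imputed, MarkerMatrix) else np.asarray(imputed, float)
    mask = np.asarray(mask, dtype=bool)
    if t.shape != x.shape or mask.shape != t.shape:
        raise ValueError("truth, imputed and mask must share one shape")
    if not mask.any():
        raise ValueError("mask selects no entries")
    diff = t[mask] - x[mask]
    return float(np.sqrt(np.mean(diff**2)))
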