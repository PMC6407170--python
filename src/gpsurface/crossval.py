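"""Repeated k-fold cross-validated prediction accuracy.

Accuracy is the Pearson correlation between the observed (adjusted)
phenotypes and the out-of-fold predicted genetic values.  Each replicate
re-partitions the lines, re-estimates variance components on every
training set (no leakage into the held-out fold), pools the n out-of-fold
predictions, and contributes one correlation; the mean and SD are taken
over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import GenomicRelationship, PhenotypeVector
from .gblup import estimate_variance_components, fit_gblup

__all__ = ["CVConfig", "AccuracyResult", "make_folds", "pearson", "cv_accuracy"]

_POOLING = ("per_replicate_pooled", "per_fold")


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 10
    n_replicates: int = 200
    seed: int = 0
    accuracy_pooling: str = "per_replicate_pooled"

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.accuracy_pooling not in _POOLING:
            raise ValueError(f"accuracy_pooling must be one of {_POOLING}")


@dataclass
class AccuracyResult:
    mean_accuracy: float
    sd_accuracy: float
    per_replicate: np.ndarray
    n_dropped: int = 0

    @property
    def n_replicates(self) -> int:
        return self.per_replicate.size


def make_folds(n: int, k: int, seed) -> np.ndarray:
    """Random partition of ``n`` lines into ``k`` folds of near-equal size.

    ``seed`` may be an int or a numpy Generator.  Fold sizes differ by at
    most one; returns the fold label of each line.
    """
    if k > n:
        raise ValueError(f"k_folds = {k} exceeds the number of lines {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


def pearson(obs, pred) -> float:
    """Product-moment correlation; NaN (with a warning) if either input is
    constant, so degenerate folds can be excluded from pooling."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size != pred.size or obs.size < 3:
        raise ValueError("pearson needs two equal-length vectors of size >= 3")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        warnings.warn("constant vector in correlation; returning NaN", stacklevel=2)
        return float("nan")
    a = obs - obs.mean()
    b = pred - pred.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def _one_replicate(
    y: PhenotypeVector, G: GenomicRelationship, cfg: CVConfig, rep_seed
) -> float:
    n = y.n_lines
    folds = make_folds(n, cfg.k_folds, rep_seed)
    preds = np.empty(n)
    fold_corrs = []
    for f in range(cfg.k_folds):
        test = folds == f
        train = np.flatnonzero(~test)
        vc = estimate_variance_components(y.subset(train), G.subset(train))
        fit = fit_gblup(y.with_mask(test), G, vc)
        preds[test] = fit.g_hat[test]
        if cfg.accuracy_pooling == "per_fold":
            fold_corrs.append(pearson(y.values[test], fit.g_hat[test]))
    if cfg.accuracy_pooling == "per_fold":
        return float(np.nanmean(fold_corrs))
    return pearson(y.values, preds)


def cv_accuracy(
    y: PhenotypeVector, G: GenomicRelationship, cfg: CVConfig
) -> AccuracyResult:
    """Repeated k-fold CV accuracy: mean and SD over replicates.

    Replicate r draws its fold partition from a seed derived from
    ``(cfg.seed, r)``, so any replicate is reproducible in isolation.
    Replicates whose model fits fail, or whose correlation is undefined,
    are dropped with a warning.
    """
    if y.n_lines != G.n_lines or not np.array_equal(y.line_ids, G.line_ids):
        raise ValueError("phenotype and relationship matrix are not aligned")
    corrs = []
    dropped = 0
    for r in range(cfg.n_replicates):
        rep_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, r]))
        try:
            c = _one_replicate(y, G, cfg, rep_rng)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"replicate {r} dropped: {exc}", stacklevel=2)
            dropped += 1
            continue
        if np.isnan(c):
            warnings.warn(f"replicate {r} dropped: undefined correlation", stacklevel=2)
            dropped += 1
            continue
        corrs.append(c)
    if not corrs:
        raise ValueError("every cross-validation replicate failed")
    arr = np.asarray(corrs)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return AccuracyResult(
        mean_accuracy=float(arr.mean()),
        sd_accuracy=sd,
        per_replicate=arr,
        n_dropped=dropped,
    )
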