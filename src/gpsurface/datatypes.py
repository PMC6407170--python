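"""Core data containers shared across the pipeline.

Dosages count copies of the alternate allele at a biallelic SNP: raw calls
are 0, 1 or 2 and missing calls are NaN.  Imputed matrices may hold real
values anywhere in [0, 2] (mean-dosage and Random-Forest imputation both
produce continuous dosages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerMatrix",
    "PhenotypeVector",
    "GenomicRelationship",
    "VarianceComponents",
    "GBLUPFit",
]


def _check_ids(ids, name: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if len(set(arr.tolist())) != arr.size:
        raise ValueError(f"duplicate entries in {name}")
    return arr


@dataclass
class MarkerMatrix:
    """Lines x markers dosage matrix with an explicit missing mask (NaN).

    Parameters
    ----------
    line_ids, marker_ids
        Unique ordered identifiers for rows and columns.
    dosages
        ``(n_lines, n_markers)`` float array; NaN marks a missing call,
        non-missing values must lie in [0, 2].
    chrom, pos
        Optional per-marker coordinates (1-based positions, as in the
        source formats).
    truth
        Optional complete dosage matrix kept aside when missingness is
        introduced synthetically; used to score imputation error.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    truth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.line_ids = _check_ids(self.line_ids, "line_ids")
        self.marker_ids = _check_ids(self.marker_ids, "marker_ids")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array (lines x markers)")
        n, p = self.dosages.shape
        if n != self.line_ids.size or p != self.marker_ids.size:
            raise ValueError(
                f"dosages shape {self.dosages.shape} does not match "
                f"{self.line_ids.size} lines x {self.marker_ids.size} markers"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        for name in ("chrom", "pos"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.size != p:
                    raise ValueError(f"{name} length must equal n_markers")
                setattr(self, name, v)
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != self.dosages.shape:
                raise ValueError("truth channel must match dosages shape")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.dosages).any()

    def copy(self) -> "MarkerMatrix":
        return MarkerMatrix(
            line_ids=self.line_ids.copy(),
            marker_ids=self.marker_ids.copy(),
            dosages=self.dosages.copy(),
            chrom=None if self.chrom is None else self.chrom.copy(),
            pos=None if self.pos is None else self.pos.copy(),
            truth=None if self.truth is None else self.truth.copy(),
            meta=dict(self.meta),
        )

    def subset_markers(self, idx) -> "MarkerMatrix":
        idx = np.asarray(idx)
        return MarkerMatrix(
            line_ids=self.line_ids.copy(),
            marker_ids=self.marker_ids[idx],
            dosages=self.dosages[:, idx],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
            truth=None if self.truth is None else self.truth[:, idx],
            meta=dict(self.meta),
        )

    def subset_lines(self, idx) -> "MarkerMatrix":
        idx = np.asarray(idx)
        return MarkerMatrix(
            line_ids=self.line_ids[idx],
            marker_ids=self.marker_ids.copy(),
            dosages=self.dosages[idx, :],
            chrom=None if self.chrom is None else self.chrom.copy(),
            pos=None if self.pos is None else self.pos.copy(),
            truth=None if self.truth is None else self.truth[idx, :],
            meta=dict(self.meta),
        )


@dataclass
class PhenotypeVector:
    """Per-line trait values with an optional prediction mask.

    ``prediction_mask[i] = True`` hides line *i*'s phenotype from model
    fitting; its genetic value is then predicted from relatives only.
    """

    line_ids: np.ndarray
    values: np.ndarray
    prediction_mask: np.ndarray | None = None
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.line_ids = _check_ids(self.line_ids, "line_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.line_ids.size,):
            raise ValueError("values length must equal line_ids length")
        if self.prediction_mask is None:
            self.prediction_mask = np.zeros(self.values.size, dtype=bool)
        else:
            self.prediction_mask = np.asarray(self.prediction_mask, dtype=bool)
            if self.prediction_mask.shape != self.values.shape:
                raise ValueError("prediction_mask length must equal values length")

    @property
    def n_lines(self) -> int:
        return self.values.size

    @property
    def observed_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.prediction_mask)

    @property
    def masked_idx(self) -> np.ndarray:
        return np.flatnonzero(self.prediction_mask)

    def with_mask(self, mask) -> "PhenotypeVector":
        return PhenotypeVector(
            line_ids=self.line_ids.copy(),
            values=self.values.copy(),
            prediction_mask=np.asarray(mask, dtype=bool).copy(),
            trait_name=self.trait_name,
        )

    def subset(self, idx) -> "PhenotypeVector":
        idx = np.asarray(idx)
        return PhenotypeVector(
            line_ids=self.line_ids[idx],
            values=self.values[idx],
            prediction_mask=self.prediction_mask[idx],
            trait_name=self.trait_name,
        )


@dataclass
class GenomicRelationship:
    """Symmetric n x n genomic relationship (kinship) matrix G = XX'/p."""

    matrix: np.ndarray
    line_ids: np.ndarray
    p_markers: int

    def __post_init__(self) -> None:
        self.line_ids = _check_ids(self.line_ids, "line_ids")
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.line_ids.size
        if self.matrix.shape != (n, n):
            raise ValueError("G must be square and match line_ids")
        scale = max(np.abs(self.matrix).max(), 1.0)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-8 * scale:
            raise ValueError("G must be symmetric")
        # enforce exact symmetry for downstream eigendecompositions
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    def subset(self, idx) -> "GenomicRelationship":
        idx = np.asarray(idx)
        return GenomicRelationship(
            matrix=self.matrix[np.ix_(idx, idx)],
            line_ids=self.line_ids[idx],
            p_markers=self.p_markers,
        )


@dataclass
class VarianceComponents:
    """REML estimates for the additive model y = 1*mu + g + e.

    ``sigma_g2`` is the genetic variance of g ~ N(0, G sigma_g2) and
    ``sigma_e2`` the residual variance; the per-marker effect variance is
    sigma_g2 / p_markers under the G = XX'/p scaling.
    """

    sigma_g2: float
    sigma_e2: float
    log_likelihood: float = float("nan")
    boundary: str | None = None  # "lower" (h2 ~ 0) or "upper" (h2 ~ 1)

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return 0.0 if tot == 0 else self.sigma_g2 / tot

    @property
    def shrinkage(self) -> float:
        """lambda = sigma_e2 / sigma_g2 (inf when sigma_g2 = 0)."""
        return np.inf if self.sigma_g2 == 0 else self.sigma_e2 / self.sigma_g2


@dataclass
class GBLUPFit:
    """Fitted mean and per-line predicted genetic values (all lines)."""

    mu_hat: float
    g_hat: np.ndarray
    vc: VarianceComponents
    line_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g_hat = np.asarray(self.g_hat, dtype=float)
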