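"""Per-marker quality control: MAF, missingness, threshold filters and the
marker-count surface over a MAF x missingness grid.

Conventions
-----------
* MAF is computed from non-missing calls only; a heterozygote contributes
  one minor allele to the tally.  Markers with zero non-missing calls get
  MAF 0 and are flagged (`no_calls`), so any positive MAF cut-off removes
  them and no NaN propagates.
* The per-marker missing fraction (the "PMMS" axis) is
  ``(# missing calls) / n_lines``.
* A marker survives the filter iff ``maf >= maf_min`` and
  ``pmms <= pmms_max`` (inclusive on both sides).
* Stats are computed once on the raw, pre-imputation calls; downstream
  imputation never changes which markers a threshold pair keeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MarkerMatrix, PhenotypeVector

__all__ = [
    "MarkerStats",
    "QCGrid",
    "compute_marker_stats",
    "filter_markers",
    "marker_count_surface",
    "adjust_phenotype",
    "marker_stats_frame",
]


@dataclass
class MarkerStats:
    """Per-marker minor-allele frequency and missing fraction."""

    maf: np.ndarray
    pmms: np.ndarray
    n_called: np.ndarray
    no_calls: np.ndarray  # True where every call is missing (maf set to 0)

    @property
    def n_markers(self) -> int:
        return self.maf.size


@dataclass(frozen=True)
class QCGrid:
    """Ordered MAF cut-offs and missingness cut-offs (as fractions)."""

    maf_levels: tuple
    pmms_levels: tuple

    def __post_init__(self) -> None:
        maf = np.asarray(self.maf_levels, dtype=float)
        pmms = np.asarray(self.pmms_levels, dtype=float)
        if maf.size == 0 or pmms.size == 0:
            raise ValueError("grid levels must be non-empty")
        if np.any(np.diff(maf) <= 0) or np.any(np.diff(pmms) <= 0):
            raise ValueError("grid levels must be strictly increasing")
        if maf.min() < 0 or maf.max() > 0.5:
            raise ValueError("MAF levels must lie in [0, 0.5]")
        if pmms.min() < 0 or pmms.max() > 1:
            raise ValueError("missingness levels must lie in [0, 1]")
        object.__setattr__(self, "maf_levels", tuple(maf))
        object.__setattr__(self, "pmms_levels", tuple(pmms))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.maf_levels), len(self.pmms_levels))

    @property
    def n_cells(self) -> int:
        return len(self.maf_levels) * len(self.pmms_levels)

    @classmethod
    def full_sweep(cls) -> "QCGrid":
        """The full 12 x 27 grid swept in the soybean response-surface
        analysis: MAF cut-offs 0.05-0.40 and missingness cut-offs 1%-80%."""
        maf = (0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
        pmms = tuple(x / 100 for x in list(range(1, 21)) + [25, 30, 40, 50, 60, 70, 80])
        return cls(maf, pmms)


def compute_marker_stats(m: MarkerMatrix) -> MarkerStats:
    """MAF and missing fraction for every marker.

    Allele frequency f = (sum of non-missing dosages) / (2 * n_called);
    maf = min(f, 1 - f).
    """
    if m.n_lines < 1 or m.n_markers < 1:
        raise ValueError("marker matrix must have at least one line and one marker")
    miss = m.missing_mask
    n_called = (~miss).sum(axis=0)
    pmms = miss.sum(axis=0) / m.n_lines
    no_calls = n_called == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(m.dosages, axis=0) / (2.0 * n_called)
    maf = np.minimum(f, 1.0 - f)
    maf[no_calls] = 0.0
    return MarkerStats(maf=maf, pmms=pmms, n_called=n_called, no_calls=no_calls)


def filter_markers(
    m: MarkerMatrix, s: MarkerStats, maf_min: float, pmms_max: float
) -> tuple[MarkerMatrix, np.ndarray]:
    """Keep marker j iff ``maf_j >= maf_min`` and ``pmms_j <= pmms_max``.

    Returns the filtered matrix (line set unchanged) and the kept marker
    indices in original order.  An empty result is legal.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not (0 <= pmms_max <= 1):
        raise ValueError("pmms_max must lie in [0, 1]")
    if s.n_markers != m.n_markers:
        raise ValueError("stats do not match the marker matrix")
    keep = (s.maf >= maf_min) & (s.pmms <= pmms_max)
    kept_idx = np.flatnonzero(keep)
    return m.subset_markers(kept_idx), kept_idx


def marker_count_surface(m: MarkerMatrix | MarkerStats, grid: QCGrid) -> np.ndarray:
    """Marker counts surviving each (maf_min, pmms_max) grid cell.

    Single pass over markers plus 2-D prefix sums, rather than one filter
    per cell: each marker is binned by the number of MAF levels it clears
    and the first missingness level that admits it.
    """
    s = m if isinstance(m, MarkerStats) else compute_marker_stats(m)
    maf_levels = np.asarray(grid.maf_levels)
    pmms_levels = np.asarray(grid.pmms_levels)
    A, B = maf_levels.size, pmms_levels.size

    # marker kept at maf level a iff maf_levels[a] <= maf  (a < ia)
    ia = np.searchsorted(maf_levels, s.maf, side="right")
    # marker kept at pmms level b iff pmms_levels[b] >= pmms  (b >= ib)
    ib = np.searchsorted(pmms_levels, s.pmms, side="left")

    hist = np.zeros((A + 1, B + 1), dtype=np.int64)
    np.add.at(hist, (ia, ib), 1)
    # counts[a, b] = sum_{i > a} sum_{j <= b} hist[i, j]
    suffix_i = np.cumsum(hist[::-1, :], axis=0)[::-1, :]
    prefix_j = np.cumsum(suffix_i, axis=1)
    return prefix_j[1 : A + 1, 0:B]


def adjust_phenotype(raw: pd.DataFrame, trait_name: str = "trait") -> PhenotypeVector:
    """Adjust replicated field records for location and block effects.

    Fits ``value ~ mean + location + block(location) + line`` by least
    squares (minimum-norm solution of the rank-deficient dummy design)
    and returns the line-effect estimates centered to sum to zero.  With a
    single location and block this reduces to centered line means.

    ``raw`` needs columns ``line`` and ``value``; ``location`` and
    ``block`` are optional.
    """
    required = {"line", "value"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise ValueError(f"phenotype table is missing columns: {sorted(missing_cols)}")
    df = raw.dropna(subset=["value"]).copy()
    if df.empty:
        raise ValueError("phenotype table has no usable records")

    lines = pd.unique(df["line"])
    y = df["value"].to_numpy(dtype=float)
    blocks_of_cols: list[np.ndarray] = [np.ones((len(df), 1))]
    if "location" in df.columns:
        blocks_of_cols.append(pd.get_dummies(df["location"]).to_numpy(dtype=float))
        if "block" in df.columns:
            loc_block = df["location"].astype(str) + "//" + df["block"].astype(str)
            blocks_of_cols.append(pd.get_dummies(loc_block).to_numpy(dtype=float))
    line_dummies = pd.get_dummies(df["line"]).reindex(columns=lines, fill_value=0)
    blocks_of_cols.append(line_dummies.to_numpy(dtype=float))

    X = np.hstack(blocks_of_cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    line_eff = beta[-len(lines) :]
    line_eff = line_eff - line_eff.mean()
    return PhenotypeVector(
        line_ids=np.asarray(lines, dtype=object),
        values=line_eff,
        trait_name=trait_name,
    )


def marker_stats_frame(m: MarkerMatrix, s: MarkerStats | None = None) -> pd.DataFrame:
    """Per-marker stats as a tidy frame (marker_id, maf, pmms, n_called)."""
    if s is None:
        s = compute_marker_stats(m)
    return pd.DataFrame(
        {
            "marker_id": m.marker_ids,
            "maf": s.maf,
            "pmms": s.pmms,
            "n_called": s.n_called,
        }
    )
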