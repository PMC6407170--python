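"""The response-surface experiment: accuracy over a MAF x missingness grid.

For every grid cell (maf_min, pmms_max) and every imputation method the
sweep filters the raw marker matrix, imputes what survives, builds the
genomic relationship matrix and estimates accuracy by repeated k-fold
cross-validation.  Cells are independent work units whose randomness is
derived from (master seed, cell index, method index), so any execution
order — or a restart — reproduces identical records.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crossval import CVConfig, cv_accuracy
from .datatypes import MarkerMatrix, PhenotypeVector
from .gblup import build_grm
from .impute import ImputationSpec, impute
from .qc import QCGrid, compute_marker_stats, filter_markers

__all__ = [
    "SurfaceResult",
    "PeakReport",
    "MethodComparison",
    "run_surface",
    "find_peak",
    "compare_methods",
]

log = logging.getLogger(__name__)

_COLUMNS = [
    "trait",
    "method",
    "maf",
    "pmms",
    "n_markers",
    "mean_accuracy",
    "sd_accuracy",
    "n_replicates",
    "status",
]


@dataclass
class SurfaceResult:
    """Long table of per-cell results plus the grid that produced it."""

    records: pd.DataFrame
    grid: QCGrid
    methods: tuple

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records are missing columns: {sorted(missing)}")
        self.records = self.records[_COLUMNS].reset_index(drop=True)

    @property
    def ok(self) -> pd.DataFrame:
        return self.records[self.records["status"] == "ok"]

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: QCGrid, methods=None) -> "SurfaceResult":
        df = pd.read_csv(path)
        if methods is None:
            methods = tuple(pd.unique(df["method"]))
        return cls(records=df, grid=grid, methods=tuple(methods))


@dataclass
class PeakReport:
    """Best cell per trait x method (highest mean accuracy; ties go to the
    cell needing fewest markers, then lowest MAF cut, then lowest
    missingness cut)."""

    peaks: pd.DataFrame

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.peaks.to_dict(orient="records"), fh, indent=2)


@dataclass
class MethodComparison:
    delta: pd.DataFrame  # per-cell accuracy difference (method_b - method_a)
    method_a: str
    method_b: str
    peak_marker_ratio: float  # markers at B's peak / markers at A's peak
    flatness_sd: dict = field(default_factory=dict)  # method -> SD of cell means


def _method_labels(methods) -> list[str]:
    labels = []
    for i, spec in enumerate(methods):
        base = spec.method
        labels.append(base if base not in labels else f"{base}_{i}")
    return labels


def run_surface(
    m: MarkerMatrix,
    y: PhenotypeVector,
    grid: QCGrid,
    methods,
    cv: CVConfig,
    min_markers: int = 10,
    checkpoint=None,
) -> SurfaceResult:
    """Evaluate accuracy at every (maf, pmms) x method combination.

    Cells with no surviving markers get status ``empty``; cells with
    fewer than ``min_markers`` get ``degenerate``; any per-cell failure
    is recorded as ``failed`` and never aborts the sweep.  When
    ``checkpoint`` names a CSV path, finished records are appended there
    after each cell and an interrupted sweep resumes from it.
    """
    if not np.array_equal(m.line_ids, y.line_ids):
        raise ValueError("marker matrix and phenotype are not aligned on line_ids")
    methods = tuple(methods)
    if not methods:
        raise ValueError("at least one imputation method is required")
    labels = _method_labels(methods)

    done: dict[tuple, dict] = {}
    if checkpoint is not None:
        try:
            prev = pd.read_csv(checkpoint)
            for rec in prev.to_dict(orient="records"):
                done[(rec["trait"], rec["method"], rec["maf"], rec["pmms"])] = rec
            log.info("resuming sweep: %d records found in %s", len(done), checkpoint)
        except FileNotFoundError:
            pass

    stats = compute_marker_stats(m)
    records: list[dict] = []
    cell = -1
    t0 = time.monotonic()
    for maf in grid.maf_levels:
        for pmms in grid.pmms_levels:
            cell += 1
            filtered, kept = filter_markers(m, stats, maf, pmms)
            n_markers = int(kept.size)
            imputed_cache: dict[int, MarkerMatrix] = {}
            for mi, (spec, label) in enumerate(zip(methods, labels)):
                key = (y.trait_name, label, float(maf), float(pmms))
                if key in done:
                    records.append(done[key])
                    continue
                rec = {
                    "trait": y.trait_name,
                    "method": label,
                    "maf": float(maf),
                    "pmms": float(pmms),
                    "n_markers": n_markers,
                    "mean_accuracy": np.nan,
                    "sd_accuracy": np.nan,
                    "n_replicates": 0,
                    "status": "ok",
                }
                if n_markers == 0:
                    rec["status"] = "empty"
                elif n_markers < min_markers:
                    rec["status"] = "degenerate"
                else:
                    seeds = np.random.SeedSequence([cv.seed, cell, mi]).generate_state(2)
                    try:
                        if mi in imputed_cache:
                            completed = imputed_cache[mi]
                        else:
                            cell_spec = replace(spec, seed=int(seeds[0] % 2**31))
                            completed = impute(filtered, cell_spec)
                            imputed_cache[mi] = completed
                        G = build_grm(completed)
                        acc = cv_accuracy(y, G, replace(cv, seed=int(seeds[1] % 2**31)))
                        rec.update(
                            mean_accuracy=acc.mean_accuracy,
                            sd_accuracy=acc.sd_accuracy,
                            n_replicates=acc.n_replicates,
                        )
                    except (ValueError, np.linalg.LinAlgError) as exc:
                        rec["status"] = f"failed: {exc}"
                records.append(rec)
                if checkpoint is not None:
                    write_header = not Path(checkpoint).exists()
                    pd.DataFrame([rec]).to_csv(
                        checkpoint, mode="a", header=write_header, index=False
                    )
            log.info(
                "cell %d/%d (maf=%.2f, pmms=%.2f): %d markers, %.1fs elapsed",
                cell + 1, grid.n_cells, maf, pmms, n_markers, time.monotonic() - t0,
            )
    return SurfaceResult(
        records=pd.DataFrame(records), grid=grid, methods=tuple(labels)
    )


def find_peak(s: SurfaceResult) -> PeakReport:
    """Highest-accuracy cell per trait x method, with deterministic ties."""
    ok = s.ok
    if ok.empty:
        raise ValueError("no successful cells to search for a peak")
    rows = []
    for (trait, method), grp in ok.groupby(["trait", "method"], sort=True):
        ordered = grp.sort_values(
            by=["mean_accuracy", "n_markers", "maf", "pmms"],
            ascending=[False, True, True, True],
            kind="mergesort",
        )
        best = ordered.iloc[0]
        rows.append(
            {
                "trait": trait,
                "method": method,
                "maf": best["maf"],
                "pmms": best["pmms"],
                "mean_accuracy": best["mean_accuracy"],
                "sd_accuracy": best["sd_accuracy"],
                "n_markers": int(best["n_markers"]),
            }
        )
    return PeakReport(peaks=pd.DataFrame(rows))


def compare_methods(
    s: SurfaceResult, method_a: str | None = None, method_b: str | None = None
) -> MethodComparison:
    """Per-cell accuracy difference (B - A), marker counts at each
    method's own peak, and a flatness summary (SD of cell means)."""
    methods = list(s.methods)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    method_a = method_a or methods[0]
    method_b = method_b or methods[1]
    for name in (method_a, method_b):
        if name not in methods:
            raise ValueError(f"unknown method {name!r}")

    a = s.records[s.records["method"] == method_a]
    b = s.records[s.records["method"] == method_b]
    merged = a.merge(
        b, on=["trait", "maf", "pmms"], suffixes=("_a", "_b"), validate="one_to_one"
    )
    if len(merged) != len(a) or len(a) != len(b):
        raise ValueError("methods were evaluated on mismatched grids")
    delta = merged[["trait", "maf", "pmms"]].copy()
    delta["delta_accuracy"] = merged["mean_accuracy_b"] - merged["mean_accuracy_a"]

    peaks = find_peak(s).peaks
    ratios = []
    for trait in pd.unique(peaks["trait"]):
        pa = peaks[(peaks["trait"] == trait) & (peaks["method"] == method_a)]
        pb = peaks[(peaks["trait"] == trait) & (peaks["method"] == method_b)]
        if len(pa) and len(pb) and pa["n_markers"].iloc[0] > 0:
            ratios.append(pb["n_markers"].iloc[0] / pa["n_markers"].iloc[0])
    peak_ratio = float(np.mean(ratios)) if ratios else float("nan")

    flat = {
        meth: float(grp["mean_accuracy"].std(ddof=1))
        for meth, grp in s.ok.groupby("method")
    }
    return MethodComparison(
        delta=delta,
        method_a=method_a,
        method_b=method_b,
        peak_marker_ratio=peak_ratio,
        flatness_sd=flat,
    )
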