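"""Readers and writers for the formats the pipeline exchanges.

Genotypes come in as VCF (via cyvcf2), HapMap-style TSV, or a plain
dosage CSV (first column line ids, header row marker ids, empty/NA cells
missing).  Dosage orientation for VCF is the count of ALT alleles; MAF is
orientation-free since it takes min(f, 1 - f).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MarkerMatrix

__all__ = [
    "read_genotypes",
    "read_dosage_csv",
    "write_dosage_csv",
    "read_vcf",
    "read_hapmap",
    "read_phenotypes",
    "write_phenotypes",
]

log = logging.getLogger(__name__)

_IUPAC_HET = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("G", "C"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}


def read_genotypes(path, format: str) -> MarkerMatrix:
    """Dispatch on ``format`` in {"vcf", "hapmap", "dosage_csv"}."""
    readers = {"vcf": read_vcf, "hapmap": read_hapmap, "dosage_csv": read_dosage_csv}
    if format not in readers:
        raise ValueError(f"format must be one of {sorted(readers)}, got {format!r}")
    return readers[format](path)


def read_dosage_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: zero markers")
    dosages = df.to_numpy(dtype=float)
    return MarkerMatrix(
        line_ids=np.asarray(df.index, dtype=object),
        marker_ids=np.asarray(df.columns, dtype=object),
        dosages=dosages,
    )


def write_dosage_csv(m: MarkerMatrix, path) -> None:
    pd.DataFrame(m.dosages, index=m.line_ids, columns=m.marker_ids).to_csv(
        path, index_label="line_id"
    )


def read_vcf(path) -> MarkerMatrix:
    """Biallelic SNP records only; GT mapped to ALT-allele dosage, missing
    genotypes to NaN.  Multi-allelic or non-SNP records are skipped and
    counted."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    marker_ids, chroms, poss, rows = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dose)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: zero usable biallelic SNP records")
    if n_skipped:
        log.warning("%s: skipped %d multi-allelic/non-SNP records", path, n_skipped)
    m = MarkerMatrix(
        line_ids=samples,
        marker_ids=np.asarray(marker_ids, dtype=object),
        dosages=np.vstack(rows).T,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
    )
    m.meta["n_skipped_records"] = n_skipped
    return m


def _hapmap_call_to_alleles(call: str) -> tuple[str, str] | None:
    call = call.strip().upper()
    if call in ("NN", "N", "", "NA", "--", "-"):
        return None
    if len(call) == 2:
        return call[0], call[1]
    if len(call) == 1:
        if call in _IUPAC_HET:
            return _IUPAC_HET[call]
        return call, call  # homozygous single-letter call
    raise ValueError(f"unparseable HapMap genotype call {call!r}")


def read_hapmap(path) -> MarkerMatrix:
    """HapMap-style TSV: 11 metadata columns (rs#, alleles, chrom, pos, ...)
    then one column per line.  Calls are letter pairs ("AA") or single
    IUPAC codes; dosage counts the non-major allele per marker."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 HapMap columns, found {df.shape[1]}")
    meta_cols = df.columns[:11]
    sample_cols = df.columns[11:]
    if df.shape[0] == 0:
        raise ValueError(f"{path}: zero markers")

    dosages = np.full((len(sample_cols), len(df)), np.nan)
    for j, (_, row) in enumerate(df.iterrows()):
        calls = [_hapmap_call_to_alleles(row[c]) for c in sample_cols]
        tally: dict[str, int] = {}
        for pair in calls:
            if pair is not None:
                for a in pair:
                    tally[a] = tally.get(a, 0) + 1
        if not tally:
            continue  # all calls missing; stays NaN, flagged later by QC
        major = max(sorted(tally), key=lambda a: tally[a])
        for i, pair in enumerate(calls):
            if pair is not None:
                dosages[i, j] = sum(1 for a in pair if a != major)

    return MarkerMatrix(
        line_ids=np.asarray(sample_cols, dtype=object),
        marker_ids=df[meta_cols[0]].to_numpy(dtype=object),
        dosages=dosages,
        chrom=df[meta_cols[2]].to_numpy(dtype=object),
        pos=pd.to_numeric(df[meta_cols[3]], errors="coerce").to_numpy(),
    )


def read_phenotypes(path, genotype_lines=None) -> pd.DataFrame:
    """Phenotype CSV with at least (line, value); location/block/trait
    columns pass through.  Records for lines absent from the genotype
    matrix are dropped with a warning."""
    df = pd.read_csv(path)
    missing = {"line", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if genotype_lines is not None:
        known = set(np.asarray(genotype_lines, dtype=object).tolist())
        unknown = sorted(set(df["line"]) - known)
        if unknown:
            warnings.warn(
                f"{len(unknown)} phenotype line(s) absent from the genotype "
                f"matrix were dropped: {unknown[:5]}",
                stacklevel=2,
            )
            df = df[df["line"].isin(known)]
    return df.reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
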