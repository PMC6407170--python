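"""Synthetic inbred-line SNP panels with LD, missingness and additive traits.

The generator emulates the structure a genotyping-by-sequencing panel of
inbred lines presents to a genomic-prediction pipeline:

* biallelic dosages in {0, 1, 2} with a controllable allele-frequency
  spectrum,
* linkage disequilibrium as block-correlated markers (latent Gaussian
  copula, equicorrelation ``ld_rho`` within blocks of ``ld_block_size``),
* a high homozygosity rate (``inbreeding``) as found in selfing crops,
* per-marker missing-completely-at-random call rates drawn from a
  configurable distribution (GBS panels show strongly heterogeneous
  per-marker missingness, which is exactly what per-marker missingness
  filters act on),
* additive phenotypes from ``n_qtl`` loci with sample-exact heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .datatypes import MarkerMatrix, PhenotypeVector

__all__ = [
    "RateSpec",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "apply_missingness",
    "simulate_phenotype",
    "simulate_dataset",
]


@dataclass(frozen=True)
class RateSpec:
    """Distribution of per-marker missing-call fractions.

    Supported kinds: ``constant(r)``, ``uniform(lo, hi)`` and
    ``beta(a, b, scale)`` (a Beta(a, b) draw multiplied by ``scale``).
    All draws must land in [0, 1].
    """

    kind: str
    params: tuple

    @classmethod
    def constant(cls, rate: float) -> "RateSpec":
        return cls("constant", (float(rate),))

    @classmethod
    def uniform(cls, low: float, high: float) -> "RateSpec":
        return cls("uniform", (float(low), float(high)))

    @classmethod
    def beta(cls, a: float, b: float, scale: float = 1.0) -> "RateSpec":
        return cls("beta", (float(a), float(b), float(scale)))

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "uniform", "beta"):
            raise ValueError(f"unknown rate spec kind {self.kind!r}")
        if self.kind == "constant":
            (r,) = self.params
            if not 0 <= r <= 1:
                raise ValueError("missing rate must lie in [0, 1]")
        elif self.kind == "uniform":
            lo, hi = self.params
            if not (0 <= lo <= hi <= 1):
                raise ValueError("uniform rate bounds must satisfy 0 <= low <= high <= 1")
        else:
            a, b, scale = self.params
            if a <= 0 or b <= 0 or not 0 <= scale <= 1:
                raise ValueError("beta rate spec needs a, b > 0 and scale in [0, 1]")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, self.params[0])
        if self.kind == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size)
        a, b, scale = self.params
        return scale * rng.beta(a, b, size)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: ~300 inbred lines, mostly-homozygous dosages,
    per-marker missingness spread over 0-80% (the range the missingness
    filter sweeps), and a moderately polygenic trait at h2 = 0.5.

    The LD defaults (blocks of 50 markers at latent correlation 0.9) give
    the low effective dimensionality characteristic of a breeding panel
    of closely related lines; an unstructured panel of independent
    markers would under-represent the relatedness genomic prediction
    exploits."""

    n_lines: int = 301
    n_markers: int = 5000
    maf_lower: float = 0.05
    maf_upper: float = 0.5
    ld_block_size: int = 50
    ld_rho: float = 0.9
    inbreeding: float = 0.95
    missing_rates: RateSpec = field(default_factory=lambda: RateSpec.uniform(0.0, 0.8))
    n_qtl: int = 300
    h2: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be positive")
        if self.n_markers < 1:
            raise ValueError("n_markers must be positive")
        if not (0 < self.maf_lower <= self.maf_upper <= 0.5):
            raise ValueError("maf_lower/maf_upper must satisfy 0 < lower <= upper <= 0.5")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be positive")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0 <= self.inbreeding <= 1):
            raise ValueError("inbreeding must lie in [0, 1]")
        if not (0 <= self.h2 <= 1):
            raise ValueError("h2 must lie in [0, 1]")
        if not (1 <= self.n_qtl <= self.n_markers):
            raise ValueError("n_qtl must satisfy 1 <= n_qtl <= n_markers")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated trait, for parameter-recovery tests."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_genetic_values: np.ndarray
    realized_h2: float


def simulate_genotypes(config: SimulationConfig) -> MarkerMatrix:
    """Draw a complete {0,1,2} dosage matrix.

    Each marker's alternate-allele frequency is uniform on
    ``[maf_lower, maf_upper]``.  Alleles come from thresholding a latent
    Gaussian that is equicorrelated (``ld_rho``) within consecutive blocks
    of ``ld_block_size`` markers, which induces dosage correlation (LD)
    within blocks and independence across blocks.  With probability
    ``inbreeding`` a genotype is forced homozygous by copying its first
    allele.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_lines, config.n_markers

    freqs = rng.uniform(config.maf_lower, config.maf_upper, p)
    thresh = norm.ppf(freqs)
    block_of = np.arange(p) // config.ld_block_size
    n_blocks = block_of[-1] + 1
    rho = config.ld_rho

    alleles = np.empty((2, n, p), dtype=bool)
    for h in range(2):
        u = rng.standard_normal((n, n_blocks))
        eps = rng.standard_normal((n, p))
        z = np.sqrt(rho) * u[:, block_of] + np.sqrt(1.0 - rho) * eps
        alleles[h] = z < thresh[None, :]

    dosages = alleles[0].astype(np.int64) + alleles[1].astype(np.int64)
    if config.inbreeding > 0:
        hom = rng.random((n, p)) < config.inbreeding
        dosages[hom] = 2 * alleles[0][hom]

    line_ids = np.array([f"L{i + 1:04d}" for i in range(n)], dtype=object)
    marker_ids = np.array([f"M{j + 1:06d}" for j in range(p)], dtype=object)
    return MarkerMatrix(
        line_ids=line_ids,
        marker_ids=marker_ids,
        dosages=dosages.astype(float),
        chrom=(block_of + 1).astype(np.int64),
        pos=(np.arange(p, dtype=np.int64) % config.ld_block_size) * 1000 + 1,
    )


def apply_missingness(
    m: MarkerMatrix, missing_rates: RateSpec, seed: int
) -> MarkerMatrix:
    """Mask entries MCAR within each marker at a per-marker rate drawn
    from ``missing_rates``; the complete matrix is retained in ``truth``."""
    if not m.is_complete:
        raise ValueError("apply_missingness expects a complete matrix")
    rng = np.random.default_rng(seed)
    rates = missing_rates.draw(rng, m.n_markers)
    if rates.min() < 0 or rates.max() > 1:
        raise ValueError("drawn missing rates must lie in [0, 1]")
    mask = rng.random(m.dosages.shape) < rates[None, :]
    out = m.copy()
    out.truth = m.dosages.copy()
    dos = out.dosages
    dos[mask] = np.nan
    return out


def simulate_phenotype(
    m: MarkerMatrix, n_qtl: int, h2: float, seed: int, trait_name: str = "trait"
) -> tuple[PhenotypeVector, SimulationTruth]:
    """Additive phenotype y = g + e with sample-exact heritability.

    ``n_qtl`` markers are drawn as causal loci with i.i.d. N(0, 1)
    effects; g is the centered sum of dosage x effect.  The residual is
    orthogonalized against g in-sample and scaled so that
    Var(g) / (Var(g) + Var(e)) equals ``h2`` exactly on the realized
    sample (hence also Var(g) / Var(y), since g ⟂ e).
    """
    if not m.is_complete:
        raise ValueError("simulate_phenotype expects a complete matrix")
    if not (1 <= n_qtl <= m.n_markers):
        raise ValueError("n_qtl must satisfy 1 <= n_qtl <= n_markers")
    if not (0 <= h2 <= 1):
        raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = m.n_lines

    qtl = np.sort(rng.choice(m.n_markers, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    g = m.dosages[:, qtl] @ effects
    g = g - g.mean()
    var_g = float(g @ g) / n

    if h2 == 0:
        g = np.zeros(n)
        e = rng.standard_normal(n)
        e = e - e.mean()
        y = e
        realized = 0.0
    else:
        if var_g == 0:
            raise ValueError(
                "all selected QTL are monomorphic: zero genetic variance "
                f"is incompatible with h2 = {h2}"
            )
        if h2 == 1:
            e = np.zeros(n)
        else:
            e = rng.standard_normal(n)
            e = e - e.mean()
            e = e - (e @ g) / (g @ g) * g  # exact in-sample orthogonality
            var_e_target = var_g * (1.0 - h2) / h2
            e = e * np.sqrt(var_e_target / (float(e @ e) / n))
        y = g + e
        var_e = float(e @ e) / n
        realized = var_g / (var_g + var_e)

    pheno = PhenotypeVector(
        line_ids=m.line_ids.copy(), values=y, trait_name=trait_name
    )
    truth = SimulationTruth(
        qtl_indices=qtl,
        qtl_effects=effects,
        true_genetic_values=g,
        realized_h2=realized,
    )
    return pheno, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[MarkerMatrix, MarkerMatrix, PhenotypeVector, SimulationTruth]:
    """Convenience wrapper: (complete panel, masked panel, phenotype, truth).

    Sub-seeds are derived deterministically from ``config.seed`` so every
    stage is independently reproducible.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_geno, s_miss, s_pheno = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    complete = simulate_genotypes(replace(config, seed=s_geno))
    masked = apply_missingness(complete, config.missing_rates, seed=s_miss)
    pheno, truth = simulate_phenotype(complete, config.n_qtl, config.h2, seed=s_pheno)
    return complete, masked, pheno, truth
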