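# Methods

## The problem

Genotyping-by-sequencing (GBS) panels deliver dense SNP calls with large
and strongly heterogeneous per-marker missingness. Before genomic
prediction, the marker matrix is quality-controlled: markers below a
minor-allele-frequency (MAF) cut-off or above a missingness cut-off are
discarded, and the remaining missing calls are imputed. These choices
change both how many markers enter the model and how informative each
one is, and therefore change prediction accuracy. `gpsurface` evaluates
the full response surface of cross-validated prediction accuracy over a
grid of MAF x missingness cut-offs for two imputation methods, and
reports the surface's peak.

## Model

The prediction model is additive G-BLUP:

    y_i = mu + g_i + e_i,      g ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2)

with G = XX'/p built from the n x p dosage matrix X (column-centered
counts of the alternate allele; p is the number of markers after
filtering). Under this scaling sigma_g^2 = p sigma_b^2, where sigma_b^2
is the common variance of per-marker effects, and the G-side mixed-model
solution is algebraically identical to ridge regression on markers with
penalty p lambda, lambda = sigma_e^2 / sigma_g^2. The test-suite checks
this identity to 1e-8 relative error.

Centering: the defining formula G = p^-1 XX' leaves centering
unspecified. We center each marker column by its mean, because
uncentered cross-products conflate allele-frequency scale with
relatedness and the N(0, G sigma_g^2) assumption presumes centered
scores. No per-marker variance standardization is applied — the
divisor is p only.

### REML

Variance components are estimated by restricted maximum likelihood.
After one eigendecomposition G = U D U', the model is rotated to a
diagonal covariance; the total variance profiles out analytically and
the restricted likelihood becomes a 1-D function of
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2). It is maximized by a
101-point grid scan followed by bounded scalar refinement; estimates
within 1e-3 of the boundaries are flagged. A ridge of 1e-8 x mean
diagonal is added to G before every factorization — panels of inbred
lines can contain duplicated rows that make G exactly singular.

Variance components are re-estimated inside every training fold of the
cross-validation, so no information from held-out lines leaks into the
shrinkage level.

### Prediction of held-out lines

With observed set O and masked set M, solving
(G_OO + lambda I) a = y_O - mu and setting g = G[:, O] a yields the
training BLUPs and the masked predictions simultaneously; for
non-singular G_OO this equals the conditional expectation
G_MO G_OO^{-1} g_O, and the suite asserts the agreement of the two
routes. The intercept is the GLS mean within the mixed model, not the
raw mean.

## Quality control

* MAF: frequency of the less common allele among non-missing calls;
  heterozygotes contribute one allele. Markers with zero non-missing
  calls get MAF 0 and a flag, so they are removed by any positive
  cut-off and no NaN propagates.
* Missingness (the "PMMS" axis): fraction of lines with no call at the
  marker.
* A marker survives cell (a, b) iff MAF >= maf_levels[a] and
  missingness <= pmms_levels[b]. Both comparisons are inclusive; the
  alternative strict reading of the missingness cut-off cannot be
  distinguished from published descriptions of such filters, and the
  inclusive convention is documented here as the package's choice.
* Stats are computed once on the raw calls; imputation happens after
  filtering, independently per grid cell, and never changes which
  markers a cell keeps. The marker-count surface is computed in a single
  pass (2-D binning + prefix sums) and is therefore cheap even on the
  full 12 x 27 grid.

Phenotypes recorded across locations and blocks are adjusted by a
fixed-effects least-squares fit
(value ~ mean + location + block-within-location + line) using the
minimum-norm solution of the rank-deficient dummy design; the centered
line effects are the adjusted phenotypes. With one location and block
this reduces to centered line means.

## Imputation

* Naive: each missing call becomes the marker's mean observed dosage
  (real-valued, not rounded). Column means are preserved exactly.
* Random Forest: a missForest-style iterative scheme. Initialize with
  the naive fill; visit markers in decreasing order of missingness; for
  each, fit a Random-Forest regressor of its observed dosages on its
  `rf_k_predictors` most-correlated companion markers (correlations
  ranked once on the initial completion) and predict its missing
  entries, clipped to [0, 2]; sweep until the mean squared change of
  imputed entries falls below `rf_tolerance` or `rf_max_iter` sweeps.
  Non-convergence returns the last iterate with a warning in the result
  metadata. Everything is deterministic under the spec's seed.

Imputed dosages stay continuous; G-matrix construction accepts
real-valued dosages, which avoids an extra rounding rule and matches the
mean-dosage convention of the naive method.

Defaults (`rf_n_trees=100`, `rf_k_predictors=30`, `rf_max_iter=5`,
`rf_tolerance=1e-3`) follow missForest conventions. The bundled
experiment configurations use smaller forests (30 trees, 2 sweeps, 15
predictors); at the panel sizes those experiments run, the extra trees
and sweeps change imputation RMSE marginally while dominating runtime.

## Cross-validation

k-fold (default 10) partitions with fold sizes differing by at most one,
repeated `n_replicates` times. Per replicate, the n out-of-fold
predictions are pooled into one Pearson correlation with the observed
(adjusted) phenotypes; the mean and SD are over replicates. Pooling per
replicate is the package default because per-fold correlations on ~30
lines are noisy; per-fold averaging is retained as an option. Replicate
r draws its partition from a seed derived from (master seed, r), so any
replicate reproduces in isolation. Undefined correlations (constant
vectors) drop the replicate with a warning.

Two statistical facts about this estimator matter when interpreting
values near zero. First, under a pure-noise phenotype its expectation is
slightly negative (about -0.08 at n = 200 with 10 folds): pooled CV
correlations carry a small negative centering bias, and per-fold REML
shrinkage — whose estimate depends on the other folds' observations —
adds to it. Second, the correlation conditional on one phenotype
realization is nearly partition-invariant, so averaging more fold
partitions of the same phenotype does not average this noise away; null
behaviour is only measurable across independent phenotype draws, which
is how the bundled null experiment is constructed.

## The surface sweep

For each cell and method: filter -> impute -> G -> CV accuracy. Cells
keeping no markers are "empty"; cells below a floor (default 10 markers)
are "degenerate" — G-BLUP on a near-empty marker set is meaningless;
failures are recorded per cell and never abort the sweep. All
per-cell randomness derives from (master seed, cell index, method
index), so cells are order-independent and a checkpointed sweep resumes
bit-identically. Peaks are the argmax of mean accuracy with
deterministic ties (fewest markers, then lowest MAF cut, then lowest
missingness cut). Method comparison reports per-cell accuracy
differences, marker counts at each method's own peak, and a flatness
summary (SD of cell mean accuracies per method).

## What the synthetic panels emulate — and what they do not

`SimulationConfig` draws per-marker alternate-allele frequencies from a
uniform spectrum, generates alleles by thresholding a latent Gaussian
that is equicorrelated within consecutive blocks (LD), forces
homozygosity with probability `inbreeding` (default 0.95, emulating
inbred lines), masks calls MCAR within marker at per-marker rates drawn
from a configurable distribution, and builds additive phenotypes whose
in-sample heritability is exact by construction (the residual is
orthogonalized against the genetic values and scaled).

Default LD is strong (blocks of 50 markers at latent correlation 0.9):
a breeding panel of a few hundred closely related lines has far fewer
effective independent segments than markers, and that low effective
dimensionality is what lets n = 300 lines predict at accuracies near
sqrt(h^2). An unstructured panel of independent markers would
under-represent this and depress accuracy far below what real panels
show.

The bundled surface experiments use a right-skewed Beta(2, 1) x 0.8
missing-rate distribution: GBS panels deliver mostly heavily-missing
markers, which is what makes low-missingness cut-offs marker-poor and
high-missingness cells imputation-limited. The experiment grids stay in
the marker-rich regime (every cell keeps roughly a hundred markers or
more) because with desk-scale marker counts, cells below that are
scarcity-dominated — both imputation methods droop identically and the
method contrast is swamped; a full-scale panel never enters that regime.

Not emulated: population structure and maturity groups, selection,
genotype-by-environment interaction, non-MCAR missingness (e.g.
restriction-site polymorphism), and allele-calling error. Passing tests
therefore show the pipeline's statistical machinery is correct under the
stated assumptions, not that any particular real panel will show the
same surface shape.

## Problem sizes

The test-suite and the acceptance script run at desk scale: panels of
60-300 lines and 120-2000 markers, 2-20 CV replicates, and a 3 x 3
experiment grid alongside one full 12 x 27 cardinality check. These
sizes keep the statistical properties measurable (sampling error well
inside the asserted bands) while a full sweep of a 216K-marker panel at
200 replicates is a cluster-scale computation out of scope for the
bundled experiments.

## Known limitations

* RF imputation cost scales with (markers with missing calls) x sweeps;
  the correlation ranking is computed once on the naive completion
  rather than re-ranked per sweep.
* The REML search is 1-D in h^2 and assumes a single genetic variance
  component; multi-kernel or GxE models are out of scope.
* The HapMap reader handles letter-pair and IUPAC single-letter calls
  only; minus-strand encodings and indel alleles are not supported.
* `adjust_phenotype` reports minimum-norm line effects; only contrasts
  among lines are identified in unbalanced designs, which is all the
  downstream correlation-based accuracy uses.
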