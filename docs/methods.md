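# Methods

## Model and estimation

One trait scored on `n` genotyped lines in `l` environments is treated as
`l` correlated traits. Stacking observations environment-major,

    y = Xβ + Zu + ε,   u ~ N(0, G₀ ⊗ K),   ε ~ N(0, R₀ ⊗ I),

with `K` the additive genomic relationship matrix (VanRaden method 1:
`ZZ′ / 2Σpⱼ(1−pⱼ)` on column-centred dosages, sample allele frequencies,
per-marker mean imputation of missing calls), `G₀` the unstructured
between-environment genetic covariance and `R₀` the residual covariance in
one of four shapes (US, ANT1, IDH, IDV). The main-effect + interaction
model (`u + v`, compound symmetry) and the univariate model are special
cases and share all machinery. Fixed effects are per-environment
intercepts (multivariate), a grand mean plus sum-to-zero environment
effects (G×E model; the constraint is ours — the column set alone is rank
deficient), or a single intercept (univariate).

ANT1 is parameterized as standard deviations `σ₁..σ_l` plus adjacent
correlations `ρ₁..ρ_{l−1}`, with `Σᵢⱼ = σᵢσⱼ Π ρₖ` over the lag-1 steps
between `i` and `j`. This is the standard first-order antedependence form:
it has exactly `l + (l−1)` parameters and a tridiagonal inverse. For US we
count all `l(l+1)/2` free entries as parameters; a covariances-only count
(`l(l−1)/2`) is available behind a flag because that convention also
circulates.

### Computational core

All solvers work in the eigenbasis `K = U D U′`. For a fully observed
trial the marginal covariance decouples into `n` independent `l × l`
blocks `Σₖ = dₖG₀ + R₀`, so one likelihood evaluation is O(`n l³`) after a
single O(`n³`) eigendecomposition. Missing cells are handled exactly by
row deletion: with `A = V_full⁻¹` and `D` the deleted cells,
`V_obs⁻¹ = A_OO − A_OD A_DD⁻¹ A_DO` and
`log|V_obs| = log|V_full| + log|A_DD|`; the `A_DD` block is assembled from
env-grouped GEMMs on slices of `U`. A dense Henderson mixed-model-equation
solver with explicit `u`/`v` blocks is kept as an independent reference
path; tests require agreement to 1e−8 with both it and brute-force dense
MVN conditioning.

The restricted likelihood follows the orthonormal-projection convention:
the log-density of `B′y` where `B` spans the orthogonal complement of the
fixed-effects space. Under `y → cy`, variances `→ c²`, it therefore shifts
by exactly `−(N_obs − p)·log c` (`p` = rank of X), which a test asserts.

### REML

Quasi-Newton (L-BFGS-B, numerically safeguarded line search, 2-point
gradients) on unconstrained coordinates: log variances, Fisher-z (atanh)
correlations, log-Cholesky for `G₀` and US `R₀`. Positive definiteness is
enforced by the parameterization, never by rejection. Convergence:
relative likelihood change below 1e−8 with projected-gradient norm 1e−5,
200-iteration cap; a non-converged fit is returned flagged, not raised.
Starts come from per-environment univariate fits — `G₀` diagonal in the
univariate genetic variances, off-diagonals at half the geometric mean,
`R₀` from the univariate residual variances. With these warm starts the
optimizer converges in 10–40 iterations on the problems we target, so the
textbook EM pre-iterations were left out; the likelihood-dominance test
(US ≥ ANT1 ≥ IDH ≥ IDV on the same data) guards against structure-specific
convergence failures. Negative genomic correlations are permitted
throughout. Target scale is MET-sized (n up to a few thousand), not
biobank-sized.

### Gibbs sampler

- `(β, u)` jointly: β from its *collapsed* Gaussian conditional
  (breeding values integrated out), then the rotated breeding values
  `aₖ = uₖ/√dₖ ~ N(0, G₀)` blockwise. Sampling β conditionally on u
  instead mixes catastrophically slowly when intercepts align with
  family-mean eigencomponents of K — the collapsed draw removes that
  pathology and is what our Bayes-vs-BLUP agreement test relies on.
- `G₀` (and US `R₀`): conjugate inverse-Wishart updates; scalar variances
  (`σ²g`, `σ²v`, IDV/IDH): scaled-inverse-χ². Priors: inverse-Wishart
  scale diagonal in the univariate variance-component estimates with
  weakly-informative df `l + 1`; scalar variances ν₀ = 3 with the same
  scales; β vague Gaussian with variance 1e8.
- ANT1 `R₀`: adaptive random-walk Metropolis on the unconstrained
  coordinates (uniform(−1,1) prior on the ρ's), scale tuned toward 20–40 %
  acceptance during burn-in only; acceptance outside (0.05, 0.8) is logged
  as a warning.
- Missing cells: data augmentation — drawn each sweep from their Gaussian
  conditional given the line's observed residuals, which keeps the
  completed trial balanced and makes held-out S_CV cells posterior
  predictions that borrow the line's other environments.

Defaults mirror the standard protocol: 10 000 iterations, 3 000 burn-in,
thinning 10 (storage only). GEBV point summary is the posterior mean
(stable for correlation-based prediction ability); variance parameters are
also summarized by the posterior mode of a Silverman-bandwidth KDE (ties
resolve to the lower value). The KDE mode of 10 000 draws has a sampling
RMSE near 0.08 on a unit-variance target, which is why tests bound it at
0.25, not tighter.

## Cross-validation

Lines are partitioned into `k = 5` folds per repeat (balanced remainder:
371 lines give 75/74/74/74/74), 10 repeats, identical folds across every
model / structure / method. M_CV removes a fold's lines from training in
all environments and predicts them through the kinship cross-covariance;
S_CV removes only the target-environment records, so the unbalanced REML
fit's conditional mean uses the fold lines' other environments. The
univariate model runs per environment on that environment's training
records only ("RND"). Validation phenotypes never enter
variance-component estimation; univariate warm starts are cached per
training split, not per structure. Prediction ability is computed within
environment, pooling a repeat's five folds before correlating; reported
as mean (SD) over repeats. Zero-variance correlations are reported
missing, never zero.

## Synthetic trials: what they emulate, and what they do not

The generator draws unlinked biallelic markers (allele frequencies uniform
on [0.05, 0.95], dosage = two Bernoulli draws), breeding values by a
matrix-normal factorization (Cholesky of `G₀` and of `K + 1e−8 I`),
residuals per line from `R₀`, and missing cells completely at random with
the guarantee that no line is missing everywhere. Two canned regimes
mirror the contrast the method is about: a high-correlation / weak-G×E
trial (genomic correlations 0.63/0.77/0.65, heritabilities
0.71/0.47/0.24) and a low-correlation / strong-G×E trial (correlations
0.54/0.30/0.11, heritabilities 0.58/0.73/0.41). Heritability patterns are
expressed as heterogeneous residual variances `(1−h²)/h²` over a unit
genetic scale.

Unlinked markers on mutually unrelated lines make `K ≈ I`, and then `G₀`
and `R₀` are barely separable — only their sum is identified, and
structure comparisons degenerate. Real panels are nothing like that:
diversity panels and doubled-haploid programs carry strong relatedness.
The qualitative experiments therefore run on a family-structured kinship
(default 10 families of 30, within-family relatedness 0.5), which restores
the eigenvalue spread that identifies the genetic/residual split. What the
passing tests show is therefore the *mechanics* of the methods under a
faithful covariance model; they do not reproduce the absolute accuracies
of real panels (no linkage disequilibrium, no population structure beyond
families, Gaussian residuals only), and effect sizes of the
structure-choice contrasts at n = 300 are small (order 0.01 in prediction
ability) relative to their own between-simulation variability.

## Problem sizes used in tests and the acceptance script

Oracle and algebra checks run at n ≤ 12. Parameter recovery: genomic
correlation 0.7 at n = 400, l = 3, m = 1000 (12 REML / 8 MCMC replicates,
median absolute error ≤ 0.15); univariate h² = 0.5 at n = 500 (10
replicates, median within ±0.1). Qualitative cross-validation contrasts:
n = 300, 5-fold × 10 repeats, REML. The acceptance script reports the
same quantities from 5-repeat cross-validation and 5–6 recovery
replicates; all randomness derives from the single `--seed` argument.

## Known limitations

- No LD, pedigree, dominance/epistasis, or spatial field effects in the
  generator; no factor-analytic or banded structures beyond the four
  supported kinds; no alternative relationship matrices.
- REML gradients are finite-difference; fine at MET scale, wasteful
  beyond it.
- S_CV prediction ability rewards absorbing residual covariance into the
  GEBV (the observed validation phenotype contains the residual), so under
  strongly correlated residuals a correctly specified `R₀` can *lower*
  measured ability even while improving breeding-value estimation — an
  intrinsic property of the phenotype-correlation metric worth keeping in
  mind when reading structure comparisons.
- Basic split-chain diagnostics only (logged split R-hat); no multi-chain
  convergence machinery.
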