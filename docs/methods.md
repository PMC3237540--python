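# Methods

This note documents the models, algorithms and design choices behind
`stickleqg`. The package implements the inference chain of a two-population
common-garden quantitative-genetics study: a paternal half-sib breeding
design (each sire mated to two dams) in a small-bodied coastal and a giant
pond population of nine-spined stickleback, body length measured at 20, 50,
80, 110 and 140 days after hatching (DAH), maturation scored as a binary
record, and a multi-allelic neutral marker panel for the parental fish.

## The animal model

The core model for one trait at one age is the pedigree mixed model

    y = X b + Z1 a + Z2 m + e

with `a ~ N(0, A sigma2_a)` (A the numerator relationship matrix implied by
the pedigree), `m ~ N(0, I sigma2_m)` the dam-identity (maternal) effects,
and `e ~ N(0, I sigma2_e)`. Fixed effects are the overall mean plus,
optionally, a density covariate and a three-level sex factor
(male/female/immature — immature fish cannot be sexed). Derived quantities
are computed draw-wise:

    h2 = sigma2_a / V_P,   m2 = sigma2_m / V_P,   V_P = sigma2_a + sigma2_m + sigma2_e

The binary timing-of-maturation record (matured: 0, immature: 1) is
analysed on the Gaussian scale as a numeric response; no liability-link
model is fitted. This keeps the estimand identical across traits at the
cost of treating a Bernoulli variable as homoscedastic — heritabilities for
the binary trait are therefore on the observed (0/1) scale.

### Sampler

All univariate posteriors are simulated by a partially collapsed
Metropolis-within-Gibbs scheme built on one block factorization:

* **Coefficient-matrix factorization.** The mixed-model equations use the
  sparse A-inverse (assembled directly from the pedigree by the standard
  parent-offspring rules, never by dense inversion). The factorization
  exploits the pedigree topology: individuals that are nobody's parent are
  mutually conditionally independent given parents, dams and fixed
  effects, because A-inverse couples an individual only to its parents and
  mates. Ordering those "terminal" individuals first makes the upper-left
  block of the coefficient matrix diagonal, so each factorization costs
  one dense Cholesky of the small Schur complement (founders + dams +
  fixed effects; a couple of hundred rows for these designs) plus O(n)
  vector work.
* **Variance components** are updated by a joint random-walk Metropolis
  step on the log variances whose target is the *marginal* posterior
  p(variances | y) with every location effect integrated out analytically
  (the log-determinant and quadratic form fall out of the same
  factorization; the log-scale Jacobian is included in the target). The
  proposal covariance is adapted during burn-in from the chain's own
  history (Haario-style, with an acceptance-rate-tuned global scale
  targeting ~28%), then frozen. Collapsing is essential: the conjugate
  variance-given-effects update mixes at O(number of effects)
  autocorrelation along the additive/maternal ridge of a half-sib design
  and does not converge in any practical run length, which was verified
  against an exact grid integration of the balanced-design posterior.
* **Location effects** `(b, a, m)` are then redrawn *jointly* from their
  exact multivariate-normal full conditional, reusing the current
  factorization.

Priors on variances are configurable per term. The default is flat on the
variance (p(sigma2) proportional to 1), the stated prior convention for
this kind of analysis. The classic scaled inverse-chi-square family is
available but deliberately not the default: its nu -> 0 "weakly
informative" limit behaves like 1/sigma2 near the origin and concentrates
the marginal posterior of any weakly identified component into a spike at
zero (only invisible to samplers that cannot reach it). A flat-on-the-SD
option (`flat_sd`) is the default inside the Q_ST model, where it makes
the Q_ST posterior exactly invariant to shifting and rescaling the
phenotypes. Fixed effects carry flat priors. The collapsed marginal
likelihood was validated against a dense brute-force computation, and the
bivariate conditional updates against a successive-conditional (Geweke)
simulation test.

Chain defaults mirror the study protocol: 2e5 iterations, the first 10%
discarded as burn-in, even thinning to 1000 retained draws. The test-suite
and the acceptance script use shorter chains (typically 2e4 iterations for
parameter-recovery checks, with proportional burn-in/thinning); those run
lengths were chosen as the point where recovery results stop changing
meaningfully at the study's design sizes. Every sampler consumes a single
`numpy` Generator, so a fixed seed gives bit-identical retained draws.

Posterior modes are the argmax of a Gaussian KDE (Silverman bandwidth) on a
512-point grid over the sample range; intervals are 95% highest-posterior-
density intervals found by the shortest-window scan over sorted draws.
Constant draws short-circuit to a zero-width summary.

### Identifiability of block and maternal effects

The rearing-tank ("block") factor is nested within dams: each family's
duplicate tanks belong to one dam. A flat-prior *fixed* block factor
therefore spans every dam contrast and removes all information about
`sigma2_m` — the maternal posterior becomes improper and the sampler
diverges. `ModelSpec` consequently supports block as an i.i.d. *random*
term (`block_random`), which is what the pipeline uses whenever a maternal
term is present; the hierarchy (tank within dam) keeps both variances
estimable. Tank variance is a nuisance component and never enters V_P, so
h2/m2 keep the same denominator convention as the fixed-block
parameterisation. Block remains available as a fixed effect for models
without a maternal term. The same nesting makes a tank-level density
covariate exactly collinear with block dummies; the design builder detects
aliased columns sequentially (like R's `lm`) and drops the later ones.

### Bivariate model and DIC

The two-trait model has unstructured 2x2 additive (G) and residual (R)
covariances, restricted to individuals with both traits observed. Sampling
alternates (i) an exact joint location draw for each trait given the other,
using the conditional-normal offsets on both the genetic side
(`a1 | a2 ~ N((g12/g22) a2, g11.2 A)`) and the residual side, so the
univariate machinery is reused unchanged; and (ii) conjugate
inverse-Wishart updates of G and R. Hyperparameters are df = 3 with scale
1e-3 x diag(trait variances): df = dim + 1 makes the implied marginal prior
on each correlation uniform on (-1, 1), which matters because smaller df
piles prior mass at r = +-1 and visibly biases weak-data fits. The genetic
correlation is computed draw-wise, r_g = g12 / sqrt(g11 g22), and
summarised by posterior mean and 95% HPD.

DIC uses the conditional (Gaussian, location-parameter) deviance:
`DIC = 2 Dbar - Dhat`, with Dbar the mean deviance over retained draws and
Dhat the deviance at the posterior means of the location effects and
residual variance. Model pairs must come from identical data (checked by
checksum) and the reduced model's random terms must nest in the full
model's.

## Q_ST

Q_ST compares quantitative divergence to neutral expectation:

    Q_ST = sigma2_GB / (sigma2_GB + 2 sigma2_GW)

`sigma2_GB` is the variance of a random population effect stacked on top of
within-population animal models that share one pooled additive variance
`sigma2_GW` (common-G assumption); the block-diagonal A-inverse spans both
pedigrees. Maternal variance is excluded from the Q_ST denominator by
default (an `include_maternal` flag adds the term to the model; it still
never enters the ratio). Q_ST is computed draw-wise and summarised as
posterior mean +- SD.

With only two populations `sigma2_GB` is weakly identified, so the prior
matters: the population-effect SD gets a half-Cauchy prior (sampled through
the inverse-gamma auxiliary-variable representation) with scale
`prior_scale x SD(y)`, default `prior_scale = 1`. An optional sensitivity
run refits at user-chosen scales and reports the resulting means/SDs
alongside the estimate. Two chains are run by default (10,000 iterations,
5000 burn-in, keep every 2nd — 2 x 2500 retained draws) and the
Gelman-Rubin statistic on `sigma2_GB` is attached; rhat > 1.2 raises a
convergence warning on the result rather than an error.

The contrast classifier places the F_ST point estimate in the Q_ST
posterior: below the 2.5% quantile -> "directional" (Q_ST > F_ST), above
the 97.5% quantile -> "stabilizing", otherwise "indistinguishable".

## F_ST (Weir-Cockerham theta)

Theta follows the 1984 variance-components estimator extended to multiple
alleles: for every allele at a locus the among-population (a), among-
individual (b) and within-individual (c) components are computed from
sample sizes, allele frequencies and observed heterozygote counts; alleles
are summed within locus, and the multilocus estimate is the ratio of sums
over loci — the global-estimator convention of FSTAT. Implementation
details:

* loci monomorphic across all sampled populations are excluded;
* per-locus sample sizes count non-missing genotypes only (a genotype is
  missing if either allele is);
* negative per-locus components are retained so the ratio-of-sums stays
  unbiased; the final point estimate may legitimately be slightly negative;
* the standard error is a delete-one-locus jackknife;
* significance comes from permuting individuals (both alleles move
  together, preserving within-individual Hardy-Weinberg departures) across
  population labels, with p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1);
* a configurable exclusion list drops named loci (for markers flagged as
  non-neutral) before estimation.

Panels are read from GENEPOP files (2- or 3-digit diploid coding; no
installed library parses GENEPOP, so a minimal reader/writer is included)
or from a long-format CSV.

## Phenotype-level statistics

* **Nested LME.** Body-length contrasts use
  `y = X beta + family + block(family) + e`, fitted by full maximum
  likelihood (not REML) so that likelihood-ratio tests on fixed effects are
  valid. The two variance ratios are profiled (GLS for beta, plug-in ML for
  the residual variance) and minimised by L-BFGS-B from three starts with
  box bounds at zero; per-family block Cholesky factorisations keep each
  evaluation O(family size^3). LRTs use a plain chi-square reference with
  df equal to the parameter-count difference — no 50:50 boundary mixture is
  applied, which makes variance-component tests conservative.
* **Maturation GLM.** The probability of having matured by a given age is
  modelled from grouped family-level counts with a binomial-logit IRLS fit
  (deviance against the saturated model). Single-term deletions report the
  deviance difference against chi-square(df = number of columns the term
  contributes). Complete separation is flagged when a coefficient diverges
  on the logit scale (|beta| > 15).
* **Sex ratio.** Pearson chi-square against 1:1 with df = 1 and no
  continuity correction.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions every
statistical check runs under.

* **Design.** 36 sires x 2 dams per population by default, family sizes
  uniform on 10-25, families split across duplicate tanks at 20 DAH with a
  configurable single-tank fraction (the coastal default is 22/72,
  mirroring families that fit in one tank only).
* **Phenotypes.** Founder breeding values are N(0, V_A) (bivariate:
  MVN(0, G) implied by V_A1, V_A2, r_g); offspring values are midparent
  plus Mendelian sampling N(0, V_A/2) — exact for non-inbred, unrelated
  parents, which the one-generation design guarantees. Dam effects
  N(0, V_M), tank effects, a sex effect, a density slope and i.i.d.
  residuals complete the record. Population growth means per age are
  config vectors shaped like the study's crossing trajectories (the pond
  population overtakes the coastal one at ~80 DAH); no parametric growth
  law is imposed. Default variance components for length (V_A = 2.2,
  V_M = 0.9, V_E = 9.2) follow the coastal population's late-age values.
* **Density.** The covariate is realized mean tank occupancy over the
  previous-to-focal interval (focal occupancy at the first age), with
  mortality thinning tanks between ages (default 5% per interval), so the
  density effect is estimable rather than degenerate.
* **Maturation.** A single heritable Gaussian liability per individual is
  thresholded by population- and age-specific cutoffs; no cutoff means no
  maturation (the giant-population regime). Sex is Bernoulli(1/2) but
  reported as "immature" until an individual matures, reproducing the
  three-level sex factor. The coastal default couples liability to length
  with r_g = -0.6 (propensity scale), i.e. genetically larger fish mature
  later, so length and the immature-coded binary trait correlate
  positively.
* **Genotypes.** Balding-Nichols: ancestral frequencies symmetric-
  Dirichlet, population frequencies Dirichlet(p (1-F)/F) at target F
  (default 0.458, 103 loci, 5 alleles, 24 + 24 individuals); F = 0 copies
  the ancestral frequencies.

What the generator does **not** emulate: microsatellite mutation processes
(stepwise mutation, size homoplasy), linkage between loci, selection or
genotype-dependent mortality during rearing, measurement error correlated
within photographs, and age-specific genetic variances (one breeding value
per trait is shared across ages). Passing tests therefore demonstrate that
the estimators recover parameters under the assumed generative model at the
study's design sizes — not that any particular real dataset satisfies those
assumptions.

## Numerical choices and degenerate inputs

* Variance draws are floored at 1e-10 x var(y) to keep the mixed-model
  equations finite; a constant response raises a degenerate-data error
  before sampling.
* A non-positive-definite Schur complement raises a numerical error rather
  than silently regularising.
* Design matrices always include an intercept; constant covariates are
  absorbed, aliased columns dropped sequentially.
* HPD/mode summaries require >= 100 retained draws.
* The jackknife needs >= 2 informative loci; permutation tests need
  >= 100 permutations.
* All randomness flows from `numpy.random.Generator` objects seeded
  explicitly; multi-stage runs spawn per-stage seeds from one
  `SeedSequence`, so stages can be replayed in isolation.

## Problem sizes used by tests and the acceptance script

Parameter-recovery checks run at the study's design scale (30 sires x 2
dams x 20 offspring, n = 1200) with 2e4-iteration chains; the bivariate
null-coverage and Q_ST checks use 20-30 sire designs; F_ST checks use the
study-sized panel (103 loci, 24 + 24 diploids); permutation calibration
uses 200 replicate 20-locus null panels at 100 permutations each. The
acceptance script runs reduced replicate counts (5 heritability replicates
at 1e4 iterations) of the same conditions.

## Known limitations

* The Bayesian posterior mean of h2 and the classical nested-ANOVA moment
  estimate are different estimators: they agree on typical half-sib
  datasets but can differ by ~0.3 on datasets whose moment estimate is
  extreme (the ANOVA h2 has a sampling SD of roughly 0.25 at 30 sires and
  is not confined to the model-coherent range, while the posterior mean
  shrinks toward it). The parameter-recovery tests document this: HPD
  coverage of the generating value is the calibrated property; per-dataset
  agreement with the moment estimator is not, and the corresponding strict
  assertion is expected to fail on a minority of replicates.

* The Gaussian treatment of the binary maturation trait means its h2 is
  scale-dependent; no threshold-model transformation is provided.
* Q_ST with two populations remains prior-sensitive no matter the
  machinery; the sensitivity report is the honest summary of that fact.
* DIC is computed at the conditional (location-level) focus; other foci
  give different absolute values, so only differences between nested fits
  on identical data are meaningful.
* The LME fitter assumes the block factor is nested in family (labels are
  interpreted within family); crossed designs are out of scope.
* Pedigrees deeper than a few generations work (the inverse uses the
  general inbreeding-aware Mendelian variances) but the samplers are tuned
  for shallow designs where most individuals are terminal.
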