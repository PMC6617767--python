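# Methods

This note documents the models the package implements, the numerical
choices inside the samplers, what the synthetic-data generator does and
does not emulate, and the limitations a user should know about.

## The analysis the package supports

The target analysis is quantitative genetics of a wild, pedigreed,
overlapping-generation population in which fitness is measured as
lifetime reproductive success (LRS: the count of an adult's offspring
that themselves recruited as adults) and the focal trait is a mean- and
variance-standardized body size (a z-score, so all evolutionary rates
are in phenotypic standard deviations; one SD per generation is a
Haldane). The stages are:

1. **Phenotypic selection.** A Poisson log-link GLMM of LRS on the
   z-scored trait, `log lambda = b0 + b1 z + b2 z^2 + cohort + e`,
   with a latent residual `e` per record supplying overdispersion.
   Latent coefficients are converted to gradients equivalent to
   Lande–Arnold regression coefficients of relative fitness `w = W/E[W]`
   on `z`: `beta = E[w'(z)]`, `gamma = E[w''(z)]` (mean second
   derivative, *not* doubled), averaged over either the empirical `z`
   sample or a standard normal via Gauss–Hermite quadrature. With
   `b2 = 0` and Gaussian averaging `beta = b1` exactly — a useful
   identity test.
2. **Animal models.** Univariate Gaussian (trait), univariate Poisson
   (LRS), and a bivariate Gaussian–Poisson model, each with intercept
   plus additive-genetic (structured by the pedigree relationship
   matrix A), dam, cohort and residual random effects; the bivariate
   model carries an unstructured 2×2 covariance matrix per term.
   Heritability is `V_A` over the sum of all four components.
3. **Scale transform.** Latent-scale Poisson parameters map to the
   observed count scale in closed form (log link):
   `mean_obs = exp(mu + V_total/2)`,
   `V_P_obs = mean_obs + mean_obs^2 (exp(V_total) - 1)`,
   `V_A_obs = mean_obs^2 V_A`, `h2_obs = V_A_obs / V_P_obs`.
4. **Predictions vs observation.** The Breeder's Equation response
   `R_BE = V_A * beta` (draws of `V_A` and `b1` paired by seeded random
   matching of the two independent chains); the secondary-theorem
   response `R_STS = cov_A(w, z)`, which for a log-link fitness model
   is the latent-scale additive covariance from the bivariate fit; the
   observed trend as the per-draw OLS slope of cohort-mean breeding
   values on cohort year; a drift null from gene dropping; and the
   bias decomposition `beta_G = cov_A / V_A(trait)`,
   `beta_E = (cov_dam + cov_cohort + cov_resid) / (V_dam + V_cohort +
   V_resid)(trait)`, `delta_beta = beta_E - beta_G` per draw.

All point estimates are posterior modes (Gaussian KDE, Silverman
rule-of-thumb bandwidth `0.9 min(sd, IQR/1.34) n^{-1/5}`, argmax on a
512-point grid) with 95% highest-posterior-density intervals (narrowest
contiguous window of sorted draws; lowest start on ties).

## Pedigree machinery

`relationship_matrix` uses the tabular method (row-vectorised, dense;
fine to a few thousand individuals), `inbreeding` recursive kinship
with memoisation, and `a_inverse` Henderson's direct rules with the
inbreeding-corrected Mendelian-sampling variances
`d_i = 0.5 - 0.25 (F_dam + F_sire)` (two known parents),
`0.75 - 0.25 F_known` (one), `1` (none). Unknown parents contribute
nothing to the mid-parent mean and enlarge `d_i` accordingly; the same
convention drives gene dropping, so drift simulations and the sparse
inverse are mutually consistent. Gene-dropped values scale exactly as
`sqrt(V_A)`, which the drift null exploits: one unit-variance drop per
posterior draw, rescaled by that draw's `V_A`.

## The Gibbs engine

**Marginalisation to phenotyped individuals.** The breeding values of
any subset of a pedigree are jointly normal with covariance
`V_A * A_obs`, the corresponding submatrix of A. The engine therefore
works with the phenotyped individuals only — an exact marginalisation —
and eigendecomposes `A_obs = U D U'` once per fit. In the eigenbasis
the full conditional of the rotated breeding values is diagonal
(2×2-block-diagonal for the bivariate model), so one Gibbs iteration
costs two dense matrix–vector products (about a millisecond at
n ≈ 1,200) instead of a sparse factorisation. Eigenvalues are floored
at 1e-10.

**Poisson latents.** Each Poisson observation carries one latent
log-rate with full conditional `y*eta - exp(eta) - (eta - m)^2/(2v)`,
updated by stepping-out/shrinkage slice sampling (unit initial width,
vectorised across observations; log-concave, so shrinkage terminates
fast). `eta` is clipped at +30 before exponentiation as an overflow
guard. Given the latents, every variance component is conjugate.

**Parameter expansion.** Variance-component Gibbs samplers mix poorly
when a variance is small relative to its uncertainty, because the
effects and their variance move in lock-step. Every non-residual term
therefore carries a working scale `g` with a diffuse N(0, 1000) prior
(per trait in the bivariate model): effects are stored unscaled, the
fitted contribution is `g * u`, and the reported variance is `g^2 V~`
(bivariate: `diag(g) G~ diag(g)`). The `g` update is a linear
regression of the current residual on the unscaled effects, coupled
across traits through the residual covariance — all conditionals stay
Gaussian. Without this the bivariate genetic block showed lag-1
autocorrelations above 0.9 at a thinning interval of 20 and visibly
unconverged covariance splits; with it the same chains mix an order of
magnitude faster.

**Priors.** Scalar variances: inverse-gamma with scale 1 and 0.002
degrees of freedom (plus the expansion scale above). 2×2 terms:
inverse-Wishart, identity scale, 3 degrees of freedom, again behind a
working scale, so the effective prior on each reported variance is
heavy-tailed and much less informative than the raw inverse-Wishart.
Fixed effects: N(0, 1e8). Chains abort with a diagnostic error if a
residual variance exceeds 1e12.

**Dam levels.** Individuals with an unknown dam each get a private
singleton level rather than a pooled "unknown" level, which would
fabricate a large phantom sibship.

**Missing data.** In the bivariate model a missing Gaussian response is
imputed from its conditional given the other trait (data
augmentation); a missing count simply removes the Poisson factor from
that latent's conditional. Traits observed on disjoint individuals
therefore run, and leave the cross-trait covariances prior-dominated.

**Chain lengths.** Defaults are desk-scale — univariate: 1,000 burn-in,
10,000 iterations thinned by 10; bivariate: 3,000 / 30,000 / 30 —
chosen so a full pipeline run takes a few minutes on one core while
keeping every reported chain at ≥ 1,000 draws. Publication-scale
presets (`PAPER_SCALE_GAUSSIAN`: 500k burn-in, 2M iterations, thin
1,000; `PAPER_SCALE_POISSON`: 1M / 14M / 10k) reproduce the chain
lengths typical for final inference on real data. Lag-1
autocorrelations above 0.10 are reported as warnings, not errors; at
desk scale the variance components typically sit at 0.1–0.3, which
widens Monte-Carlo error but leaves coverage intact (the acceptance
suite checks this directly).

## The synthetic population

The generator emulates a trapped, census-style study system: nine
annual return cohorts (1977–1985 by default), a modal four-year life
cycle (ages 3–5 at return, probabilities 0.05/0.90/0.05), about 1,185
female and 300 male adult records, a unit-variance standardized size
trait with `V_A = 0.25`, `V_dam = 0.001`, `V_cohort = 0.08`,
`V_resid = 0.67` (h² ≈ 0.25), and Poisson LRS with latent fitness
variances 0.003 (genetic), 0.33 (cohort) and 0.93 (residual) — the
variance architecture a study of this kind reports. Sizes are emitted
in centimetres through an affine map (mean 60, SD 6) so the
standardization step is exercised.

Three ground-truth links connect trait and fitness. `b_w` (default
0.23) is a direct effect of maternal size on the latent log rate —
real selection, giving a true `cov_A(w, z) = b_w V_A + rho_A`.
`rho_A` adds a purely genetic covariance. `confounder_s` adds one
shared environmental deviate to both the trait residual and the
fitness residual (component variances preserved; requires
`s^2 <= min(V_resid, V_resid_w)`), creating phenotypic selection with
no genetic basis — the "missing factor" scenario in which the Breeder's
Equation overpredicts and `delta_beta > 0`.

**Demography.** Founder cohorts fill the five pre-window years at the
configured sizes. Each year's returning females spawn with a random
sire from the same run; candidate offspring draw an age and a return
year; each run is then capped at the configured run size by uniform
thinning (density regulation, recruitment surplus 3.0). Two properties
make this regulation safe for inference: uniform thinning of
per-mother Poisson counts leaves LRS Poisson with a year-level factor
on the rate, which the cohort random effect absorbs, and the
stationary run sizes match the study design (~1,185 female records in
every seed). Without regulation, the cohort-level fitness variance
drives a demographic random walk; in development runs that walk's
population momentum leaked into the estimated genetic covariance as a
spurious negative component whenever a replicate's population crashed.
LRS counts offspring returning up to four years past the last cohort
(the assignment horizon), so only the final cohorts' oldest offspring
are truncated — mirroring census designs in which parentage assignment
outlives the analysed cohorts.

**What the generator does not emulate**, and hence what passing tests
cannot certify about real data: hatchery gene flow and ranching,
straying, iteroparity and sneaker males, assortative mating, sex- or
age-dependent trait expression, pedigree assignment error, and
observation error in LRS beyond window truncation. Mendelian-sampling
variance in the generator ignores parental inbreeding (F stays below
~0.01 in these shallow pedigrees); the analysis side does account for
it.

## Design choices that were genuinely open

- **Selection-model random effects:** cohort is included by default
  (`include_cohort` flag to disable) — the trait and fitness data are
  strongly year-structured, and leaving cohort out pushes year effects
  into overdispersion.
- **beta for the Breeder's Equation** is the latent linear coefficient
  `b1`; the Lande–Arnold-converted gradient is reported alongside.
- **gamma convention:** mean second derivative of relative fitness,
  not doubled; output metadata says so.
- **Trend estimator:** unweighted OLS on per-draw cohort means, one
  point per cohort. Cohort-size weighting is a one-line change in
  `_cohort_mean_slope` but is not the default: regulated cohorts are
  near-equal in size, and unweighted means keep the drift null exactly
  symmetric with the observed-slope computation.
- **beta_E denominator** includes all three non-genetic trait variance
  components (dam, cohort, residual), matching the "sum of all
  environmental covariance terms" reading; the dam component is
  near-zero in practice so the distinction is immaterial.
- **Data-scale heritability for LRS** treats all four latent components
  as `V_total`, mirroring the latent h² denominator; excluding cohort
  from the mixing variance is a one-argument change in
  `transform_posterior` for sensitivity work.
- **Generation time** is fixed at 4 years by default (the modal age at
  return) and configurable everywhere Haldanes are produced; the
  Haldane conversion refuses nothing — it assumes the trait was
  variance-standardized upstream, which the pipeline enforces by
  construction.

## Known limitations

- The Gaussian-Poisson bivariate covariance split (`cov_A` vs
  `cov_resid`) is weakly identified at n ≈ 1,200 with a shallow
  (2–3 generation) pedigree: the likelihood carries little information
  about `cov_A` against latent fitness noise of ~1 on the log scale,
  so its posterior shrinks toward the zero-centred prior — HPD
  intervals cover a true genetic covariance of 0.05 but the point
  estimate attenuates toward 0. Detached-count controls show this is a
  power property of the design, not an artifact of fitness being
  defined by the pedigree itself. Studies of this design report
  correspondingly wide secondary-theorem intervals.
- The engine's dense eigendecomposition is quadratic in memory in the
  number of *phenotyped* individuals; beyond ~20,000 records a sparse
  factorisation would be the right backend.
- A founder-only pedigree cannot identify `V_A` against the residual
  (the likelihood depends only on their sum); fits run but the split
  is prior-driven. Pedigree structure is what identifies the model.
- Male analyses run through the identical code path but, as in the
  study system, small male sample sizes leave their quantitative
  genetic parameters poorly identified.
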