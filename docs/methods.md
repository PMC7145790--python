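# Methods

This note documents the statistical models implemented by `enwas`, the
defaults of the synthetic-region generator, and the numerical choices that
shape the results. It is the package's account of its own science; every
number quoted here is computed by the test suite or the analysis scripts.

## The three-stage design

The package implements an ecological, area-level association study for a
rare disease observed as counts `O_i` over areal units `i = 1..n` with
age–sex structured populations and many candidate exposure covariates.

**Stage 0 — standardisation.** Expected counts are indirectly
standardised: reference rates `r_s = (Σ_i cases_{i,s}) / (Σ_i pop_{i,s})`
per age–sex stratum `s`, and `E_i = Σ_s pop_{i,s} · r_s`. With this
internal reference the calibration identity `Σ_i E_i = Σ_i O_i` holds
exactly; a property test enforces it to 1e-9 relative error. Overall
incidence is reported per 100,000 person-years with the exact Poisson
(gamma-quantile) confidence interval, which stays valid at the small
per-area counts of a rare childhood disease and converges to the normal
interval at large counts.

**Stage 1 — frequentist screen (EnWAS).** For each exposure `x` a
univariable Poisson regression with offset,

    O_i ~ Poisson(E_i · exp(a + b·x_i)),

is fitted by IRLS to relative tolerance 1e-10 (max 100 iterations;
non-convergence raises with diagnostics). p-values are two-sided Wald —
the convention of standard GLM output. Covariates enter in native units
(a z-score option exists but is off by default). Family-wise error over
the `m` screened exposures is controlled by Bonferroni (`p < α/m`; with
α = 0.05 and m = 53 the per-test threshold is 9.43e-4 ≈ 0.0009). Areas
with a missing covariate are dropped per test (complete-case per
variable). The Manhattan quantity is `−log10(p) · sign(b̂)` (a p-value
underflow is clamped at 1e-300 for plotting only); QQ points pair the
sorted `−log10 p` with uniform order-statistic midpoints `(k − 0.5)/m`.

**Stage 2 — Bayesian disease mapping.** The same Poisson-offset model with
a BYM2 convolution random effect:

    log RR_i = a + x_i'β + b_i,
    b = σ (√φ · u* + √(1−φ) · v),

where `v ~ N(0, I)` is unstructured over-dispersion and `u*` is an
intrinsic CAR (ICAR) field on the area adjacency graph, scaled so that the
geometric mean of its marginal variances is 1. The scaling factor is
computed per connected component as the geometric mean of the diagonal of
the constrained generalised inverse of the component's graph Laplacian
(explicit eigendecomposition with a relative null-space tolerance — a
generic pseudo-inverse cutoff mishandles the near-zero eigenvalue on
larger graphs). This scaling makes `σ` the marginal standard deviation of
the combined effect and `φ ∈ [0,1]` the *structured share*: the
proportion of random-effect variability attributed to spatial structure
rather than over-dispersion. Per-area smoothed relative risks are
`exp(b_i)` (risk relative to the covariate-adjusted national expectation);
areas are classified `elevated`/`lowered` when the posterior probability
of RR above/below 1 reaches 0.8, else `uncertain`.

**Stage 3 — selection and multivariable regression.** A covariate is a
candidate when its Bonferroni-adjusted screen p is below 0.05 *and* its
disease-mapping 95% CrI excludes 1 ("relevant CrI" = RR entirely >1 or
<1). Because exposures arrive in strongly intercorrelated groups (air
pollutants, deprivation domains, …), candidates are clustered as
connected components of the graph joining pairs with |Spearman ρ| ≥ 0.7
(midrank ties, pairwise-complete); one representative per cluster — by
default the smallest screen p, overridable to encode expert choices —
enters the multivariable BYM2 regression. Both the 0.7 cutoff and the
representative rule are deliberate objective defaults for what is, in
practice, partly a judgement call; the override hook exists for exactly
that reason. A temporal-split utility (Pearson correlation of per-area
counts between two sub-periods) provides the stability check.

## Priors

The primary literature for this model family rarely prints its priors, so
the package uses modern shrinkage defaults, all configurable via
`PriorConfig`:

| parameter | prior | default rationale |
|---|---|---|
| σ | Exponential, rate log(100) ≈ 4.61 | penalised-complexity-style: Pr(σ > 1) = 0.01; shrinks toward no random effect |
| φ | Uniform(0, 1) | no preference between structure and over-dispersion |
| a, β | Normal(0, 10²) | vague on the log-RR scale |

`sigma_fixed=0` switches the random effect off entirely (the model then
reduces to the stage-1 GLM; a test checks posterior means agree with the
frequentist fit within 2 posterior SDs). Equal-tailed central 95%
intervals are reported throughout.

## MCMC

Inference is dependency-free adaptive MCMC (default 4 chains × 5,000
iterations, half warm-up; reduced schedules of 2 × 2,000 are used for the
bulk simulation studies). The kernel combines:

1. **Colour-group random-walk updates of `u`**: a greedy proper colouring
   of the adjacency graph lets all areas of one colour be updated
   simultaneously (their full conditionals are independent), vectorising
   the single-site sweep. Sum-to-zero is enforced per component by
   centring each sweep, standard ICAR practice.
2. **Vectorised site updates of `v`** (fully independent given the rest).
3. **Random-walk updates** of `a`, each `β_j` (internally centred
   covariates to decorrelate from the intercept), `log σ` and `logit φ`,
   with Robbins–Monro adaptation toward 0.44 acceptance, frozen after
   warm-up.
4. **A partially collapsed block for (σ, φ)**: given the combined field
   `b`, the split `(u, v)` can be marginalised — in the eigenbasis of the
   scaled Laplacian the free coordinates of `b` are independent
   `N(0, σ²(φ/λ_k + 1 − φ))` (null modes and zero-neighbour islands carry
   pure unstructured variance). Metropolis sweeps on this collapsed
   conditional are followed by an **exact Gibbs redraw of `(u, v)` given
   `b`**, whose conditional is diagonal in the same basis (the sum-to-zero
   constraint is just zeroing the null modes). This block leaves the
   likelihood untouched but removes the anchor between the scale
   parameters and one particular field split; without it the bulk ESS of
   `φ` is an order of magnitude lower and the default schedule cannot
   meet its own convergence contract.

Convergence is monitored by split-R̂ < 1.01 and bulk ESS > 400 (via
`arviz`) for the intercept, coefficients, σ and φ; a fit that misses the
thresholds is returned with `converged=False` and full diagnostics, never
silently. Zero-neighbour areas receive a pure unstructured effect
(`b_i = σ v_i`); disconnected components get separate scaling factors and
sum-to-zero constraints.

In prior-predictive mode (`prior_only=True`) σ and φ are drawn directly
from their priors — with the likelihood off those *are* their full
conditionals — so the prior-recovery test applies a Kolmogorov–Smirnov
check to independent draws.

## The synthetic-region generator

The generator emulates a national district-level childhood-disease study
so that every stage is testable with known ground truth. Defaults (chosen
once, as study conditions):

- **354 areas** on a random planar (Delaunay) or lattice graph — the
  scale of English local authority districts.
- **Population**: per-area at-risk (child) totals log-normal with mean
  17,000 and log-SD 0.5, split over 4 strata (2 age bands × 2 sexes) by a
  symmetric Dirichlet (concentration 50). The 17,000 figure follows from
  ~14,000 cases at 21.2 per 100,000 person-years over an 11-year window
  across 354 districts; district *total* populations (~140,000) include
  all ages and are not the denominator.
- **Baseline rates**: 21.2e-5 per child-year × 11 years, with stratum
  multipliers (0.78/0.82 younger F/M, 1.16/1.24 older F/M) encoding rising
  incidence with age band and a slight male excess.
- **53 exposures** in correlated blocks of 3–6 (within-block ρ drawn from
  0.5–0.9, independent across blocks), alternate variables smoothed by the
  graph-Laplacian filter `(I + ρL)^{-1}` (range 2.0) to give spatially
  structured exposures; cross-correlations imposed by a Cholesky mix of
  standardised fields.
- **Effects**: 6 causal covariates with log-RR ±0.05 per SD; random
  effect σ = 0.3, φ = 0.78.

With these defaults one draw gives counts with median ≈ 37 (IQR 23–56,
max ≈ 140), total ≈ 15,000 cases, and a stage-1 screen flagging ~20–30 of
53 variables — the qualitative shape of a real national study. Stratum
case tables are allocated from area totals multinomially in proportion to
stratum expected load, so the stratified table is internally consistent.

What the generator does *not* emulate: real geography or boundary shapes,
postcode-level population weighting, exposure measurement error,
missingness (available per-variable via NaN but off by default),
record-linkage artefacts, or temporal drift in exposures. Passing tests
therefore demonstrate statistical correctness of the machinery under the
stated generative model, not robustness to those real-data features. One
deliberate property: because the random effect is multiplicative, the
realised marginal incidence exceeds the baseline rate by ≈ exp(σ²/2)
(≈ 4.6% at σ = 0.3).

## Numerical choices and degenerate inputs

- IRLS: relative coefficient tolerance 1e-10; all-zero counts raise (the
  intercept MLE diverges); fewer than 2 distinct covariate values raise.
- Decile coding: national distribution, ties take the lowest applicable
  decile (`rank(method="min")`), deterministic and order-independent;
  requires ≥ 10 non-missing areas.
- Weighted aggregation: zero-total-weight areas become missing with a
  logged warning; outputs are invariant to rescaling all weights.
- Spearman matrix: constant variables yield missing correlations with a
  warning rather than an error.
- Selection: deterministic under variable reordering (clusters sorted by
  smallest member; ties in the representative rule broken by name).
- Rank-deficient multivariable designs (duplicate/collinear covariates)
  are rejected before sampling.
- Pipeline outputs use fixed float formatting and sorted JSON keys; with a
  fixed seed the entire artefact set is byte-identical across runs
  (hashes recorded in `manifest.json`; wall-times go to the log, not the
  manifest, to keep it deterministic).

## Problem sizes in tests and the acceptance script

Simulation studies use sizes chosen to make the checks sharp but
desk-scale: interval-calibration at 200 areas with 50 replicates (2 × 2,000
chains), structured-share recovery at φ = 0.9 with 20 replicates,
family-wise error at 354 areas × 53 covariates × 1,000 replicates, CI
coverage with 2,000 Poisson draws, and the full 354-area, 53-covariate
pipeline end to end (twice, to verify byte-identity). The acceptance
script repeats the same computations at 500/20-replicate scale with
seed-derived substreams.

## Known limitations

- MCMC here is not a drop-in replica of INLA-based fits: with weakly
  identified φ (its posterior can span half the unit interval at n ≈ 350),
  different inference engines and priors will print visibly different
  share estimates on the same data.
- The ecological design carries ecological bias by construction; nothing
  in the package licenses individual-level interpretation of area-level
  associations.
- The exposure screen treats tests marginally; correlated exposures make
  the Bonferroni correction conservative in the FWER sense while doing
  nothing about confounding between exposures — that is what stage 3's
  clustering addresses, bluntly, with one representative per cluster.
- The under-dispersed S-shape that a QQ plot of screen p-values can show
  on real data is observed, not modelled; no correction is applied.
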