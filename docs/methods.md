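# Methods

## Model

`rngxe` fits a hierarchical one-step linear reaction norm model to
single-trait records of pedigreed animals:

```
y_ij = x_i' β + ℓ_j + a_i + b_i ℓ_j + pm_dam(i) + e_ij
```

with fixed effects `β` (intercept, cow-age linear and quadratic; cow age is
centred at its sample mean so the intercept refers to an average-age dam),
random contemporary-group (CG) environmental effects
`ℓ_j ~ N(0, σ²_cg)`, bivariate intercept/slope breeding values
`u = (a, b) ~ N(0, G ⊗ A)` structured by the numerator relationship matrix
`A`, maternal permanent environment effects `pm ~ N(0, σ²_pe)` indexed by
dam, and homogeneous residuals `e ~ N(0, σ²_e)`.  The slope's environmental
covariate is the *current draw* of `ℓ_j`, so the environmental gradient and
the reaction norms are estimated jointly (the "one-step" formulation) rather
than by plugging in pre-estimated CG solutions.  Records of animals with an
unknown dam carry no `pm` term.

### Sampler

All full conditionals are conjugate and cycled in a fixed order each
iteration: `β` (weighted least-squares normal draw, flat prior), each `ℓ_j`
(normal with precision `Σ_i (1+b_i)²/σ²_e + 1/σ²_cg` over the CG's
members), each animal's `(a_i, b_i)` jointly as a 2-vector in pedigree
order (the prior conditional uses the sparse rows of `A⁻¹`; the block update
matters because intercepts and slopes are strongly correlated a
posteriori), each dam's `pm`, then `G` from its inverse-Wishart conditional
(scale updated by the 2×2 sum of products `U' A⁻¹ U`) and the scalar
variances from scaled inverse chi-squares.  The sweep is compiled with
numba; the residual vector is updated incrementally and refreshed from
scratch every 1,000 iterations to stop floating-point drift.  Draws are
saved after burn-in at the thinning interval; the saved count is exactly
`floor((n_iterations − burn_in)/thin)`.  A second fixed update order is
available (`update_order="alternate"`) and is checked in the tests to give
the same posterior within Monte Carlo error.  Runs are bit-reproducible for
a fixed seed.

### Priors

Field analyses of this kind rarely state priors, so the defaults are proper but
diffuse: inverse-Wishart with 4 degrees of freedom and diagonal scale
`0.25 × var(y)` for `G` (an off-diagonal scale is available), and scaled
inverse chi-square with 4 df and scale `0.25 × var(y)` for `σ²_cg`,
`σ²_pe`, `σ²_e`.  With thousands of records these contribute a few percent
to the posterior scale at most.

### Identifiability of the environmental origin

The likelihood is invariant under `ℓ → ℓ − δ`, `β₀ → β₀ + δ`,
`a → a + δ b`, so the origin of the gradient must come from the priors.
Re-centring `ℓ` to mean zero every sweep (a commonly used device, available
as `center_cg_effects=True`) pins the origin at the *sample mean of the
realized CG effects*, which differs from the generative origin by
`m ~ N(0, σ²_cg/n_cg)` and therefore shifts the intercept variance estimand
by `2mσ_il + m²σ²_l` — material when slopes are large.  The default is
therefore *not* to re-centre: the genetic prior itself pins the origin,
because the prior energy of `(a + δb)` is minimised at `δ = 0` for states
consistent with `G` (the minimiser is `−S_ab/S_bb − g_c/g_i`, which
vanishes when the realized cross-products match `G`).  Empirically the
un-centred sampler holds the CG-effect mean near zero with no mixing
penalty.

### Geweke diagnostic

Convergence is screened by the classic early/late mean comparison:
`z = (mean of first 10% − mean of last 50%) / sqrt(S_f(0)/n_f + S_l(0)/n_l)`
with the spectral density at zero estimated by a Bartlett-windowed
autocovariance sum (Newey–West lag `4(m/100)^{2/9}`), flagged two-sided at
α = 0.05.  A constant chain returns a degenerate flag instead of dividing
by zero.  On iid normal chains of length 10,000 the empirical rejection
rate is ≈ 0.035–0.065 across seeds, inside the 0.05 ± 0.02 calibration
band asserted in the tests.

## Downstream summaries

CGs are ranked by posterior-mean solution and cut into `k = 5` quantile
levels of near-equal CG counts (largest-remainder sizes, extra CGs to the
lowest levels; ties broken by CG id).  A level's descriptor `X` is the mean
of its member solutions.  Per level, `σ²_a(X) = σ²_i + X²σ²_l + 2Xσ_il`
and `h²(X) = σ²_a(X)/(σ²_a(X) + σ²_pe + σ²_e)` are evaluated **draw-wise**
and reported as posterior mean ± SD; between-level genetic correlations are
likewise draw-wise means.  The heritability denominator excludes `σ²_cg`
(the gradient is treated as environment, not noise) — the common
convention in reaction-norm cattle studies; a flag adds it back.  Gradients
are built from posterior means, not per-draw re-ranking, so the levels are
deterministic.

Sires with at least 3 recorded progeny are classified from the posterior
means of their slopes, in SD units of the between-sire dispersion
(denominator n−1), centred at the sire mean: ER ≤ 1 SD < R < 2 SD ≤ P
< 3 SD ≤ EP, with the boundary at exactly 1 SD read as ER ("within 1 SD")
and the 2- and 3-SD boundaries as P and EP.  Centring at the sire mean
makes the scheme invariant to affine transformations of the slopes, hence
to the origin/scale conventions above; `center="zero"` is available.  Under
normally distributed slope means the expected class fractions are the
normal bands 68.3 / 27.2 / 4.3 / 0.3%, which is why "more than 90% robust
or extremely robust" is the structural expectation.

## Synthetic data generator

The generator emulates a multi-herd zebu beef population with known truth:

* **Pedigree** — overlapping birth cohorts of `n_founders` calves; sires
  are a sampled pool of males active for up to 3 cohorts, dams a breeding
  -cow pool active for up to 4 cohorts with **at most one calf per dam per
  cohort** (a cow cannot calve twice within one herd-year-season).  The
  default `sire_fraction = 0.03` yields ≈ 30 progeny per sire at study
  scale, matching the records-per-sire ratio of large zebu herd-book
  datasets.  No selection, no assortative mating.
* **Breeding values** — founders `N(0, G)`, descendants by parental average
  plus Mendelian sampling with covariance `G·d_i`,
  `d_i = ½(1 − (F_s + F_d)/2)` (with the usual one/no-parent variants), so
  the simulated covariance is exactly `G ⊗ A`.
* **Contemporary groups** — nested within cohort × sex (sex is simulated
  Bernoulli(½) and folded into the CG, as in the herd-year-season-sex
  definition), counts apportioned by cell size, sizes jittered around the
  mean; effects iid `N(0, σ²_cg)`.
* **Cow age** — truncated normal, mean 72.63, SD 36.65 months, floor 24
  months; enters via linear + quadratic coefficients (defaults 0.3 kg/mo
  and −0.002 kg/mo², weight-like scale).
* **Noise** — dam-level `pm ~ N(0, σ²_pe)` and iid residuals.

Default dispersion truth: `σ²_i = 100`, `σ²_l = 25`, `σ_il = 20`,
`σ²_cg = 150`, `σ²_pe = 30`, `σ²_e = 200`; ~2,100 phenotyped animals in
100 CGs.  What the generator does **not** emulate: selection and genetic
trend, heterogeneous residual variance, repeated records, multiple traits,
genotype data, and non-random allocation of families to herds.  Passing
recovery tests therefore show the estimator is correct *for data generated
by its own model*, not that real herd data satisfy these assumptions.

## Data editing

Only CGs with at least 5 records ("more than 4") and sires with at least 3
recorded progeny are retained; records of animals with unknown sire are
exempt from the progeny rule.  Because each filter can re-violate the
other, they iterate to a fixed point (the tests compare against exhaustive
brute-force filtering); the edit is idempotent and returns an audit report.

## Known limitations

* **Weak identification at extreme slope variance.**  With a single record
  per animal, an individual's slope is informed only through relatives.
  When the simulated slope SD is large relative to the gradient scale (the
  default truth puts ~90% of phenotypic variance into `b·ℓ` products), the
  exact posterior — verified against an independent MCMC implementation of
  the same model — reallocates unresolved slope variance into `σ²_pe` and
  `σ²_l` and shrinks `σ_il` towards zero.  Credible intervals for those
  parameters then sit away from the generative values at this sample size
  even though the sampler is exact; `σ²_i`, `σ²_cg` and the gradient-level
  summaries remain well behaved.  This is a property of the model-data
  configuration, not of the implementation, and is smaller for the modest
  slope variances typical of real cattle traits.
* Residual variance is homogeneous across gradients; maternal *genetic*
  effects, unknown-parent groups and genomic relationships are out of
  scope.
* The per-gradient heritability convention (denominator without `σ²_cg`)
  and the classification centre are explicit configuration choices, since
  field usage varies.

## Problem sizes used in the tests

Unit tests run on ~200-animal herds with short chains (seconds).  The
recovery study runs 20 seeded replicates at the default study scale with
20,000-iteration chains (~10 s per fit after JIT compilation); the
reduced-model check compares a frozen-slope fit against a dense-likelihood
REML oracle on a ~300-record dataset; the Geweke calibration uses 1,000
iid chains of length 10,000.
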