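# Methods

## Model

For bear k at date-time t, the response is `y_tk = sqrt(rate_tk)` with
`rate_tk` the hourly movement rate in km/h (planar Euclidean distance
between fixes exactly one clock-hour apart). The observation model is
`y_tk = λ*_tk + ε_tk`, `ε_tk ~ N(0, σ²)`; the square-root stabilizes the
right-skewed rates. The linear predictor sums, per model variant:

- hour-of-day effects λ (one 24-vector per stratum: shared, per season, or
  per season × sex), each `λ ~ MN(0, Σ(ν, ψ))` with
  `Σ[i,i'] = exp(−ν·d_circ(i,i'))/ψ`, `d_circ = min(|i−i'|, 24−|i−i'|)`.
  The circular distance makes hour 24 and hour 1 neighbours, so the diel
  curve is periodic by construction rather than by post-hoc wrapping;
- individual effects `ω_k ~ N(α, ρ²)`; α carries the global intercept and
  the λ vectors keep their zero-mean prior;
- fixed effects μ_s (sex), γ_r (season), or their interaction ξ_rs, under
  corner constraints (female, spring, female-in-spring pinned at zero);
- distance-decay terms `β_j exp(−φ_j x_j)` (optionally per season) for
  x₁ = distance to any road = min(x₂, x₃), x₂ primary roads, x₃ secondary
  roads, x₄ settlements, all in km measured at the step's *origin* fix.

The 13 registered variants differ in which blocks they include and whether
the anthropogenic block interacts with season; `ModelSpec.k_interaction`
counts the season/sex-interacting blocks (hour-effect stratification, ξ,
and each season-specific β block), reproducing the conventional "K" column
of such selection tables.

All λ strata share a single (ν, ψ) pair: the priors are stated once for ν
and ψ, and per-stratum ranges would be weakly identified from 24 points
per stratum.

### Priors

| parameter | prior | note |
|---|---|---|
| α, μ, γ, ξ, β | N(0, 1000) | mean/VARIANCE parameterization |
| 1/ρ², 1/σ² | Ga(1, 1) | shape/rate, on the precisions |
| ψ | Ga(1, 1) | covariance scale (diag Σ = 1/ψ) |
| ν | Unif(3/24, 3) | practical range 3/ν ∈ 1–24 h |
| φ | Unif(3/4, 15) | practical range 3/φ ∈ 0.2–4 km |

"N(mean, variance)" is read literally (the noise term is stated that way);
a precision-parameterized reading would make these priors tighter but they
remain weakly informative either way, and the values are configurable in
`Priors`.

## Sampler

Metropolis-within-Gibbs, written in-house so every conditional is explicit:

- **λ vectors**, jointly per stratum: Gaussian conditional with precision
  `ψC⁻¹ + diag(n_i)/σ²` (C the unit-scale circulant, n_i the per-hour
  record counts in the stratum), sampled via Cholesky. C's inverse,
  log-determinant and quadratic forms use the circulant spectral
  decomposition (FFT of the first row), which the tests pin against dense
  linear algebra at 1e-8.
- **α, ω, ρ²** as one block: α is drawn with ω *collapsed out* (the
  per-animal residual means are `N(α, σ²/n_k + ρ²)`), then ω | α, then the
  conjugate Gamma for 1/ρ². The collapsed draw matters: the naive
  α | ω update random-walks with step ~ρ against a prior sd of ~31.6 and
  takes thousands of sweeps to traverse it; the collapsed version mixes in
  one and is what lets a zero-data run reproduce the α prior.
- **μ, γ, ξ, β**: scalar conjugate normal updates (β given its φ).
- **1/σ², ψ**: conjugate Gammas.
- **ν and each φ**: adaptive random-walk Metropolis reflected at the
  uniform prior bounds (log-scale walk for ν, with the Jacobian term in
  the acceptance ratio). Step sizes adapt by Robbins–Monro (gain
  (t+10)^−0.6) toward 0.35 acceptance during burn-in only, so the
  post-burn-in kernel is fixed and satisfies detailed balance.

Initialization: location parameters 0, variances 1, ν and φ at their prior
midpoints. Chain c uses `default_rng(seed + c)`; identical configs give
bit-identical chains. Acceptance rates are recorded post-burn-in per
Metropolis block. When a decay parameter is weakly identified (its β near
zero) its conditional is nearly flat and reflected-walk acceptance tends
to 1 regardless of step size — the (0.1, 0.6) working-range check is
therefore made on a fixture with strong amplitudes, where the target has
curvature to adapt to.

Two chain profiles ship: the full field-scale protocol (2 chains, burn-in 50,000,
20,000 kept, thin 10 → 2,000 points/chain) and a desk profile
(burn-in 2,000, 2,000 kept, thin 2 → 1,000 points/chain) used by the
analysis drivers and the test suite. Convergence is monitored with the
Gelman–Rubin PSRF; summaries pool chains post burn-in and report means with
equal-tailed 2.5–97.5% quantile intervals.

## Model selection

DIC = D̄ + p_D with D(θ) = −2 log L(θ) and p_D = D̄ − D(θ̄):
Spiegelhalter's effective-parameter count, *conditional* on all sampled
quantities including λ and ω (the focus a JAGS-style observed-data deviance
reports for this hierarchy). θ̄ takes each parameter's pointwise posterior
mean on its sampled scale (mean of σ², not of 1/σ²; mean of φ inside the
exponent). Both choices are documented here because the alternative
(marginal) focus changes absolute DIC values; on synthetic data the
*rankings* the tests assert are robust to it.

## Summaries

Curves are built per posterior draw on the sqrt scale — hour effect +
α (a "typical bear": the random-effect mean, not a specific ω_k) + fixed
effects + anthropogenic terms at a stated covariate profile (default 4 km,
effectively the asymptote since φ ≥ 0.75) — clipped at zero, squared to
km/h, and only then summarized (mean, 2.5/97.5% quantiles). Squaring a
posterior mean instead would be biased low; a property test enforces the
per-draw convention. The reported index is the typical-hour activity
(λ*)², excluding σ²; an `include_noise` flag adds σ² for the predictive
mean of the squared response. Sex-pooled ("50:50") and season-pooled curves
average the back-transformed rates per draw; averaging on the sqrt scale
is available by flag.

Active vs inactive hours: hour i is active iff its posterior-mean rate
strictly exceeds the across-hour mean of the curve; ties are inactive.
Distance-response curves hold other terms at the typical-hour profile and
report whether each amplitude's 95% CI excludes zero.

## Synthetic studies

The generator emulates the intended telemetry design: 18 bears (11 F/7 M)
by default, hourly fix schedule over March 1 – December 15 (or compact
per-season blocks for fast tests), acquisition success 0.88 (the middle of
the 0.79–0.97 range; configurable), and isotropic GPS noise scaled so the
mean radial error is 24.7 m (Rayleigh mean σ√(π/2)). Distance covariates
are drawn log-uniform on [0.02, 4] km by default so inference tests do not
depend on geometry code; alternatively bears random-walk (uniform heading,
step length = rate) over a simulated landscape of road polylines and
settlement points, and covariates are measured from the geometry at each
step's origin.

Default generating parameters: ν = 0.4, ψ = 60 (hour-effect sd ≈ 0.13),
α = 0.6, ρ² = 0.005, σ² = 0.09, |β| ~ 0.08 — i.e. λ* ≈ 0.3–0.9 on the sqrt
scale, movement rates ≈ 0.1–0.7 km/h, the regime these models are used in.
Negative draws of y are truncated at zero (a sqrt-rate cannot be negative);
the truncation fraction is attached to the emitted table and logged, with a
warning above 5%. In the default regime it is 2–6% depending on the λ draw.

Truncation is a deliberate, acknowledged misspecification: it keeps the
emitted data valid while the Gaussian model ignores it. Two consequences
for what the tests do and do not show:

- **Interval-calibration replicates use a high-baseline regime**
  (α = 1.2, truncation < 1%). Calibration of credibility intervals is a
  property of the sampler *under the model*; at 3–5% truncation the tightly
  estimated σ (posterior sd ~0.003 at n ≈ 5,000) is biased a few standard
  errors low by the clipped tail and coverage of σ would reflect the data
  misspecification, not the sampler. The truncation rate itself is tested
  separately in the default regime.
- Coverage is assessed as the empirical rate aggregated within each
  parameter family (over replicates × 12 β_jr; over 20 replicates for σ;
  over replicates × 8 strata × 24 hours for λ), with an 0.85 floor per
  family. Per-scalar 17/20 thresholds would fail ~17% of the time for a
  perfectly calibrated sampler purely by binomial noise across 12
  parameters.

What the generator does *not* emulate: autocorrelated movement (steps are
drawn independently given the hour), home ranges or habitat selection,
temporally correlated distance covariates, and state-dependent fix failure.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated generative model, not robustness to real-data features
outside it.

## Problem sizes and runtimes

The validation suite runs at desk scale by design: the conjugate oracle
uses 2 bears × 96 records; prior recovery uses 2,000 draws thinned ×20
from a zero-data run; interval calibration uses 20 replicates of 8 bears ×
~4,700 records fitted with the desk profile (single chain per replicate);
DIC discrimination uses 20 replicates per direction of 4 bears × ~1,900
records with burn-in/keep 800. These sizes give each check clear
statistical resolution while keeping the whole suite in the minutes range.

## Numerical and design choices

- Hourly standardization keeps, per (animal, clock hour), the fix closest
  to the top of the hour; ties go to the earlier fix.
- Outlier screening (the published procedure is external and undescribed):
  a symmetric speed filter — a fix is removed only if the implied speed to
  *both* temporal neighbours exceeds a threshold (default 10 km/h,
  generous for bears). Transparent, deterministic, endpoint-safe.
- A movement step is labelled with the hour index, season and covariates of
  its *starting* fix; "mid-December" is fixed at December 15 inclusive;
  midnight maps to hour 24; timestamps are treated as a single fixed local
  offset (no DST) to preserve exact 1-h spacing.
- Settlements are point centroids, roads polylines, all geometry planar in
  a projected CRS.
- Gamma-prior densities for ρ² and σ² are evaluated on the variance scale
  (precision density × Jacobian) so `log_prior` is a proper joint density
  of the stored state.
- Degenerate inputs: zero records is a supported fit (prior sampling);
  an empty hour set in the rate table yields NaN cells; a constant curve
  classifies all hours inactive (strict-inequality threshold).

## Known limitations

- The Gaussian likelihood admits negative sqrt-rates; no truncated or
  zero-inflated variant is implemented.
- DIC is the only selection criterion (no WAIC/LOO).
- The sampler is single-threaded; the full-scale protocol (52 Gibbs
  sweeps × 10⁴ on ~27k records × 13 models) is hours of compute, which is
  why the desk profile exists.
- Identifiability between α, ξ_rs and the λ strata means is soft (prior
  shrinkage of λ toward zero); curves and rate tables, which sum the
  blocks, are insensitive to this, but individual block posteriors have
  wide, correlated margins.
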