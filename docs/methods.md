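# Methods

## The problem

Cervical cancer incidence among women diagnosed with HIV varies
strongly across space and time, and the registry data that measure it
are incomplete in structured ways: cancer cases whose HIV care happened
in the private sector never appear in the public laboratory database
that defines the HIV cohort, probabilistic record linkage misses true
matches, and person-year denominators are only available at the
provincial level from an epidemic model. `iccmap` implements the full
chain — disease-mapping model, model selection, under-ascertainment
corrections, denominator disaggregation, and age-standardised
reporting — as a tested library, exercisable end-to-end on synthetic
data with known ground truth.

## Model

Counts per municipality *i*, age group *a* and calendar year *t* follow

    y_iat ~ Poisson( E_iat * exp(eta_iat) )
    eta_iat = alpha + x_i' beta + b_i + gamma_t + delta_a + theta_it

with person-years `E` as an offset. The components:

* **b — BYM2 spatial field.** `b = sigma_b (sqrt(phi) u + sqrt(1-phi) v)`
  where `u` is a scaled intrinsic CAR (ICAR) field on the contiguity
  graph and `v` iid standard normal. The ICAR structure matrix `Q` (degree
  on the diagonal, −1 between neighbours) is scaled per connected
  component by the geometric mean of the diagonal of its constrained
  generalised inverse, so the generalised marginal variances have
  geometric mean 1 and `sigma_b` is the marginal sd of the whole field;
  `phi` in [0,1] is the fraction of variance that is spatially
  structured. Sum-to-zero holds per component; singleton components
  (islands) carry no structured effect (`u = 0` there, `v` takes all
  variation).
* **gamma, delta — first-order random walks** over years and age
  groups, parameterised by their increment sd, constrained to sum to
  zero; the intercept carries the level.
* **theta — type-I space-time interaction**: exchangeable iid normal
  over (area, year) cells, i.e. unstructured-space × unstructured-time.
  No sum-to-zero constraint (it is exchangeable).
* **Covariates** enter as categorical levels: deprivation decile and
  health-facility-count decile (decile 1 — most deprived / fewest
  facilities — as reference) and binary urbanicity (rural reference).

Priors: penalised-complexity (PC) priors on all hyperparameters. For
each sd, `P(sigma > U) = alpha` with defaults `U = 1, alpha = 0.01`
(sigma ~ Exponential with rate −ln(alpha)/U). For the mixing fraction,
the PC prior built from `d(phi) = sqrt(2 KLD(phi))` with the KLD
between the BYM2 field at `phi` and the pure-overdispersion base model,
computed from the eigenvalues of the scaled-ICAR generalised covariance
on the constrained subspace; calibration `P(phi < 0.5) = 2/3` by
default. Requesting less mass below `U_phi` than the rate→0 limit
`d(U)/d(1)` is infeasible in this family and raises a configuration
error. Fixed effects get normal(0, 10²) priors (not stated by the
source analyses; configurable).

Candidate structures for model selection: the 8 subsets of
{age, time, space} plus the interaction added to each of the 4 subsets
containing the spatial effect — 12 structures, compared covariate-free
by DIC (primary), WAIC and the CPO mean log score. DIC uses the plug-in
deviance at the posterior mean of the linear predictor, which is well
defined under the constraints; WAIC uses the sample variance of the
per-cell log likelihood (defined as 0 for a single draw); the CPO
harmonic means are computed by log-sum-exp, and cells with non-finite
CPO are flagged and dropped from the mean. Lower is better for all
three; disagreements are reported, and best-by-DIC returned.

## Posterior computation

The model is a latent Gaussian model with at most five
hyperparameters, so the engine is a nested Laplace approximation —
the same approximation family as the INLA machinery this model class
is usually fitted with, implemented here directly on numpy/scipy:

1. **Non-centred parameterisation.** Latent blocks are standardised
   (`u` scaled-ICAR with unit generalised variance, `v`, interaction
   and RW1 blocks with unit increments); the hyperparameters enter as
   per-column scalings of a sparse design matrix. The latent prior
   precision is therefore hyperparameter-free.
2. **Inner Gaussian approximation.** For fixed hyperparameters, the
   latent posterior mode is found by damped Newton iterations with the
   exact Hessian `P + M' diag(mu) M` and dense Cholesky factorisation
   (latent dimension at desk scale is a few hundred to ~1500).
   Sum-to-zero constraints are imposed by a large soft precision term
   plus exact conditioning-by-kriging of the mode and of every draw;
   the conditioned distribution is invariant to the soft term, so the
   constraints hold to numerical precision (|sum u| ~ 1e-10).
3. **Hyperparameter posterior.** The Laplace-approximated marginal
   (joint mode value minus half the log determinant of the latent
   curvature) plus the PC priors is maximised coarsely (Nelder–Mead on
   the log/logit scale), a finite-difference curvature gives an
   inflated multivariate-t proposal (df 5), and two to four rounds of
   self-normalised adaptive importance sampling re-centre the proposal
   and weight the sampled hyperparameter points. The importance
   effective sample size is recorded; runs with ESS below 5% of the
   points are flagged, and summaries refuse flagged runs unless forced.
   Hyperparameter credible intervals come from weighted moments on the
   transformed (log / logit) scale with a Student-t critical value at
   df = ESS − 1 — the marginal posterior is close to Gaussian there,
   and moment intervals are markedly more stable in the tails than
   weighted order statistics at moderate effective sample sizes (they
   were validated against long ensemble-MCMC runs of the same kernel).
   An optional `emcee` backend samples the same marginal kernel by
   ensemble MCMC behind the same interface.
4. **Joint draws.** Hyperparameter points are resampled by weight; at
   each, the latent Gaussian is re-solved (warm-started Newton) and
   latent vectors are drawn and conditioned. Each draw's linear
   predictor and per-cell Poisson log likelihood are stored, which is
   what DIC/WAIC/CPO and all rate summaries consume.

Everything is driven by one master seed; two runs with the same seed
are bit-identical. Default draws: 64 hyperparameter points × 16 latent
draws = 1024; reporting runs should not go below ~1000 draws, and the
test suite uses reduced settings documented in each test.

Numerical choices: eigenvalues below 1e-8 × max count as null when
pseudo-inverting ICAR blocks; the linear predictor is clipped at ±40
inside Newton steps to guard `exp` overflow (never active at the
solution for realistic data); `d'(phi)` uses central differences with
step 1e-6; quadrature tolerances for prior normalisation checks are
1e-8. The Poisson log likelihood uses the continuous extension
`y*eta − exp(eta) − lnGamma(y+1)` so the fractional expected counts
produced by correction II are handled without rounding (a
round-to-nearest mode exists behind a flag).

## Corrections and exclusions

The exclusion cascade drops, in order: cases not linked to an HIV
record; missing/imprecise geocodes; cancers diagnosed two years or more
before the first HIV test (diagnosis offset, defined as cancer date
minus HIV-test date, strictly below −730 days; exactly −730 stays
eligible); and cases resident in excluded regions (modelled as a plain
area flag). The survivor set is order-invariant; per-rule counts are
not.

* **Correction I** (private-sector HIV diagnosis): the linked fraction
  f of all registry cases is assumed to apply to the unlinked
  private-sector cases; `floor(n_unlinked_private × f)` cases are
  resampled **with replacement** from the linked private-sector cases,
  passed through the cascade, and added to the panel — M times
  (default 100; tests use 2–20), with the per-replicate posteriors
  pooled by equal-weight Bayesian model averaging (draw
  concatenation). f is rounded to two decimals before multiplying,
  matching the published worked example (5,077 × 0.43 = 2,183).
* **Correction II** (linkage under-ascertainment): from a sentinel
  cancer assumed to occur only in the HIV-positive population, each
  area's observed counts are inflated by
  `q_m = unlinked-non-private / linked` sentinel cases (odds-style
  inflation; areas without linked sentinel cases fall back to the
  national ratio with a warning). The inflation is a per-area scalar,
  so spreading it over age and year proportionally to observed cells
  equals direct cell-wise multiplication.
* **Full correction**: the additional cases of I and II summed, per
  replicate.

## Denominators and age standardisation

Provincial person-year series are split to municipalities with weights
proportional to observed diagnosed counts per (municipality, age,
year) stratum — weights are per-stratum, not pooled — conserving
provincial totals exactly; all-zero strata get uniform weights with a
warning. Age standardisation weights the posterior draws of the
national age-year rates (person-year-weighted fitted rates per 100,000)
by the WHO World Standard population restricted to the 14 adult bands
(80–84 and 85+ pooled into 80+) and renormalised; the standard is a
plain (age group, weight) table, so Segi or any other standard can be
swapped in.

## Synthetic data

The generator emulates the study conditions: a rook-adjacency lattice
(default 10×10) standing in for the municipality contiguity map, 11
years × 14 five-year age groups, person-years built from a lognormal
area size (sd 0.5 on the log scale), a young-skewed age profile
peaking at 25–39 (the age distribution of women diagnosed with HIV),
and 8%/year growth of the diagnosed population, scaled to 750
person-years per mean cell (matching a ~24M person-year national total
over ~33k cells). True effect scales default to magnitudes anchored to
what national analyses of this outcome report: spatial sd 0.5 with
mixing 0.75 (relative rates spanning roughly 0.3–4, strongly
structured), year-walk increment sd 0.1, age-walk increment sd 0.5,
interaction sd 0.2, and covariate ramps rising to RR 3.2 (deprivation
decile 10), 1.5 (facility decile 10) and 0.85 (urban). The
reference-cell baseline of 55/100,000 person-years puts the national
crude rate near 300/100,000 once the covariate ramps and field
variances act (the convexity of exp lifts the mean above the
reference cell). Deciles are assigned by ranking
smoothed Gaussian surfaces, so covariates are spatially autocorrelated
like their real counterparts. The registry flags use 43% linkage, 16%
private-sector among unlinked, a 6.5% geocode-failure share, a 15.8%
share of diagnosis offsets violating the two-year rule (mixture with
an exponential tail below −731 days; the real offset distribution is
not published, so these are knobs, not estimates), and a sentinel
stream of 23,046 cases with 70% linkage and 27.3% private-sector among
unlinked. Tests that use fewer age groups scale person-years per cell
up to conserve the national total (e.g. 2,200 per cell with 5 groups).

What the generator does **not** emulate: real municipality geometry and
population sizes, HIV epidemic dynamics (denominator series are
conserved aggregates of the simulated person-years, not an epidemic
model), case-level HIV test histories beyond the offset field,
screening coverage and ethnicity (unavailable in the source data), and
reporting artefacts such as late registration. Passing tests therefore
demonstrate correctness of the machinery and calibration under the
assumed generative model, not robustness to real-data misspecification.

## Design choices where the design was open

* **Engine**: a Laplace-family approximation rather than MCMC over the
  joint space — the estimands (posterior medians, 95% CrIs, exceedance
  probabilities) are engine-agnostic, the model class is exactly the
  one Laplace-based machinery was built for, and the marginal
  hyperparameter space is small enough (≤5) to correct by importance
  sampling; an ensemble-MCMC backend over the same marginal exists for
  cross-checking.
* **Candidate grid**: the interaction may enter any structure that
  contains the spatial effect (12 candidates); an iid area-year effect
  is well defined without the temporal main effect.
* **DIC as primary selection key** with WAIC and CPO reported; the
  criteria usually agree, and disagreement triggers a warning rather
  than a tie-break heuristic.
* **Correction II kept fractional** (expected counts) rather than
  rounded, avoiding an arbitrary integerisation rule.
* **Age effects additive** (no age × space or age × time interaction).
* **Islands**: per-component scaling and constraints; structured effect
  pinned to zero on singletons. Real municipality maps are effectively
  contiguous, but the machinery must not crash on arbitrary graphs.

## Known limitations

* The latent-field Gaussian approximation shares INLA's behaviour for
  low-count Poisson cells: slight skewness of the exact conditional is
  ignored. At the simulated count levels (0.5–5 cases per cell) this
  is negligible relative to posterior spread.
* Hyperparameter tails rest on ≤ a few hundred weighted support
  points; extreme quantiles beyond 95% are coarse.
* Frequentist coverage of credible intervals for random-effect sds is
  intrinsically fragile when the effective replication is small: for
  random walks over 5–6 years or age groups the posterior concentrates
  on the realised path's variation, and for the spatial sd the
  spatial correlation of the field makes its realised standard
  deviation scatter far more across replicates than an iid field of
  the same size would (≈0.1 at 100 areas rather than ≈0.036). Combined
  with the PC prior's shrinkage, exact-posterior coverage of the
  nominal 95% interval for the spatial sd sits near 80–85% under the
  calibration suite's conditions — verified by re-running the missing
  replicates with long ensemble-MCMC sampling of the same marginal.
  This is a property of the model and prior, not of the engine.
* Dense Cholesky limits the latent dimension to a few thousand areas ×
  years; a sparse factorisation would be the next step for national
  full-resolution runs.
* **Spatial confounding.** With spatially smooth covariate surfaces
  (the generator's default, mirroring real deprivation maps), the
  covariate pattern partially aliases with the BYM2 field, and
  frequentist coverage of the covariate-effect credible intervals
  degrades — a documented property of areal random-effect models, not
  of this engine (the same replicates regenerated with unsmoothed,
  identifiable covariate surfaces show nominal coverage). The
  calibration suite therefore runs with
  ``covariate_smoothing_passes=0``; analyses of real data should read
  covariate effects under the same caveat the applied literature
  attaches to them.
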