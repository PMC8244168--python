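# iccmap

Bayesian spatiotemporal disease mapping of invasive cervical cancer
(ICC) incidence among women diagnosed with HIV — the full analysis
chain behind a national municipality-level incidence study, as a
tested Python library with a synthetic-data generator so every stage
runs end-to-end with known ground truth.

**Who it is for.** Epidemiologists and biostatisticians working with
areal cancer-registry data linked to laboratory-defined cohorts, where
incidence must be modelled over space, time and age while correcting
for registry linkage failure and private-sector care, and where
person-year denominators exist only at a coarser (provincial)
geography.

## The model

Counts per municipality *i*, age group *a*, year *t*:

```
y_iat ~ Poisson( E_iat · exp(η_iat) )
η_iat = α + x_i'β + b_i + γ_t + δ_a + θ_it
b_i   = σ_b ( √φ · u_i + √(1−φ) · v_i )        (BYM2)
```

with person-years `E` as offset, `u` a scaled intrinsic CAR field on
the contiguity graph (unit generalised marginal variance, sum-to-zero
per component), `v` iid normal, `γ` and `δ` sum-to-zero first-order
random walks over year and age, and `θ` an exchangeable type-I
space–time interaction. Penalised-complexity priors on all
hyperparameters: `P(σ > 1) = 0.01` for each sd and `P(φ < 0.5) = 2/3`
for the mixing fraction. Candidate structures (the 8 subsets of
{age, time, space} plus the interaction on each spatial subset — 12 in
all) are ranked by DIC, WAIC and the CPO mean log score.

Around the model sit the study's data corrections: the case-selection
cascade (linkage, geocodes, the two-year HIV-test rule, excluded
regions), correction I (oversampling linked private-sector cases,
pooled by Bayesian model averaging over replicates), correction II
(per-area inflation from a sentinel cancer's linkage proportions),
their sum ("full correction"), provincial→municipal person-year
disaggregation with diagnosed-count weights, and age standardisation
with WHO world-standard weights.

Posterior computation is a nested Laplace approximation (the model is
a latent Gaussian model with ≤5 hyperparameters) with adaptive
importance sampling over the hyperparameters and an optional `emcee`
ensemble-MCMC backend; see `docs/methods.md`.

## Worked example

Simulate a national-shaped panel (10×10 contiguity lattice, 11 years,
14 age groups, ~300 cases per 100,000 person-years), then rank the 12
candidate structures on a compact panel and fit the full
covariate-adjusted model:

```
$ python analysis/01_simulate_data.py
areas=100 years=11 ages=14
total cases=34675, person-years=11550000
registry rows=34675 (linked 42.5%)

$ python analysis/02_exclusion_cascade.py
published stratum counts:
           rule  removed  remaining
       unlinked    32393      24768
        geocode     1607      23161
early_diagnosis     3666      19495
excluded_region     1674      17821
-> 17821 analytic cases of 57161
```

The cascade on the published stratum counts reproduces the study's
selection flow exactly: 57,161 registered cases reduce to 17,821
analysis-eligible ones. `03_model_selection.py` then fits all 12
structures; on data generated from the full model the spatial
structures dominate (the four spatial-effect-free candidates trail by
hundreds of DIC units) and the generating structure sits at or near
the top — it attains the smallest DIC in at least nine of ten
replicates in the calibration suite.
`04_fit_full_model.py` fits the covariate-adjusted full model on the
simulated panel (truth: σ_b = 0.5, φ = 0.75, deprivation ramp rising
to RR 3.2) and prints, among other summaries:

```
      hyper  median  lo95  hi95
    sigma_b   0.505 0.412 0.618
        phi   0.834 0.311 0.982
...
                label  median  lo95  hi95  pr_gt_1
 deprivation_decile_2   1.156 0.793 1.718    0.759
...
deprivation_decile_10   2.370 1.441 4.088    0.999
...
spatial RR medians span 0.33 .. 3.93; 28 of 100 areas with Pr(RR>1) > 0.95
```

— the spatial-field sd is recovered, the mixing fraction's posterior
mass sits on strongly structured variation, the deprivation gradient
rises monotonically with Pr(RR > 1) ≈ 1 in the upper deciles, and the
spatial relative rates span the order-of-magnitude range national
analyses of this outcome report. `05_corrections.py` builds the
corrected panels (on this registry: 42.5% linked, 1,383 oversampled
correction-I cases; corrected totals 34,675 → 45,461 → 46,548 for
none → II → full) and `06_age_standardised_rates.py` reports the
age-standardised incidence per year under each correction
(e.g. 248 → 294 per 100,000 person-years across 2004–2014 without
correction, 332 → 391 with the full correction).

Numbers to expect: the correction-I arithmetic yields a 43% linked
fraction and 2,183 oversampled cases from the published counts; the
sentinel-cancer shares are 8.2% unlinked-private and 21.8% unlinked
non-private; the 2-node-path ICAR scaling factor is 0.25.

## Layout

```
src/iccmap/        library: graphs, priors, model, inference,
                   simulate, corrections, denominators, io
analysis/          numbered drivers writing results/ tables
tests/             unit, property and acceptance suites
scripts/           acceptance.py
docs/methods.md    model, engine, generator and design notes
```
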