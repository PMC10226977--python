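# Methods

## The model

`aftclock` fits a multivariate latent time-shift model — an "accelerated
failure time" style nonlinear mixed-effects model — to long-format
longitudinal biomarker data. Each biomarker k has a single common,
nondecreasing progression curve g_k defined on an *adjusted age* axis.
Person i's measurement of marker k at chronological age a is modeled as

    y = g_k(a + x_i' beta_k + u_ik) + eps,    eps ~ N(0, sigma_k^2)

- `x_i` — person-level covariates: APOE ε4 carriership (with an explicit
  `unknown` third level), female sex, years of education (centered at the
  cohort mean), and clinic-referral status.
- `beta_k` — covariate effects **in years**; positive values shift the
  curve left, i.e. earlier onset for that marker.
- `u_i = (u_i1, ..., u_iK)` — per-person onset adjustments in years, drawn
  from N(0, diag(tau) R diag(tau)). `tau_k` is the between-person SD of
  marker k's onset timing; `R` is the correlation matrix of adjustments
  across markers and the primary scientific estimand: R(j,k) near 1 means
  people early on marker j are also early on marker k (a shared timeline);
  R near 0 means the processes are temporally unrelated.

All markers are transformed so that progression increases the value:
natural-log SUVR for amyloid and tau PET (tames right skew), WMH volume as
percent of intracranial volume (identity scale by default, configurable),
and 1 − FA for fractional anisotropy. Validation-cohort style inputs use
centiloid/200, log tau SUVR, WMH%/5 and 1 − FA.

## Curves

g_k is an I-spline (integrated M-spline) mixture: cubic, five equally
spaced interior knots spanning adjusted ages 40–110 y, nonnegative weights,
plus a free intercept. Nonnegative weights make every curve monotone by
construction in every posterior draw; linear-looking trends (the FA
pattern) emerge as a special case without special-casing. Outside the
support the curve extends flat, so extreme adjusted ages have zero
gradient rather than wild extrapolation.

## Identifiability

Adding δ years to every u_ik of one marker while translating that marker's
knots by the same amount leaves the likelihood unchanged (verified to
1e-8 in the tests). The zero-mean prior on u plus fixed knot locations
break this translation invariance; covariates are reference-coded so the
common curve describes a male, APOE-noncarrier, population-based person of
average education.

## Priors

Weakly informative and config-overridable (`PriorConfig`): beta ~ N(0,
10 y); tau ~ half-N(10 y); curve weights ~ half-N(1) on the standardized
response scale; intercepts ~ N(0, 5); sigma ~ half-N(1); R ~ LKJ(1) via a
tanh canonical-partial-correlation Cholesky parameterization. Education's
effect is per year of schooling. Unknown APOE status is its own indicator
level with an estimated effect, so no one is dropped and no imputation
model is needed.

## Inference

Sampling is Hamiltonian Monte Carlo with NUTS-style trajectories,
implemented in `aftclock.hmc` against analytic gradients of the joint log
density (`aftclock.aft_model._Posterior`, hot loops compiled with numba in
`aftclock._kernels`). The gradients — including the backprop through the
correlation-Cholesky transform — are verified against finite differences
in the test suite. Numerical choices:

- Non-centered parameterization of u (standard normals times the Cholesky
  factor of the covariance) to avoid funnel geometry between tau and u.
- The response is standardized per marker inside the sampler (curvature
  would otherwise differ by an order of magnitude across markers because
  residual SDs do); intercepts, weights and sigmas are mapped back to the
  transformed scale when draws are unpacked.
- Warmup adapts the step size by dual averaging (target acceptance 0.8)
  and a diagonal mass matrix over two expanding windows; each window ends
  with a fresh step-size search.
- A draw is divergent when the Hamiltonian error exceeds 1000; divergences
  and split-R-hat (threshold 1.05, via arviz) feed a `converged` flag on
  the returned posterior. A non-converged fit is returned flagged, not
  discarded.
- Library defaults are 4 chains × 1000 warmup + 1000 draws; the test suite
  and the recovery experiments use smaller, explicitly stated settings
  (e.g. 2 × 400 + 400) chosen as the package's own test-scale trade-off.
- Credible intervals are equal-tailed; summaries of R use draws of the
  model-level correlation parameter, never the empirical correlation of
  per-person point estimates.

Participants who never contributed a marker still carry u draws for it
(from the conditional prior — this is what lets unbalanced panels fit in
one joint model), but those prior-only entries are masked out of every
summary, table and figure.

## Harmonization

Scanner changes are handled by Deming (errors-in-variables) regression on
a crossover sample measured on both systems, with the error-variance ratio
λ defaulting to 1 (the study does not report λ; it is config). The package
ships the published GE→Siemens maps (WMH%: −0.0357 + 0.9276·x with an
anti-extrapolation floor of 0.01; FA GCC: 0.2644 + 0.5988·x, no floor) and
can refit maps from data. Harmonization maps the designated source scanner
onto the reference before modeling; direction is configuration.

## The synthetic generator

The real cohorts are restricted-access, so `aftclock.synthetic` generates
cohorts from exactly the generative model being fit, with ground truth
retained for recovery tests. Default study conditions emulate the
published cohort description:

- Visit-count margins per marker (probabilities of 0/1/2/3+ scans):
  amyloid 0/.49/.24/.27, tau .40/.36/.16/.08, WMH .01/.39/.26/.34,
  FA .17/.40/.25/.18; the 3+ bucket adds a Poisson(0.8) tail. Inter-visit
  gaps ~ N(2.5, 0.5²) y truncated at 0.5 (the study does not report gap
  distributions; this is a stand-in, config-exposed).
- Entry ages ~ N(70, 10²) truncated to [50, 95]; covariate prevalences:
  31% APOE carriers, 6% unknown, 48% female, education ~ N(15, 3²),
  11% clinic-referred.
- True covariate effects follow the published effect table (e.g. APOE→
  amyloid 9.0 y, referral→tau 29.4 y); tau = 10 y per marker; R has the
  block structure strong amyloid–tau (0.60), moderate WMH–FA (0.45),
  cross-block 0.05.
- Curves: generalized-logistic sigmoids for amyloid/tau/WMH and a linear
  trend for 1−FA, parameterized so native-scale ranges match the published
  cohort summaries (SUVR ≈ 1.3–2.8 and 1.1–2.6, WMH% ≈ 0–5, FA ≈
  0.52–0.68). Values are generated on the transformed scale and
  inverse-transformed, clipping FA into (0.01, 0.99).
- Reproducibility: one root seed; per-participant substreams are spawned
  from it, so the first m participants are identical for any cohort size
  ≥ m, and identical seeds give byte-identical CSVs.
- An optional two-scanner artifact assigns calendar entry years and pushes
  pre-switch MRI values through the *inverse* harmonization map plus extra
  noise, so the harmonization stage is exercised end to end.

What the generator does **not** emulate: diagnosis labels and
diagnosis-dependent sampling, visit attrition correlated with disease
severity, residual correlation between markers measured at the same visit,
floor/ceiling censoring of PET, and site effects beyond the two-scanner
artifact. Passing recovery tests therefore demonstrate that the estimator
inverts its own generative model at realistic size/missingness — not that
the model is correctly specified for any real cohort.

## Validation experiments (run by the test suite)

- **Parameter recovery**: 5 cohorts (n=300, the visit structure above, 40%
  missing tau) simulated from known truth with R(amyloid,tau)=0.60,
  R(WMH,FA)=0.45, cross-entries 0.05 and β(APOE→amyloid)=9 y, then refit
  blind at 2 chains × 400+400. Required: each R entry recovered within
  ±0.15 on average, 95% CIs covering truth in ≥4/5 cohorts, β̂ in (7, 11).
  Five cohorts is the reduced-replicate version of a 20-cohort design,
  keeping the same 85% coverage bar at test-suite scale.
- **Ordering**: amyloid plus three "stage composite" markers generated
  with decreasing true correlations 0.55/0.50/0.45 to amyloid and mutual
  correlation 0.98 (stage composites derived from the same scan are
  near-collinear), sharing one visit schedule, with a small (0.04)
  stage-specific residual SD — the stage-specific noise left after the
  scan-level component that the independent-residual model cannot
  represent. The fitted correlations must preserve the ordering in ≥8/10
  seeded replicates. This experiment is a property check of the estimator
  and is powered accordingly (n=350, full stage visit coverage);
  participants with no stage visits would contribute nothing and are not
  simulated.
- **Generator calibration**: empirical correlation of realized shifts
  within ±0.03 of configured R at n=5000; missing-tau fraction within
  ±0.02 of 0.40 at n=10000; the 80% coverage ellipse contains 80% ± 2% of
  10⁵ simulated bivariate-normal points.
- **Oracles**: the joint log likelihood equals a brute-force sum of normal
  log densities (1e-10); the Deming fit equals its closed form and inverts
  under axis swap at λ=1; curve evaluation matches quadrature of its
  density basis (1e-6); the likelihood is invariant under matched (u,
  knot) translations (1e-8).

## Known limitations

- Gaussian residuals on the transformed scale are assumed; no robust or
  heteroskedastic error option.
- The common-curve assumption (everyone follows one trajectory per marker,
  only shifted in time) is the model's core simplification; systematic
  shape differences between people would be absorbed into u and sigma.
- Plain NUTS with a diagonal metric: posteriors with strong global
  correlations (curve level vs. covariate effects) mix slowly; at test
  scale, split-R-hat on the slowest estimands can sit slightly above 1.05
  and the `converged` flag reports it honestly.
- Time-varying covariates, survival outcomes, and model comparison are out
  of scope.
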