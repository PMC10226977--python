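# aftclock

Latent time-shift modeling of longitudinal imaging-biomarker progression.

## The problem

Do two disease processes run on a shared clock? For Alzheimer's disease
(amyloid and tau PET) versus cerebrovascular small-vessel disease (white
matter hyperintensities, WMH, and fractional anisotropy in the genu of
the corpus callosum, FA GCC), coexistence in the same brains does not
settle whether the processes are mechanistically linked. A sharper
question is *temporal*: if a person starts accumulating amyloid earlier
than their demographic peers, do they also develop WMH earlier?

`aftclock` answers this with an accelerated-failure-time style nonlinear
mixed-effects model. Every biomarker k follows one common nondecreasing
curve g_k over an *adjusted age* axis; each person is shifted left or
right along it:

    y_ik(a) = g_k(a + x_i' beta_k + u_ik) + eps,   eps ~ N(0, sigma_k^2)
    u_i ~ N(0, diag(tau) R diag(tau))

Covariate effects `beta_k` and per-person onset adjustments `u_ik` are in
years (positive = earlier onset). The correlation matrix **R** of the
adjustments across markers is the estimand: R(amyloid, tau) ≈ 0.6 means
amyloid timing explains ~36% (R²) of tau timing; R ≈ 0 means the
processes are temporally unrelated. Inference is Bayesian via
Hamiltonian Monte Carlo with analytic gradients (implemented in-package;
see `docs/methods.md`).

The package is aimed at biostatisticians and imaging researchers who want
to fit, simulate, and stress-test this model class: it ships the full
simulate → harmonize → fit → report pipeline, including the study's
biomarker derivation formulas (WMH as % of intracranial volume,
voxel-count-weighted PET meta-ROIs, sex-specific head-size adjustment of
hippocampal volume, validation-cohort rescalings) and crossover-based
Deming scanner harmonization with the published GE→Siemens maps.

## Worked example

Simulate a realistic cohort (n=300; ~2000 observations; 40% of
participants with no tau PET; visit counts, covariate prevalences and
curve shapes emulating a population-based aging cohort), fit it, and
report — all from one config:

```python
from aftclock.reporting import run_pipeline

manifest = run_pipeline(
    {
        "seed": 1000,
        "cohort": {"n_participants": 300},
        "harmonize": {"enabled": False},
        "mcmc": {"chains": 2, "warmup": 400, "draws": 400, "max_depth": 7},
    },
    "out/",
)
```

`out/adjustment_correlations.csv` from this exact run:

```
   marker_1 marker_2   mean  ci_low  ci_high  pct_variance_explained
amyloid_pet  tau_pet  0.519   0.328    0.666                  26.907
amyloid_pet  wmh_pct -0.060  -0.201    0.077                   0.363
amyloid_pet   fa_gcc -0.042  -0.186    0.111                   0.181
    tau_pet  wmh_pct -0.052  -0.201    0.107                   0.270
    tau_pet   fa_gcc  0.124  -0.151    0.329                   1.529
    wmh_pct   fa_gcc  0.363   0.219    0.487                  13.184
```

The generator's truth for this cohort was R(amyloid, tau) = 0.60,
R(WMH, FA) = 0.45, all cross-block entries 0.05: the fit recovers the
block structure — a strong amyloid–tau coupling, a moderate WMH–FA
coupling, near-zero in between — with 95% credible intervals covering the
truth. Covariate effects land on the simulated truth too
(`covariate_effects.csv`, amyloid rows; true APOE effect 9 y, referral
19 y):

```
     marker     covariate  mean  ci_low  ci_high
amyloid_pet apoe4_carrier  8.90    6.29    11.98
amyloid_pet      referral 18.52   14.17    23.44
```

Read: carrying an APOE ε4 allele shifts amyloid onset ~8.9 years earlier;
clinic-referred participants are ~18.5 years "older" on the amyloid
clock. The run manifest records diagnostics (`max_rhat`, divergence
count) and sets `converged: false` whenever split-R̂ exceeds 1.05 on any
headline estimand — at this deliberately small test scale the slowest
estimands sit above that bar, so treat intervals as approximate and scale
up chains/draws for production use.

The same pipeline is scriptable from the shell:

```bash
aftclock simulate --seed 4 --n 300 --out cohort/
aftclock harmonize fit --pairs crossover.csv --out wmh_map.json
aftclock run --config pipeline.yaml --out results/
```

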