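# Methods

## The model

`zolekpd` implements a kinetic-pharmacodynamic (K-PD) analysis of the effect
of intravenous zoledronic acid on lumbar-spine bone mineral density (BMD).
Zoledronic acid binds bone mineral within hours, while BMD responds over
months to years; plasma concentrations are both hard to link to effect-site
exposure and absent from aggregate literature data.  The K-PD formulation
sidesteps pharmacokinetics entirely: each dose D (ng) enters a virtual
compartment with first-order loss,

    dA/dt = −KDE·A,        IR(t) = KDE·A(t),

and the virtual infusion rate IR (ng/month) drives an indirect-response
model of BMD R (g/cm²) through an Emax stimulation of the synthesis rate,
attenuated by an exponential tolerance term:

    dR/dt = KS·(1 + IR/(EDK50 + IR))·Tol(t) − KD·R,
    Tol(t) = exp(−K·(t − t_first dose)),     R(0) = KS/KD = BASE.

Assumptions worth stating explicitly:

* **Stimulation is bounded**: the Emax form caps the synthesis multiplier
  below 2, whatever the dose.
* **Tolerance is a single global clock.**  `Tol` decays from the first
  administered dose and never resets.  In every bundled trial design the
  first dose coincides with study start, so the two candidate conventions
  (study time vs time since first dose) are indistinguishable on these data.
* **Tolerance multiplies all synthesis**, including the drug-free part, as
  the response equation is written.  A side effect is that the drug-free
  trajectory itself drifts downward over years (≈7% over 72 months at the
  default parameters), which is not unreasonable for an untreated
  osteoporotic population but is a structural artifact to keep in mind for
  long-horizon extrapolation: as t → ∞ with no drug, R → 0.
* **Baseline ties synthesis to degradation** (KS = BASE·KD), so percent
  change from baseline is invariant to BASE; the choice of baseline for
  simulation is cosmetic.

### Parameters (defaults = the published population estimates)

| name     | meaning                                   | unit     | default  |
|----------|-------------------------------------------|----------|----------|
| `kde`    | virtual-compartment elimination rate      | 1/month  | 0.08150  |
| `kd`     | BMD degradation rate                      | 1/month  | 0.00474  |
| `edk50`  | infusion rate at half-maximal stimulation | ng/month | 41300.0  |
| `k_tol`  | tolerance decay rate                      | 1/month  | 0.00754  |
| `base`   | baseline BMD, supplied per study arm      | g/cm²    | per arm  |
| `omega2` | variance of the log-scale EDK50 random effect | —    | 0.45410  |
| `sigma2` | additive residual variance on BMD         | (g/cm²)² | 0.00005  |

Internal units are ng and months throughout (1 mg = 10⁶ ng), forced by the
unit of `edk50`; the CLI converts mg at the boundary.

## Numerics of the structural model

Because the virtual compartment is linear, A(t) and IR(t) are computed
exactly by superposition of dose contributions.  R obeys a linear ODE whose
forcing is smooth between dose events, so `simulate` evaluates the exact
integrating-factor solution

    R(t) = e^(−kd·t) · (BASE + ∫₀ᵗ e^(kd·s) f(s) ds)

with composite 7-point Gauss–Legendre quadrature on panels no longer than
3 months, split at every dose event and at the tolerance-clock start so no
panel straddles a discontinuity of the forcing.  This is both faster and
more accurate than a generic ODE solver here: against the drug-free closed
form the error is at machine precision, and against a fixed-step RK4
reference with dosing it agrees to the reference's own error floor (~1e-6).
Speed matters because the population estimator evaluates arm trajectories
inside a doubly nested optimisation; a kernel object caches the quadrature
layout and every node quantity that depends on a single parameter.

Degenerate inputs: coincident doses are summed into one event; an empty
regimen yields the analytic drug-free solution; `kd == k_tol` needs no
special-casing because the quadrature never forms the (kd − k_tol) ratio.

## Population layer

Each literature study arm is one "individual" (the fitted series are
arm-level means), with:

* a log-normal random effect on EDK50 only — `edk50_i = edk50·exp(η_i)`,
  `η ~ N(0, ω²)`.  The published variability estimate (0.4541) is only
  interpretable as a log-scale variance (≈74% CV); an additive η of that
  variance on an EDK50 of 41,300 ng/month would be numerically inert.
  Random effects on the other rate constants are fixed to zero, matching
  the published model.
* additive Gaussian residual error on absolute BMD (σ ≈ 0.0071 g/cm²,
  ~1% of a typical baseline).  A proportional alternative is available via
  `PopulationModel(residual="proportional")`.
* per-arm BASE anchored to the arm's earliest observation, not estimated.

Estimation maximises a Laplace approximation to the marginal likelihood:
the empirical-Bayes mode of each arm's η is found by a warm-started,
safeguarded Newton iteration (finite-difference derivatives, step tolerance
1e-10, bounded-Brent fallback), and the curvature correction uses a central
second difference (step 1e-3, balancing truncation against cancellation —
verified exact to <1e-8 on conjugate linear-in-η toys).  The outer search
runs Nelder–Mead on log-transformed (kde, kd, edk50, k_tol, ω², σ²) with
absolute objective tolerance 1e-5 (≈1e-8 relative at the typical −2LL
magnitude).  Standard errors come from a finite-difference Hessian of the
objective at the optimum, mapped to the natural scale by the delta method;
the condition number is the eigenvalue ratio of the resulting correlation
matrix.  Arms are unweighted by default (mirroring an aggregate fit of
arm-level means); `weights=` accepts per-arm likelihood weights such as
subject counts.

A generic likelihood-ratio stepwise scaffold
(`stepwise_covariate_search`, forward ΔOFV > 6.63 / backward > 10.83) ships
disabled: the final model carries no covariates, so nothing in the pipeline
calls it.

## Synthetic data: what it emulates and what it does not

`synthetic.default_designs()` transcribes the ten pooled osteoporosis trial
arms (6,014 subjects; single doses of 1–5 mg and annual 5 mg regimens for
2–6 years; baseline vertebral BMD 0.64–1.06 g/cm²).  Three of the trials
randomised subjects across 1/2.5/5 mg single doses; one representative dose
per trial is used (1, 2.5 and 5 mg) so the defaults span the studied dose
range.  Follow-up lengths follow each trial's stated duration; observations
fall every 6 months from baseline.

The generator draws one η per arm, simulates the arm trajectory at its
design baseline, and adds i.i.d. residual noise to each scheduled
observation (non-positive draws are redrawn; at σ ≈ 0.007 this is
essentially never exercised).  Arms use independent child streams spawned
from the root seed, so extending a design list never perturbs existing
arms, and a fixed seed reproduces the dataset byte for byte.

Features of the real data deliberately *not* emulated: irregular digitised
sampling times, graph-digitisation error (subsumed into σ²), dropout,
missed doses, and DXA drift.  Passing recovery and calibration tests on
these synthetic designs therefore demonstrates that the estimator is
consistent with its own assumptions under the published design — not that
those assumptions hold for any particular real trial.

## Diagnostics

* **GOF**: PRED (η = 0), IPRED (empirical-Bayes η), IWRES, and whitened
  WRES.  Anchoring BASE to the first observation makes that observation's
  residual structurally zero (flagged `anchor`) and propagates its
  measurement noise multiplicatively into later predictions; WRES therefore
  whitens with the first-order marginal covariance
  σ²(I + ρρᵀ) + ω²GGᵀ, where ρ is the prediction relative to baseline and
  G the η-sensitivity.  On self-generated data this brings the residual
  distribution to approximately N(0,1); the residual miscalibration left is
  the first-order linearisation of the exponential η.
* **VPC**: replicate datasets are simulated under the observed design; per
  time bin the observed 5th/50th/95th percentiles (2.5/97.5 available as
  the CI variant) are compared with the median and 95% envelope of the same
  percentile across simulations.  Bins are the union of scheduled
  observation times.  Late bins are carried by the few long-follow-up arms,
  so single-dataset coverage is a strongly correlated statistic; the
  calibration test averages coverage over replicate datasets.
* **Bootstrap**: study arms (the only exchangeable unit) are resampled with
  replacement and refitted; medians and 2.5/97.5 percentiles are reported,
  with the result flagged unreliable above 20% replicate failures.
* **Shrinkage**: η-shrinkage = 100·(1 − SD(EBE η)/ω); ε-shrinkage =
  100·(1 − SD(IWRES)), excluding anchor residuals.  Mildly negative values
  occur on rich designs because the noisy baseline anchor inflates the
  apparent spread of the EBEs.

## Regimen simulation and the efficacy rule

Candidate schedules (single doses 0.5–5 mg; the same amounts annually; 1 mg
half-yearly ×6 and 5 mg yearly ×3) are simulated for a population of
virtual individuals on a monthly grid over 72 months, and percent change
from baseline is summarised pointwise by median and 2.5/97.5 percentiles.
The percentiles describe model-response variability; residual measurement
noise is not added.  A regimen "meets efficacy" when its median series
reaches the 3% clinical threshold at any grid point within the horizon (a
conservative variant applies the rule to the 2.5th percentile).  Ranking
among meeting regimens is by total administered mass, tie-broken by earlier
crossing — the "lowest effective regimen" reading — with non-meeting
regimens listed after by peak change.  At the published parameter values
the 1 mg half-yearly schedule (6 mg total over 3 years) meets the rule with
less than half the drug of the standard 5 mg yearly ×3 (15 mg), which is
the package-level reproduction of the study's headline recommendation.
Note that low single doses also cross 3% at their peak under this rule;
the annual low-dose schedules additionally show the rapid post-cessation
decline that argues against them.

## Acceptance experiments and problem sizes

The original fit was performed on digitised literature trajectories that
were never deposited, so it cannot be re-run verbatim.  The package instead
re-estimates from self-generated data: 20 replicate synthetic datasets of
40 arms each (the ten designs, replicated and relabelled) are generated at
the published population values and refitted; the median estimates are
compared against the published bootstrap 95% intervals.  These sizes keep
the full experiment in the few-minute range on one core while leaving the
medians stable; the bootstrap test uses 10 resamples of a 40-arm dataset
and the VPC calibration 200 simulations × 20 datasets, chosen on the same
grounds.  The known finite-sample wrinkle is a ≈+20% median bias in KD,
driven by conditioning each arm's BASE on its noisy baseline observation
(errors-in-variables); it sits well inside the published interval for KD
and vanishes as σ² → 0.

## Exposure–response of the acute-phase reaction

APR counts are pooled within dose groups (1, 4, 5 mg); incidence comes with
exact Clopper–Pearson intervals (one group has n = 12, so a normal
approximation would be inappropriate), and dose dependence is tested by a
Cochran–Armitage-style linear-by-linear trend with dose scores.  The
bundled count table reproduces the published per-study counts, including
one impossible row (27 events of 20 subjects in a 5 mg study); the loader
flags and excludes it rather than pooling it, so the pooled 5 mg incidence
here (64.7%, 488/754) is computed from the internally consistent rows only
and deliberately does not match the published 65.7%, whose provenance
cannot be reconstructed from the printed counts.  The 4 mg group (50.0%,
6/12) matches exactly; the 1 mg table row gives 40.7% (11/27) against a
published 40.0%.

## Known limitations

* The estimator is a Laplace approximation, not FOCE-I; on these designs
  the two agree closely in simulation, but objective values are not
  comparable across implementations.
* BASE is anchored, not estimated; with 1% baseline noise this induces the
  small KD bias described above.
* The tolerance formulation drives the drug-free response to zero at
  infinite time; do not extrapolate drug-free trajectories beyond the
  study horizon.
* Arm-level aggregate data cannot identify subject-level variability; ω²
  here is inter-arm, and simulated percentile bands describe arm means,
  not individual patients.
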