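# Methods

## The model

Migraine classification usually distinguishes only "active migraine"
(symptoms within the last year) from "no active migraine". This package
implements a three-state extension that splits the no-active pool into
*never migraine* (S0) and *inactive migraine* (Ci, remitted after a
previously active phase), alongside *active migraine* (Ca):

    S0 --i0--> Ca --r--> Ci --f--> Ca

with age-dependent hazards per person-year: first incidence i0, remission
r, reactivation f. No differential mortality is assumed, so a cohort is
closed and the three occupancies sum to the cohort size exactly. All three
state prevalences follow once the hazards are known; the package's job is
estimating the hazards from two data sources and simulating the cohort.

### Remission from the illness-death balance (module `remission`)

In the two-state illness-death view (active vs not-active, no differential
mortality), the active-state prevalence p(a, t) satisfies

    dp/da + dp/dt = i * (1 - p) - r * p,

where i is the incidence applied to everyone not currently active (the
pooled S0 + Ci denominator, as burden-of-disease studies report it).
Given smooth fitted surfaces p(a, t) and i(a, t), this is solved directly:

    r(a, t) = (i * (1 - p) - dp/da - dp/dt) / p.

The calendar-time term dp/dt is included by default and can be switched
off (`include_dp_dt`) as a sensitivity option. Negative inverted rates are
kept (flagged) in raw output — they diagnose surface misfit — and clamped
to zero only where a proper hazard is required, inside the cohort
simulator.

Uncertainty: a parametric bootstrap redraws every input record from
Normal(value, (upper − lower)/(2·1.96)) truncated to its admissible range,
refits both surfaces, and recomputes the curve; the point estimate is the
pointwise median over resamples (a plug-in curve from the unperturbed fit
is kept alongside) and the band the 2.5th/97.5th percentiles. Default
1,000 resamples. The bands quantify input-uncertainty propagation through
the fit; they do not include structural (model-form) error.

### Surfaces (module `surfaces`)

p and i are modelled per sex and location as linear forms on a transformed
scale — logit link for prevalence, log link for incidence — with a
polynomial in age, a linear term in calendar year, and an age×year
interaction, fitted by (optionally inverse-UI-weighted) least squares via
statsmodels. Derivatives are analytic from the fitted form; no data-level
finite differencing, which would amplify noise in the inversion above.

Two numerical choices matter and were set by a design study on synthetic
worlds with known hazards:

* **Age degree 13 (default).** The inversion divides a derivative by p, so
  remission error is dominated by d/da bias. Low-order global polynomials
  (cubic: >20% error at interior ages) leave bias that also ruins
  bootstrap-band coverage, because with ~540 records the bands are narrow.
  GBD-style age profiles have at most 18 support midpoints and are
  themselves smoothed model output, so a near-interpolating high-order
  polynomial behaves like a smooth quasi-nonparametric age curve: with it,
  noiseless recovery error is ~0.01–0.08% at ages 30–60 and ≤7.4% over
  17.5–72.5, and 95% bands cover the generating hazard at ≥90% of grid
  ages under 5% UIs.
* **Fitting window 12.5–82.5 (default).** The open-ended oldest groups
  have poorly defined midpoints and dominate global misfit; restricting
  the training window so the reporting range 17.5–72.5 sits interior to it
  removes most endpoint bias. Both settings are `SurfaceSpec` fields.

Age and year are centred/scaled before the basis is built, keeping the
normal equations well conditioned at degree 13. Prevalence predictions are
clamped to (0, 1) at 1e-9; clamping never activates on well-posed inputs.

### Lifetime stage (module `lifetime`)

Lifetime prevalence q0(a) pins down what the burden-of-disease extract
cannot: p0 = 1 − q0 and the first-incidence hazard among the never pool,

    i0(a) = q0'(a) / (1 - q0(a)),

which holds because the never pool is depleted only by first onset (no
re-entry, no differential mortality). The input is a small survey table
(four 10-year age groups per sex with 95% CIs, attributed to group
midpoints). Uncertainty is propagated by drawing 5,000 complete tables
(Normal per point, sd = CI-width/3.92; draws outside (0, 1) treated as
missing — negatives are not prevalences, and ≥1 has no logit), fitting
OLS of logit(q0) on age, sex (0 = male, 1 = female) and age×sex to each,
discarding *inadmissible* fits (b1 ≤ 0 or b1 + b3 ≤ 0, i.e. lifetime
prevalence not increasing in age for one sex), and pooling survivors by
coordinate-wise median. Under the pooled logit-linear form the identity
reduces to i0(a) = (b1 + b3·s) · q0(a). The admissible-set count is
reported but is input- and seed-dependent; only its reproducibility under
a fixed seed is asserted.

### Cohort simulation (module `multistate`)

The extended model runs as a deterministic expected-value Markov cohort
(recursion on compartment counts, not a microsimulation): explicit Euler
steps of h = 0.01 years over 30 years of follow-up for a cohort of
N = 100,000 starting at age 30 in calendar year 1990, age and year
advancing in lockstep. The update conserves the total exactly (to float
rounding, <1e-6 over 3,001 steps) and refuses steps with h·hazard ≥ 1.
Halving h moves end-of-follow-up prevalences by <0.1%, so O(h) Euler error
is negligible at the default step.

The reactivation hazard is not directly observable. It is recovered each
step from the balance identity that makes the extended model's inflow into
Ca equal the pooled incidence applied to the no-active pool:

    f = (i_gbd * (S0 + Ci) - i0 * S0) / Ci,

with two guards: when Ci < 1e-6·(S0 + Ci) the identity is ill conditioned
and its uniform-incidence limit f = i_gbd is used (flagged); a negative
solution is clamped to 0 (flagged). Initial occupancy takes Ca from the
prevalence surface at (30, 1990), S0 from the lifetime stage's p0(30), and
Ci as the remainder, floored at zero with a flag if the two sources
disagree enough to imply a negative count.

## The synthetic worlds (module `synthetic`)

Every estimation stage is validated against worlds whose hazards are known
exactly. A world fixes i0, r, f per sex; `solve_truth` integrates the
dynamics on a fine grid (h ≤ 0.005), also deriving the pooled incidence
i_gbd = (i0·S0 + f·Ci)/(S0 + Ci) and q0 = 1 − p0. Emitters aggregate to
the 5-year age groups over 1990–2019 with fabricated relative UIs
(multiplicative Normal(1, noise/1.96) perturbation, limits value·(1∓noise))
and to the four lifetime groups per sex. At zero noise the emitted tables
equal the truth at the group midpoints, giving noiseless recovery oracles.

The default world is parameterized once to echo the broad epidemiology of
migraine rather than any one dataset:

* **First incidence** is derived from a logit-linear lifetime-prevalence
  surface anchored at lifetime prevalences 5.6% → 9.4% (men) and
  19.8% → 32.5% (women) between ages 25 and 65 (the magnitudes reported
  for Northern European adults), implying i0 of 0.08→0.13% and
  0.33→0.54% per year respectively. Deriving i0 from a logit-linear q0 —
  rather than positing an arbitrary hazard shape — makes the world satisfy
  the structural assumption the lifetime regression relies on, so its
  recovery error measures estimation, not deliberate misspecification.
  Because a logit-linear q0 is nonzero at the integration start (age 10),
  that accrued mass starts in the active state (`GroundTruth.init_q0`);
  otherwise the simulated q0 would be warped away from logit-linearity at
  every later age.
* **Remission** rises linearly with adult age within reported bounds:
  women 1.8 → 5.5 per 100 person-years (floor 1.5), men 4.7 → 6.3.
* **Reactivation** is unreported in the literature; it is modelled as
  f(a) = 0.35/(1 + exp(0.25·(a − 36))) + 0.005 per year — frequent relapse
  shortly after youthful onset, remission increasingly permanent with age —
  calibrated once so the world reproduces the qualitative pattern that
  inactive-migraine prevalence is near zero at age 30 (0.8% men, 1.5%
  women) and rises steadily (5.4% / 14.9% at 60).
* **No secular trend**: the world is calendar-year invariant, and records
  across years are perturbed independently. Real burden-of-disease
  estimates are correlated across years and carry structural uncertainty
  the fabricated UIs do not represent, so passing tests bound estimation
  error under the model's assumptions — they do not certify accuracy on
  real extracts.

## Problem sizes used in checks

Fast checks use reduced but statistically adequate sizes: 200 bootstrap
resamples for band coverage (pooled over three independently emitted
tables and both sexes, since single-realization coverage of a 95%
pointwise band is itself a random variable), 1,000 lifetime resamples for
coefficient recovery (recovery to within 2% with CI half-width 0.02), and
the full N = 100,000 / h = 0.01 cohort everywhere, which costs seconds.
The reference analysis defaults (5,000 lifetime samples, 1,000 bootstrap
resamples) run in well under a minute end to end.

## Known limitations

* The bootstrap bands exclude model-form error; a polynomial degree far
  from the default can reintroduce derivative bias (low degree) or noise
  amplification (degree near the number of support ages with very noisy
  inputs).
* The lifetime stage extrapolates a logit-linear form outside the observed
  25–64 survey range; `age_support` (default 15–80) flags evaluations
  beyond it.
* Remission estimates at the reporting-range endpoints (17.5, 72.5) carry
  several-fold larger error than interior ages; worst-case tail errors on
  noisy inputs can be large where the true rate is small.
* No mortality, migration, or differential mortality; closed cohorts only.
* Real extracts are supported as an input pathway (same CSV layout) but no
  accuracy claims are made for them.
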