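# migraine-states

Age-specific prevalence of **never**, **active**, and **inactive**
migraine from an extended illness-death multistate model.

Most epidemiological sources — including the Global Burden of Disease
(GBD) results — report migraine as a two-state condition: active migraine
(symptoms within the last year) versus everything else. That lumps people
whose migraine has gone into remission together with people who never had
it. This package separates them. It is aimed at epidemiologists and
biostatisticians who want state-resolved age-prevalence curves and the
transition hazards behind them.

## The model

Three states with age-dependent hazards per person-year:

```
never (S0) --i0--> active (Ca) --r--> inactive (Ci)
                        ^---------f---------/
```

No differential mortality, so cohorts are closed. Three estimation stages
feed the model:

1. **Remission `r`** — smooth surfaces p(a, t), i(a, t) are fitted to a
   GBD-style prevalence/incidence extract (logit/log-linear in a
   polynomial age basis), and the illness-death balance equation is
   inverted analytically:
   `r = (i·(1−p) − ∂p/∂a − ∂p/∂t) / p`,
   with 95% bands from a parametric bootstrap of the input records.
2. **First incidence `i0` and never-prevalence `p0`** — lifetime
   prevalence q0 by age group and sex (survey table with CIs) is modelled
   by 5,000 resampled OLS regressions of logit(q0) on age, sex and their
   interaction; fits implying q0 decreasing in age are inadmissible;
   admissible coefficients are median-pooled. Then `p0 = 1 − q0` and
   `i0 = q0′/(1 − q0) = (b1 + b3·s)·q0`.
3. **Reactivation `f` and the cohort** — a deterministic Markov cohort
   (N = 100,000, start age 30 in 1990, 30 years, Euler step 0.01) advances
   the three compartments; `f` is re-derived each step from the balance
   identity `f = (i_gbd·(S0+Ci) − i0·S0)/Ci` that reconciles the extended
   model with the pooled GBD incidence denominator.

A synthetic-world generator (`migraine_states.synthetic`) produces
GBD-layout and lifetime tables from known ground-truth hazards, so every
stage has a parameter-recovery oracle without downloads. See
`docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Evaluate the first-incidence identity from two published anchors — the
never-migraine prevalence of women falls from 80.2% at age 25 to 67.5% at
age 65 (men: 94.4% to 90.6%):

```python
from migraine_states.lifetime import first_incidence_from_anchors

for sex, (p_lo, p_hi) in {"female": (0.802, 0.675),
                          "male": (0.944, 0.906)}.items():
    for age in (25.0, 65.0):
        i0 = first_incidence_from_anchors(age, 25.0, 1 - p_lo, 65.0, 1 - p_hi)
        print(f"{sex} i0({age:.0f}) = {100 * i0:.2f}% per year")
```

```
female i0(25) = 0.33% per year
female i0(65) = 0.54% per year
male i0(25) = 0.08% per year
male i0(65) = 0.13% per year
```

Interpolating logit(q0) linearly between the anchors, the incidence of
first-ever migraine among never-migraine women rises from 0.33% to 0.54%
per year between ages 25 and 65 (men: 0.08% to 0.13%).

For a full run on synthetic inputs:

```sh
python analysis/01_make_fixtures.py     # world + input tables -> results/fixtures/
python analysis/02_estimate_remission.py
python analysis/03_fit_lifetime.py
python analysis/04_simulate_cohorts.py  # cohort trajectories -> results/run/
```

The last step prints, e.g. (numbers from the run above):

```
age-60 state prevalences (estimate vs generating world):
  male p_i: 0.0539 vs 0.0542 (rel err 0.5%)
  female p_i: 0.1446 vs 0.1487 (rel err 2.7%)
```

i.e. the full pipeline recovers the generating world's inactive-migraine
prevalence at age 60 to within a few percent. The same pipeline runs on a
real GBD Results Tool extract by pointing `RunConfig.gbd_csv` /
`lifetime_csv` (or the `migraine-states run-all` CLI with a YAML config)
at the files; column layouts are documented in `migraine_states.io`.

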