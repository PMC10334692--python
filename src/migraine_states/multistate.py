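"""Three-state Markov cohort: never, active and inactive migraine.

The extended model splits "no active migraine" into never-migraine (S0) and
inactive migraine (Ci), with transitions

    S0 --i0--> Ca --r--> Ci --f--> Ca

where i0 is the first-incidence hazard, r the remission hazard and f the
reactivation hazard, all per person-year and age dependent.  There is no
mortality differential, so the cohort is closed and S0 + Ca + Ci is
conserved exactly.  The cohort is advanced by an explicit Euler recursion
with step h (default 0.01 years):

    S0' = S0 - h*i0*S0
    Ca' = Ca + h*i0*S0 + h*f*Ci - h*r*Ca
    Ci' = Ci + h*r*Ca - h*f*Ci

The compartment counts are deterministic expected values, not a stochastic
microsimulation; the nominal cohort size N only sets the reporting scale.

The reactivation hazard is not directly observable.  It is recovered from
the GBD incidence i_gbd — which applies to the pooled S0 + Ci denominator —
by requiring the extended model's inflow into Ca to match i_gbd applied to
that pool:

    f = (i_gbd * (S0 + Ci) - i0 * S0) / Ci .
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd


class StepSizeError(ValueError):
    """h times a hazard reached 1: the Euler step would overshoot."""


class UndefinedRateError(ValueError):
    """Reactivation balance undefined (empty no-active-migraine pool)."""


class Reactivation(NamedTuple):
    rate: float
    fallback: bool  # Ci numerically empty: returned f = i_gbd
    clamped: bool   # balance gave a negative hazard, clamped to 0


def reactivation_from_gbd(i_gbd: float, i0: float, S0: float, Ci: float,
                          eps: float = 1e-6) -> Reactivation:
    """Reactivation hazard making extended-model inflow match GBD incidence.

    When the inactive pool is numerically empty (Ci < eps * (S0 + Ci)) the
    balance is ill conditioned and the limit value f = i_gbd is returned
    with a fallback flag; a negative solution is clamped to 0 and flagged.
    """
    pool = S0 + Ci
    if pool <= 0.0:
        raise UndefinedRateError("S0 + Ci must be positive")
    if Ci < 0.0:
        raise ValueError("Ci must be nonnegative")
    if Ci < eps * pool:
        return Reactivation(rate=float(i_gbd), fallback=True, clamped=False)
    f = (i_gbd * pool - i0 * S0) / Ci
    if f < 0.0:
        return Reactivation(rate=0.0, fallback=False, clamped=True)
    return Reactivation(rate=float(f), fallback=False, clamped=False)


def _wrap_reactivation(f: Callable) -> Callable[[float, float, float], float]:
    """Accept f(age) or f(age, S0, Ci); normalize to the latter."""
    n = len(inspect.signature(f).parameters)
    if n >= 3:
        return f
    return lambda age, S0, Ci: f(age)


@dataclass
class TransitionRates:
    """The extended model's three age-dependent hazards per person-year.

    ``i0`` and ``r`` are callables of age.  ``f`` may be a callable of age
    or of (age, S0, Ci) — the latter lets the reactivation hazard be
    rederived from the balance identity at the current state, which is how
    the pipeline couples the simulator to the GBD incidence surface.
    """

    i0: Callable[[float], float]
    r: Callable[[float], float]
    f: Callable
    _f3: Callable = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._f3 = _wrap_reactivation(self.f)

    @classmethod
    def constant(cls, i0: float = 0.0, r: float = 0.0,
                 f: float = 0.0) -> "TransitionRates":
        return cls(i0=lambda a: i0, r=lambda a: r, f=lambda a: f)

    @classmethod
    def with_gbd_reactivation(cls, i0: Callable, r: Callable,
                              i_gbd: Callable,
                              eps: float = 1e-6) -> "TransitionRates":
        """Rates whose reactivation is solved from the balance identity."""
        def f(age, S0, Ci):
            return reactivation_from_gbd(i_gbd(age), i0(age), S0, Ci,
                                         eps=eps).rate
        return cls(i0=i0, r=r, f=f)


@dataclass
class CohortState:
    """Occupancy counts at one age; the cohort is closed (counts sum to N)."""

    age: float
    S0: float
    Ca: float
    Ci: float

    def __post_init__(self) -> None:
        if min(self.S0, self.Ca, self.Ci) < 0.0:
            raise ValueError("state counts must be nonnegative")

    @property
    def N(self) -> float:
        return self.S0 + self.Ca + self.Ci


@dataclass
class Trajectory:
    """Euler trajectory of a cohort: parallel arrays over ages."""

    ages: np.ndarray
    S0: np.ndarray
    Ca: np.ndarray
    Ci: np.ndarray
    step: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ages)

    def state(self, k: int) -> CohortState:
        return CohortState(age=float(self.ages[k]), S0=float(self.S0[k]),
                           Ca=float(self.Ca[k]), Ci=float(self.Ci[k]))

    def to_frame(self) -> pd.DataFrame:
        N = self.S0 + self.Ca + self.Ci
        df = pd.DataFrame({
            "age": self.ages, "S0": self.S0, "Ca": self.Ca, "Ci": self.Ci,
            "p0": self.S0 / N, "p_a": self.Ca / N, "p_i": self.Ci / N,
        })
        if "start_year" in self.meta:
            df.insert(1, "year", self.meta["start_year"]
                      + (df["age"] - df["age"].iloc[0]))
        return df


def markov_step(state: CohortState, rates: TransitionRates,
                h: float) -> CohortState:
    """One explicit Euler step of length h years."""
    if h <= 0.0:
        raise StepSizeError("h must be positive")
    a = state.age
    i0 = rates.i0(a)
    r = rates.r(a)
    f = rates._f3(a, state.S0, state.Ci)
    worst = h * max(i0, r, f)
    if worst >= 1.0:
        raise StepSizeError(
            f"h * hazard = {worst:.3g} >= 1 at age {a:.2f}; reduce h")
    onset = h * i0 * state.S0
    remit = h * r * state.Ca
    react = h * f * state.Ci
    return CohortState(
        age=a + h,
        S0=state.S0 - onset,
        Ca=state.Ca + onset + react - remit,
        Ci=state.Ci + remit - react,
    )


def run_cohort(init: CohortState, rates: TransitionRates, follow_up: float,
               h: float = 0.01, start_year: float | None = None,
               meta: dict | None = None) -> Trajectory:
    """Advance a cohort for ``follow_up`` years in steps of ``h``.

    ``follow_up / h`` must be a whole number of steps (within 1e-9).  Rates
    are evaluated at the current age each step; when the cohort tracks
    calendar time, age-indexed rate closures should advance year in
    lockstep (year = start_year + age - start_age).
    """
    n_steps_f = follow_up / h
    n_steps = round(n_steps_f)
    if abs(n_steps_f - n_steps) > 1e-9:
        raise ValueError("follow_up must be a whole number of steps")
    ages = np.empty(n_steps + 1)
    S0 = np.empty(n_steps + 1)
    Ca = np.empty(n_steps + 1)
    Ci = np.empty(n_steps + 1)
    state = init
    for k in range(n_steps + 1):
        ages[k], S0[k], Ca[k], Ci[k] = state.age, state.S0, state.Ca, state.Ci
        if k < n_steps:
            try:
                state = markov_step(state, rates, h)
            except StepSizeError as exc:
                raise StepSizeError(
                    f"simulation aborted at age {state.age:.2f}: {exc}"
                ) from exc
    full_meta = dict(meta or {})
    if start_year is not None:
        full_meta["start_year"] = float(start_year)
    return Trajectory(ages=ages, S0=S0, Ca=Ca, Ci=Ci, step=h, meta=full_meta)


def prevalence_curves(traj: Trajectory) -> pd.DataFrame:
    """Per-step state proportions (age, p0, p_a, p_i); rows sum to 1."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    N = traj.S0 + traj.Ca + traj.Ci
    return pd.DataFrame({
        "age": traj.ages,
        "p0": traj.S0 / N,
        "p_a": traj.Ca / N,
        "p_i": traj.Ci / N,
    })


def initialize_cohort(baseline, prev_surface, start_age: float,
                      start_year: float, N: float,
                      sex: str) -> tuple[CohortState, bool]:
    """Initial occupancy from the baseline functions and prevalence surface.

    Ca = N * p(start_age, start_year) from the fitted prevalence surface,
    S0 = N * p0(start_age) from the lifetime model, and Ci takes the
    remainder.  If the two sources are inconsistent enough to imply a
    negative Ci, it is floored at 0, S0 rescaled to N - Ca, and the flag in
    the returned tuple set (never silently).
    """
    p_a = float(prev_surface.predict(start_age, start_year))
    p_0 = float(baseline.p0(start_age, sex))
    Ca = N * p_a
    S0 = N * p_0
    Ci = N - S0 - Ca
    flagged = False
    if Ci < 0.0:
        flagged = True
        Ci = 0.0
        S0 = N - Ca
    return CohortState(age=float(start_age), S0=S0, Ca=Ca, Ci=Ci), flagged
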