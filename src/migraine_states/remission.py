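"""Remission-rate estimation by inverting the illness-death balance equation.

In a two-state illness-death model without differential mortality, the
prevalence p(a, t) of the active state obeys

    dp/da + dp/dt = i * (1 - p) - r * p

where i is the incidence applied to everyone not currently active and r the
remission hazard out of the active state.  Given smooth fitted surfaces for
p and i this solves directly for the remission rate:

    r(a, t) = (i * (1 - p) - dp/da - dp/dt) / p .

Uncertainty is propagated by a parametric bootstrap of the input table: each
record's value is redrawn from a normal centred at the point estimate with
sd = (upper - lower) / (2 * 1.96), the surfaces are refitted and the curve
recomputed; the point estimate is the across-resample median and the 95%
band the 2.5th/97.5th percentiles.

Rates are handled per person-year internally; the per-100-person-year
reporting convention is applied only when writing output tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GbdTable
from .surfaces import FittingError, RateSurface, SurfaceSpec, fit_surface


class UndefinedRateError(ValueError):
    """The balance equation is undefined (prevalence at or beyond 0 or 1)."""


class EstimationError(RuntimeError):
    """No resample produced a usable fit."""


def remission_from_pde(p, i, dp_da, dp_dt=0.0):
    """Remission hazard solving the illness-death balance equation.

    Accepts scalars or arrays.  Requires 0 < p < 1 and i >= 0; negative
    results are returned as-is (they diagnose model misfit and are clamped
    only where a proper hazard is required, in the cohort simulator).
    """
    p = np.asarray(p, float)
    i = np.asarray(i, float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise UndefinedRateError("prevalence must lie strictly in (0, 1)")
    if np.any(i < 0.0):
        raise UndefinedRateError("incidence must be nonnegative")
    r = (i * (1.0 - p) - np.asarray(dp_da, float) - np.asarray(dp_dt, float)) / p
    return r if r.ndim else float(r)


@dataclass
class RemissionCurve:
    """Remission hazard per person-year on an age grid, one year/sex/location."""

    sex: str
    location: str
    year: int
    ages: np.ndarray
    rate: np.ndarray  # per person-year; report as per 100 py at output only
    negative_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, float)
        self.rate = np.asarray(self.rate, float)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if self.negative_flag is None:
            self.negative_flag = self.rate < 0.0


@dataclass
class RemissionEstimate:
    """Resampled point estimate and 95% band for a remission curve.

    ``plug_in`` is the curve from the unperturbed fit, kept alongside the
    median-of-resamples point estimate for comparison.
    """

    point: RemissionCurve
    lower: RemissionCurve
    upper: RemissionCurve
    n_resamples: int
    seed: int
    plug_in: RemissionCurve | None = None
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Reporting table with rates scaled to per 100 person-years."""
        return pd.DataFrame({
            "sex": self.point.sex,
            "location": self.point.location,
            "year": self.point.year,
            "age": self.point.ages,
            "rate_per_100py": 100.0 * self.point.rate,
            "lower": 100.0 * self.lower.rate,
            "upper": 100.0 * self.upper.rate,
            "flag_negative": self.point.negative_flag,
        })


def estimate_remission(prev_surface: RateSurface, inc_surface: RateSurface,
                       ages, year: int,
                       include_dp_dt: bool = True) -> RemissionCurve:
    """Remission curve from fitted surfaces at one calendar year.

    Applies :func:`remission_from_pde` pointwise using the surfaces' values
    and analytic partial derivatives.  ``include_dp_dt=False`` drops the
    calendar-time term (sensitivity option).
    """
    if (prev_surface.sex, prev_surface.location) != (inc_surface.sex,
                                                     inc_surface.location):
        raise ValueError("prevalence and incidence surfaces must share "
                         "sex and location")
    ages = np.asarray(list(ages), float)
    yr = np.full_like(ages, float(year))
    p = np.asarray(prev_surface.predict(ages, yr), float)
    i = np.clip(np.asarray(inc_surface.predict(ages, yr), float), 0.0, None)
    dp_da = np.asarray(prev_surface.d_age(ages, yr), float)
    dp_dt = prev_surface.d_year(ages, yr) if include_dp_dt else 0.0
    r = remission_from_pde(p, i, dp_da, dp_dt)
    return RemissionCurve(sex=prev_surface.sex, location=prev_surface.location,
                          year=int(year), ages=ages, rate=np.asarray(r, float))


def _perturb_values(frame: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    sd = (frame["upper"].to_numpy(float)
          - frame["lower"].to_numpy(float)) / (2 * 1.96)
    draw = rng.normal(frame["value"].to_numpy(float), sd)
    prev = (frame["measure"] == "prevalence").to_numpy()
    draw[prev] = np.clip(draw[prev], 0.0, 1.0)
    draw[~prev] = np.clip(draw[~prev], 0.0, None)
    return draw


def resample_remission(table: GbdTable, spec: SurfaceSpec, ages,
                       year: int, n_resamples: int = 1000, seed: int = 0,
                       sex: str | None = None, location: str | None = None,
                       include_dp_dt: bool = True) -> RemissionEstimate:
    """Parametric-bootstrap remission estimate from a GBD-style table.

    ``table`` must contain both measures for the requested (sex, location);
    if the table holds a single sex/location those arguments may be omitted.
    Every record's value is redrawn from Normal(value, (upper-lower)/3.92),
    truncated to the measure's admissible range, both surfaces are refitted
    and the curve recomputed.  Point = pointwise median across resamples,
    band = 2.5th/97.5th percentiles.  Deterministic under a fixed seed.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    frame = table.frame
    if sex is None:
        (sex,) = frame["sex"].unique()
    if location is None:
        (location,) = frame["location"].unique()
    sub = frame[(frame["sex"] == sex) & (frame["location"] == location)]
    if sub.empty:
        raise ValueError(f"no records for sex={sex!r}, location={location!r}")

    def curve_from(values: np.ndarray) -> np.ndarray:
        work = sub.copy()
        work["value"] = values
        prev = fit_surface(work[work["measure"] == "prevalence"], spec)
        inc = fit_surface(work[work["measure"] == "incidence"], spec)
        return estimate_remission(prev, inc, ages, year,
                                  include_dp_dt=include_dp_dt).rate

    ages = np.asarray(list(ages), float)
    plug_in_rate = curve_from(sub["value"].to_numpy(float))

    rng = np.random.default_rng(seed)
    draws, failures = [], []
    for k in range(n_resamples):
        values = _perturb_values(sub, rng)
        try:
            draws.append(curve_from(values))
        except (FittingError, UndefinedRateError) as exc:
            failures.append((k, repr(exc)))
    if not draws:
        raise EstimationError(
            f"all {n_resamples} resamples failed; first failures: "
            f"{failures[:5]}")
    stack = np.vstack(draws)
    lo, mid, hi = np.percentile(stack, [2.5, 50.0, 97.5], axis=0)

    def _curve(rate):
        return RemissionCurve(sex=sex, location=location, year=int(year),
                              ages=ages, rate=rate)

    return RemissionEstimate(
        point=_curve(mid), lower=_curve(lo), upper=_curve(hi),
        n_resamples=n_resamples, seed=seed,
        plug_in=_curve(plug_in_rate), n_failed=len(failures),
    )
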