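"""Smooth age x calendar-year models for prevalence and incidence.

The remission-rate inversion needs the active-migraine prevalence p(a, t)
and incidence i_GBD(a, t) as differentiable functions of age and year, per
sex and location.  We fit a linear model on a transformed scale — logit for
prevalence, log for incidence — with a polynomial in age (high order by
default; see :class:`SurfaceSpec`), a polynomial in year (default linear)
and an age x year interaction.  The
transformed-linear form keeps predictions inside the admissible range and
makes both partial derivatives available analytically, which matters because
the downstream differential-equation inversion divides by prevalence: noise
amplification from data-level finite differencing would dominate the
remission estimate.

Age and year are centred and scaled before building the polynomial basis so
the normal equations stay well conditioned up to moderate degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

_P_EPS = 1e-9      # clip for logit transform of observed prevalence
_RATE_EPS = 1e-12  # clip for log transform of observed incidence


class FittingError(ValueError):
    """The surface could not be fitted (too few support points, NaNs, ...)."""


@dataclass(frozen=True)
class SurfaceSpec:
    """Configuration of the transformed-scale linear surface model.

    ``age_degree`` polynomial degree in age; ``year_degree`` in calendar
    year; ``interaction`` adds an age x year product term.  ``age_range``
    restricts the training records to a window of age midpoints (GBD age
    profiles are already smoothed model output with at most 18 support
    ages, so the default uses a high-order, near-interpolating age
    polynomial over the adult window that feeds the remission inversion;
    the open-ended oldest groups are left out because their midpoints are
    poorly defined and they dominate global-polynomial misfit).  With
    ``weight_by_ui`` each record is weighted by the inverse variance
    implied by its 95% uncertainty interval, sd = (upper - lower)/(2*1.96).
    """

    age_degree: int = 13
    year_degree: int = 1
    interaction: bool = True
    weight_by_ui: bool = False
    age_range: tuple[float, float] | None = (12.5, 82.5)


def _design(a0: np.ndarray, t0: np.ndarray, spec: SurfaceSpec) -> np.ndarray:
    cols = [np.ones_like(a0)]
    cols += [a0 ** k for k in range(1, spec.age_degree + 1)]
    cols += [t0 ** k for k in range(1, spec.year_degree + 1)]
    if spec.interaction:
        cols.append(a0 * t0)
    return np.column_stack(cols)


def _design_d_age(a0, t0, spec: SurfaceSpec) -> np.ndarray:
    cols = [np.zeros_like(a0)]
    cols += [k * a0 ** (k - 1) for k in range(1, spec.age_degree + 1)]
    cols += [np.zeros_like(a0) for _ in range(1, spec.year_degree + 1)]
    if spec.interaction:
        cols.append(t0)
    return np.column_stack(cols)


def _design_d_year(a0, t0, spec: SurfaceSpec) -> np.ndarray:
    cols = [np.zeros_like(a0)]
    cols += [np.zeros_like(a0) for _ in range(1, spec.age_degree + 1)]
    cols += [k * t0 ** (k - 1) for k in range(1, spec.year_degree + 1)]
    if spec.interaction:
        cols.append(a0)
    return np.column_stack(cols)


@dataclass
class RateSurface:
    """Fitted smooth surface over (age, year) with analytic partials.

    ``kind`` is "prevalence" (logit link, predictions in (0, 1)) or
    "incidence" (log link, predictions > 0).  ``predict``, ``d_age`` and
    ``d_year`` accept scalars or arrays of age in years and calendar year.
    """

    kind: str
    sex: str
    location: str
    spec: SurfaceSpec
    coef: np.ndarray
    age_center: float
    age_scale: float
    year_center: float
    year_scale: float
    domain: tuple[tuple[float, float], tuple[float, float]]
    resid_max_abs: float = float("nan")
    meta: dict = field(default_factory=dict)

    # -- linear predictor and its exact derivatives -----------------------
    def _eta(self, age, year):
        scalar = np.ndim(age) == 0 and np.ndim(year) == 0
        a0 = (np.atleast_1d(np.asarray(age, float))
              - self.age_center) / self.age_scale
        t0 = (np.atleast_1d(np.asarray(year, float))
              - self.year_center) / self.year_scale
        a0, t0 = np.broadcast_arrays(a0, t0)
        return _design(a0, t0, self.spec) @ self.coef, a0, t0, scalar

    def predict(self, age, year):
        eta, _, _, scalar = self._eta(age, year)
        if self.kind == "prevalence":
            out = np.clip(expit(eta), _P_EPS, 1.0 - _P_EPS)
        else:
            out = np.exp(eta)
        return float(out[0]) if scalar else out

    def _chain(self, age, year, which: str):
        _, a0, t0, scalar = self._eta(age, year)
        if which == "age":
            deta = _design_d_age(a0, t0, self.spec) @ self.coef / self.age_scale
        else:
            deta = _design_d_year(a0, t0, self.spec) @ self.coef / self.year_scale
        mu = np.atleast_1d(np.asarray(self.predict(age, year), float))
        if self.kind == "prevalence":
            out = mu * (1.0 - mu) * deta
        else:
            out = mu * deta
        return float(out[0]) if scalar else out

    def d_age(self, age, year):
        """Partial derivative of the prediction with respect to age."""
        return self._chain(age, year, "age")

    def d_year(self, age, year):
        """Partial derivative of the prediction with respect to year."""
        return self._chain(age, year, "year")

    def in_domain(self, age, year):
        (alo, ahi), (tlo, thi) = self.domain
        age = np.asarray(age, float)
        year = np.asarray(year, float)
        return (age >= alo) & (age <= ahi) & (year >= tlo) & (year <= thi)


def fit_surface(table_slice: pd.DataFrame, spec: SurfaceSpec | None = None,
                kind: str | None = None) -> RateSurface:
    """Fit a :class:`RateSurface` to one (measure, sex, location) slice.

    ``table_slice`` needs columns age_mid, year, value (and lower/upper when
    inverse-UI weighting is on); ``kind`` defaults to the slice's measure
    column.  Requires at least ``age_degree + 1`` distinct age midpoints and
    ``year_degree + 1`` distinct years.
    """
    spec = spec or SurfaceSpec()
    df = table_slice
    if spec.age_range is not None:
        lo, hi = spec.age_range
        df = df[(df["age_mid"] >= lo) & (df["age_mid"] <= hi)]
        if df.empty:
            raise FittingError(
                f"no records with age midpoints in [{lo}, {hi}]")
    if kind is None:
        kinds = df["measure"].unique()
        if len(kinds) != 1:
            raise FittingError(f"slice mixes measures: {list(kinds)}")
        kind = str(kinds[0])
    if kind not in ("prevalence", "incidence"):
        raise FittingError(f"unknown surface kind: {kind!r}")

    ages = df["age_mid"].to_numpy(float)
    years = df["year"].to_numpy(float)
    values = df["value"].to_numpy(float)
    n_ages = len(np.unique(ages))
    n_years = len(np.unique(years))
    if n_ages < spec.age_degree + 1 or n_ages < 4:
        raise FittingError(
            f"need >= {max(4, spec.age_degree + 1)} distinct age midpoints, "
            f"got {n_ages}")
    if n_years < spec.year_degree + 1:
        raise FittingError(
            f"need >= {spec.year_degree + 1} distinct years, got {n_years}")

    if kind == "prevalence":
        y = logit(np.clip(values, _P_EPS, 1.0 - _P_EPS))
    else:
        y = np.log(np.clip(values, _RATE_EPS, None))

    a_c, a_s = ages.mean(), max(ages.std(), 1e-9)
    t_c = years.mean()
    t_s = max(years.std(), 1.0)  # single-year slices: degenerate scale guard
    X = _design((ages - a_c) / a_s, (years - t_c) / t_s, spec)

    if spec.weight_by_ui:
        sd = (df["upper"].to_numpy(float) - df["lower"].to_numpy(float)) / (2 * 1.96)
        w = 1.0 / np.clip(sd, 1e-6, None) ** 2
        res = sm.WLS(y, X, weights=w).fit()
    else:
        res = sm.OLS(y, X).fit()
    coef = np.asarray(res.params, float)
    if not np.all(np.isfinite(coef)):
        raise FittingError(f"non-finite coefficients: {coef}")

    surface = RateSurface(
        kind=kind,
        sex=str(df["sex"].iloc[0]) if "sex" in df else "",
        location=str(df["location"].iloc[0]) if "location" in df else "",
        spec=spec,
        coef=coef,
        age_center=a_c, age_scale=a_s,
        year_center=t_c, year_scale=t_s,
        domain=((float(ages.min()), float(ages.max())),
                (float(years.min()), float(years.max()))),
        meta={"n_obs": len(df)},
    )
    fitted = surface.predict(ages, years)
    surface.resid_max_abs = float(np.max(np.abs(fitted - values)))
    return surface


def surface_grid(surface: RateSurface, ages: Sequence[float],
                 years: Sequence[float]) -> pd.DataFrame:
    """Evaluate a surface on the rectangular grid ages x years.

    Returns (age, year, value, d_age, d_year, extrapolated); rows outside
    the fitted domain are flagged extrapolated rather than refused.
    """
    ages = np.asarray(list(ages), float)
    years = np.asarray(list(years), float)
    if ages.size == 0 or years.size == 0:
        raise ValueError("empty evaluation grid")
    aa, tt = np.meshgrid(ages, years, indexing="ij")
    aa, tt = aa.ravel(), tt.ravel()
    return pd.DataFrame({
        "age": aa,
        "year": tt,
        "value": surface.predict(aa, tt),
        "d_age": surface.d_age(aa, tt),
        "d_year": surface.d_year(aa, tt),
        "extrapolated": ~surface.in_domain(aa, tt),
    })
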