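"""Never-migraine prevalence and first incidence from lifetime prevalence.

Lifetime prevalence q0(a) — the proportion who have ever had migraine by
age a — pins down the two quantities the GBD extract cannot provide: the
never-migraine prevalence p0(a) = 1 - q0(a) and the incidence of first-ever
migraine among the never-migraine pool,

    i0(a) = q0'(a) / (1 - q0(a)) .

The relation holds because, absent differential mortality and re-entry into
the never state, the never pool is only depleted by first onset.

The input is a small table of lifetime prevalences by 10-year age group and
sex with 95% confidence limits.  To propagate their uncertainty we draw
n_samples complete tables (each value from a normal centred at the estimate
with sd = (upper - lower) / (2 * 1.96); draws outside (0, 1) are treated as
missing), fit a linear regression of logit(q0) on age, sex and their
interaction to each, discard coefficient sets implying lifetime prevalence
decreasing in age for either sex, and pool the surviving sets by
coordinate-wise median.  With the logit-linear form the first-incidence
identity reduces to i0(a) = (b1 + b3 * s) * q0(a).

Sex coding: s = 0 for male, 1 for female.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .io import LifetimePoint

#: Age support over which baseline functions are considered reliable.
DEFAULT_AGE_SUPPORT = (15.0, 80.0)


class EstimationError(RuntimeError):
    """No admissible coefficient set survived the filter."""


def sex_indicator(sex) -> float:
    """Map a sex label (or 0/1) to the regression indicator."""
    if sex in (0, 1):
        return float(sex)
    if sex == "male":
        return 0.0
    if sex == "female":
        return 1.0
    raise ValueError(f"unknown sex: {sex!r}")


@dataclass(frozen=True)
class CoefSet:
    """Logit-linear lifetime-prevalence coefficients.

    logit(q0) = b0 + b1*age + b2*s + b3*age*s with s the female indicator.
    Admissible iff lifetime prevalence is increasing in age for both sexes,
    i.e. b1 > 0 and b1 + b3 > 0.
    """

    b0: float
    b1: float
    b2: float
    b3: float

    @property
    def admissible(self) -> bool:
        return self.b1 > 0.0 and self.b1 + self.b3 > 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2, self.b3], float)

    def q0(self, age, sex):
        s = sex_indicator(sex)
        age = np.asarray(age, float)
        out = expit(self.b0 + self.b1 * age + s * (self.b2 + self.b3 * age))
        return out if out.ndim else float(out)

    def slope(self, sex) -> float:
        """Age slope of logit(q0) for the given sex."""
        return self.b1 + sex_indicator(sex) * self.b3


def sample_lifetime_sets(points: Sequence[LifetimePoint], n_samples: int,
                         seed: int) -> np.ndarray:
    """Draw resampled lifetime-prevalence tables.

    Returns an (n_samples, n_points) array aligned with ``points``; each
    entry is a draw from Normal(q0, (upper - lower)/(2*1.96)).  Draws <= 0
    or >= 1 are NaN (missing): negatives are not prevalences, and values at
    or above 1 have no logit.  Deterministic under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for p in points:
        if not p.upper > p.lower:
            raise ValueError(
                f"degenerate CI for {p.sex}/{p.age_group}: "
                f"upper must exceed lower")
    means = np.array([p.q0 for p in points], float)
    sds = np.array([(p.upper - p.lower) / (2 * 1.96) for p in points], float)
    rng = np.random.default_rng(seed)
    draws = rng.normal(means, sds, size=(n_samples, len(points)))
    draws[(draws <= 0.0) | (draws >= 1.0)] = np.nan
    return draws


def fit_logit_model(points: Sequence[LifetimePoint],
                    values: Sequence[float] | None = None) -> CoefSet | None:
    """OLS of logit(lifetime prevalence) on age, sex and age x sex.

    ``values`` overrides the points' q0 (one resampled table); NaNs are
    dropped.  Returns None when the design is rank deficient (e.g. one sex
    entirely missing), so callers can count failed resamples.
    """
    q = np.array([p.q0 for p in points], float) if values is None \
        else np.asarray(values, float)
    age = np.array([p.age_mid for p in points], float)
    s = np.array([sex_indicator(p.sex) for p in points], float)
    ok = np.isfinite(q)
    if ok.sum() < 4:
        return None
    q, age, s = q[ok], age[ok], s[ok]
    X = np.column_stack([np.ones_like(age), age, s, age * s])
    if np.linalg.matrix_rank(X) < 4:
        return None
    beta, *_ = np.linalg.lstsq(X, logit(q), rcond=None)
    if not np.all(np.isfinite(beta)):
        return None
    return CoefSet(*map(float, beta))


@dataclass
class BaselineFunctions:
    """Pooled lifetime model and the derived baseline functions.

    ``coefs`` is the coordinate-wise median of the admissible sets;
    ``n_valid`` counts admissible sets, ``n_total`` all attempted fits.
    """

    coefs: CoefSet
    n_valid: int
    n_total: int
    age_support: tuple[float, float] = DEFAULT_AGE_SUPPORT

    def q0(self, age, sex):
        """Lifetime prevalence of migraine at ``age`` for ``sex``."""
        return self.coefs.q0(age, sex)

    def p0(self, age, sex):
        """Never-migraine prevalence, 1 - q0."""
        q = np.asarray(self.coefs.q0(age, sex), float)
        out = 1.0 - q
        return out if out.ndim else float(out)

    def i0(self, age, sex):
        """First-incidence hazard per person-year among the never pool."""
        s = self.coefs.slope(sex)
        q = np.asarray(self.coefs.q0(age, sex), float)
        out = s * q
        return out if out.ndim else float(out)


def filter_and_pool(sets: Sequence[CoefSet | None],
                    age_support=DEFAULT_AGE_SUPPORT) -> BaselineFunctions:
    """Drop inadmissible sets and pool the rest by coordinate-wise median."""
    attempted = [c for c in sets if c is not None]
    valid = [c for c in attempted if c.admissible]
    if not valid:
        raise EstimationError("no admissible coefficient sets")
    stack = np.vstack([c.as_array() for c in valid])
    pooled = CoefSet(*map(float, np.median(stack, axis=0)))
    return BaselineFunctions(coefs=pooled, n_valid=len(valid),
                             n_total=len(sets), age_support=tuple(age_support))


def i0_eval(baseline: BaselineFunctions, age, sex):
    """Evaluate first incidence, warning outside the configured age support."""
    lo, hi = baseline.age_support
    if np.any((np.asarray(age, float) < lo) | (np.asarray(age, float) > hi)):
        warnings.warn(
            f"age outside baseline support [{lo}, {hi}]; extrapolating",
            stacklevel=2)
    return baseline.i0(age, sex)


def fit_resampled_baseline(points: Sequence[LifetimePoint], n_samples: int,
                           seed: int,
                           age_support=DEFAULT_AGE_SUPPORT) -> BaselineFunctions:
    """Full lifetime stage: sample, fit per table, filter, pool."""
    draws = sample_lifetime_sets(points, n_samples, seed)
    sets = [fit_logit_model(points, row) for row in draws]
    return filter_and_pool(sets, age_support=age_support)


# -- two-point anchored model (worked example) ---------------------------

def anchored_coefs(age_lo: float, q_lo: float, age_hi: float,
                   q_hi: float) -> tuple[float, float]:
    """Intercept and slope of logit(q0) through two (age, q0) anchors."""
    slope = (logit(q_hi) - logit(q_lo)) / (age_hi - age_lo)
    intercept = logit(q_lo) - slope * age_lo
    return float(intercept), float(slope)


def first_incidence_from_anchors(age, age_lo: float, q_lo: float,
                                 age_hi: float, q_hi: float):
    """i0(age) from a logit-linear q0 interpolated through two anchors.

    Used for desk checks: given lifetime prevalence at two ages, the
    logit-linear interpolation yields i0(a) = slope * q0(a) directly.
    """
    b0, b1 = anchored_coefs(age_lo, q_lo, age_hi, q_hi)
    q = expit(b0 + b1 * np.asarray(age, float))
    out = b1 * q
    return out if out.ndim else float(out)
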