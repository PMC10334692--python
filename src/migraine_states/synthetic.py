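"""Synthetic ground-truth worlds and the GBD-like tables they imply.

Every estimation stage in this package is validated against worlds whose
transition hazards are known exactly.  A :class:`GroundTruth` fixes the
three hazards of the extended model — first incidence i0(a, sex), remission
r(a, sex) and reactivation f(a, sex) — and :func:`solve_truth` integrates
the closed three-state dynamics on a fine age grid, also deriving the
pooled-denominator incidence the GBD reports,

    i_gbd(a) = (i0 * S0 + f * Ci) / (S0 + Ci),

and the lifetime prevalence q0 = 1 - p0.  From the solved world,
:func:`emit_gbd_tables` aggregates to 5-year age groups over a span of
calendar years and fabricates uncertainty intervals with controlled
relative width, and :func:`emit_lifetime_table` produces the four 10-year
lifetime-prevalence groups per sex.  At zero noise the emitted tables equal
the truth at the group midpoints exactly, giving noiseless
parameter-recovery oracles for the surface fits, the differential-equation
inversion and the full pipeline.

The default world mirrors the broad epidemiology of migraine: first
incidence a few per mille per year, several-fold higher in women; remission
a few per 100 person-years, rising with adult age; a bell-shaped active
prevalence; no secular trend.  It does not emulate GBD's own estimation
machinery or real calendar-time trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import (AGE_LABELS, GbdTable, LifetimePoint, LIFETIME_GROUPS,
                 age_midpoint, write_lifetime_table)
from .lifetime import CoefSet

HAZARD_BOUND = 0.5  # per person-year; sanity cap for ground-truth hazards

Hazard = Callable[[np.ndarray, str], np.ndarray]


@dataclass
class GroundTruth:
    """A fully specified three-state world.

    Hazards are callables of (age array, sex label) returning per-person-
    year rates; ``noise`` is the relative half-width of the fabricated 95%
    uncertainty intervals on emitted GBD-like records.
    """

    i0: Hazard
    r: Hazard
    f: Hazard
    sexes: tuple[str, ...] = ("male", "female")
    age_span: tuple[float, float] = (10.0, 98.0)
    year_span: tuple[int, int] = (1990, 2019)
    noise: float = 0.05
    seed: int = 0
    #: lifetime prevalence already accrued at the start of the age span,
    #: per sex; that mass begins in the active state.  None = onset starts
    #: at the span's lower end (everyone in the never state).
    init_q0: Callable[[str], float] | None = None

    def check_bounds(self, ages: np.ndarray) -> None:
        for sex in self.sexes:
            for name, fn in (("i0", self.i0), ("r", self.r), ("f", self.f)):
                vals = np.asarray(fn(ages, sex), float)
                if np.any(vals < 0.0) or np.any(vals > HAZARD_BOUND):
                    raise ValueError(
                        f"{name} for {sex} outside [0, {HAZARD_BOUND}]")


def _logit(x: float) -> float:
    return float(np.log(x / (1.0 - x)))


def default_lifetime_coefs() -> CoefSet:
    """Logit-linear lifetime-prevalence coefficients of the default world.

    Anchored at lifetime prevalences 5.6% -> 9.4% (men) and 19.8% -> 32.5%
    (women) between ages 25 and 65, the magnitudes reported for Northern
    European adults; the implied first incidence runs 0.08 -> 0.13% per
    year in men and 0.33 -> 0.54% in women over that span.
    """
    b1 = (_logit(0.094) - _logit(0.056)) / 40.0
    slope_f = (_logit(0.325) - _logit(0.198)) / 40.0
    b0 = _logit(0.056) - 25.0 * b1
    b0_f = _logit(0.198) - 25.0 * slope_f
    return CoefSet(b0=b0, b1=b1, b2=b0_f - b0, b3=slope_f - b1)


def default_ground_truth(noise: float = 0.05, seed: int = 0) -> GroundTruth:
    """The package's reference world (see module docstring).

    First incidence is the hazard implied by a logit-linear lifetime-
    prevalence surface (:func:`default_lifetime_coefs`), i0 = slope * q0,
    so the world satisfies the structural assumption the lifetime
    regression stage relies on; remission echoes the reported adult
    pattern (a few per 100 person-years, rising with age, higher in men at
    younger ages) and reactivation is a small constant hazard.
    """
    coefs = default_lifetime_coefs()

    def i0(age, sex):
        age = np.asarray(age, float)
        return coefs.slope(sex) * np.asarray(coefs.q0(age, sex), float)

    def r(age, sex):
        age = np.asarray(age, float)
        if sex == "female":
            return np.clip(0.018 + 0.000664 * (age - 17.5), 0.015, 0.055)
        return np.clip(0.047 + 0.0004 * (age - 17.5), 0.04, 0.063)

    def f(age, sex):
        # relapse is common soon after youthful onset; remission becomes
        # increasingly permanent with age (keeps inactive prevalence near
        # zero at 30 while letting it rise steadily afterwards)
        age = np.asarray(age, float)
        return 0.35 / (1.0 + np.exp(0.25 * (age - 36.0))) + 0.005

    return GroundTruth(i0=i0, r=r, f=f, noise=noise, seed=seed,
                       init_q0=lambda sex: float(coefs.q0(10.0, sex)))


def constant_ground_truth(i: float = 0.02, r: float = 0.05,
                          f: float | None = None, noise: float = 0.0,
                          seed: int = 0) -> GroundTruth:
    """World with constant hazards; by default f = i0 = i so i_gbd == i.

    With uniform incidence across the pooled never/inactive denominator the
    pooled i_gbd equals i exactly and the active prevalence solves the
    two-state illness-death equation dp/da = i*(1-p) - r*p — the closed-form
    oracle for the remission inversion.
    """
    f_val = i if f is None else f
    return GroundTruth(
        i0=lambda a, s: np.full_like(np.asarray(a, float), i),
        r=lambda a, s: np.full_like(np.asarray(a, float), r),
        f=lambda a, s: np.full_like(np.asarray(a, float), f_val),
        noise=noise, seed=seed,
    )


def solve_truth(truth: GroundTruth, h_fine: float = 0.0025) -> pd.DataFrame:
    """Integrate the world's dynamics; columns (age, sex, p0, p_a, p_i, i_gbd, q0).

    Starts at the lower end of the age span with everyone in the never
    state — unless the world declares lifetime prevalence already accrued
    there (``init_q0``), in which case that mass starts active; this keeps
    worlds whose lifetime-prevalence curve is logit-linear exactly
    consistent with the curve at every age.  Advances by explicit Euler
    with step ``h_fine`` (must be <= 0.005 so discretization error is
    negligible relative to the noise scales used downstream).  Proportions
    are conserved exactly.
    """
    if h_fine > 0.005:
        raise ValueError("h_fine must be <= 0.005")
    lo, hi = truth.age_span
    n = int(round((hi - lo) / h_fine))
    ages = lo + h_fine * np.arange(n + 1)
    truth.check_bounds(ages)
    frames = []
    for sex in truth.sexes:
        i0 = np.asarray(truth.i0(ages, sex), float)
        r = np.asarray(truth.r(ages, sex), float)
        f = np.asarray(truth.f(ages, sex), float)
        S0 = np.empty(n + 1)
        Ca = np.empty(n + 1)
        Ci = np.empty(n + 1)
        q_init = float(truth.init_q0(sex)) if truth.init_q0 else 0.0
        S0[0], Ca[0], Ci[0] = 1.0 - q_init, q_init, 0.0
        for k in range(n):
            onset = h_fine * i0[k] * S0[k]
            remit = h_fine * r[k] * Ca[k]
            react = h_fine * f[k] * Ci[k]
            S0[k + 1] = S0[k] - onset
            Ca[k + 1] = Ca[k] + onset + react - remit
            Ci[k + 1] = Ci[k] + remit - react
        pool = S0 + Ci
        i_gbd = np.where(pool > 0.0, (i0 * S0 + f * Ci) / np.where(pool > 0, pool, 1.0), 0.0)
        frames.append(pd.DataFrame({
            "age": ages, "sex": sex, "p0": S0, "p_a": Ca, "p_i": Ci,
            "i_gbd": i_gbd, "q0": 1.0 - S0,
        }))
    return pd.concat(frames, ignore_index=True)


def truth_at(solution: pd.DataFrame, column: str, ages,
             sex: str) -> np.ndarray:
    """Interpolate a solved-truth column at arbitrary ages for one sex."""
    sub = solution[solution["sex"] == sex]
    return np.interp(np.asarray(ages, float), sub["age"].to_numpy(),
                     sub[column].to_numpy())


def _emittable_labels(solution: pd.DataFrame) -> list[str]:
    lo = solution["age"].min()
    hi = solution["age"].max()
    return [lab for lab in AGE_LABELS if lo <= age_midpoint(lab) <= hi]


def emit_gbd_tables(truth_solution: pd.DataFrame, noise: float, seed: int,
                    location: str = "Germany",
                    years: Sequence[int] | None = None) -> GbdTable:
    """GBD-layout table from a solved world with fabricated uncertainty.

    One record per (measure, sex, year, age group); the group value is the
    truth at the group midpoint.  With ``noise`` > 0 each value is perturbed
    multiplicatively by Normal(1, noise / 1.96) and the uncertainty limits
    are written as value * (1 -/+ noise); prevalence is truncated to [0, 1]
    and incidence to >= 0 after perturbation (truncations counted in meta).
    Deterministic (byte-identical CSV) under a fixed seed.
    """
    if not 0.0 <= noise <= 0.5:
        raise ValueError("noise must lie in [0, 0.5]")
    if years is None:
        years = range(1990, 2020)
    labels = _emittable_labels(truth_solution)
    mids = np.array([age_midpoint(lab) for lab in labels])
    sexes = list(dict.fromkeys(truth_solution["sex"]))
    rng = np.random.default_rng(seed)
    rows = []
    n_truncated = 0
    for sex in sexes:
        for measure, column in (("prevalence", "p_a"), ("incidence", "i_gbd")):
            base = truth_at(truth_solution, column, mids, sex)
            for year in years:
                vals = base.copy()
                if noise > 0.0:
                    vals = vals * rng.normal(1.0, noise / 1.96, size=len(vals))
                if measure == "prevalence":
                    clipped = np.clip(vals, 0.0, 1.0)
                else:
                    clipped = np.clip(vals, 0.0, None)
                n_truncated += int(np.sum(clipped != vals))
                vals = clipped
                for lab, mid, v in zip(labels, mids, vals):
                    rows.append((measure, location, sex, int(year), lab,
                                 mid, v, v * (1.0 - noise),
                                 min(v * (1.0 + noise), 1.0)
                                 if measure == "prevalence"
                                 else v * (1.0 + noise)))
    frame = pd.DataFrame(rows, columns=[
        "measure", "location", "sex", "year", "age_label", "age_mid",
        "value", "lower", "upper"])
    return GbdTable(frame, meta={
        "source": "synthetic", "noise": noise, "seed": seed,
        "n_truncated": n_truncated,
    })


def emit_lifetime_table(truth_solution: pd.DataFrame, ci_halfwidth: float,
                        seed: int | None = None,
                        jitter: float = 0.0) -> list[LifetimePoint]:
    """Lifetime-prevalence points (four 10-year groups per sex) from a world.

    lower/upper = q0 -/+ ``ci_halfwidth``, floored at 0 and capped at 1.
    With ``jitter`` > 0 the central estimate itself is perturbed by
    Normal(0, jitter) under ``seed`` (kept inside the interval).
    """
    if not 0.0 < ci_halfwidth < 0.5:
        raise ValueError("ci_halfwidth must lie in (0, 0.5)")
    rng = np.random.default_rng(seed) if jitter > 0.0 else None
    points = []
    for sex in dict.fromkeys(truth_solution["sex"]):
        for group, mid in LIFETIME_GROUPS.items():
            q = float(truth_at(truth_solution, "q0", mid, sex))
            if rng is not None:
                q = float(np.clip(q + rng.normal(0.0, jitter),
                                  1e-6, 1.0 - 1e-6))
            points.append(LifetimePoint(
                sex=sex, age_group=group, age_mid=mid, q0=q,
                lower=max(q - ci_halfwidth, 0.0),
                upper=min(q + ci_halfwidth, 1.0),
            ))
    return points


def lifetime_points_from_coefs(coefs: CoefSet, ci_halfwidth: float,
                               sexes=("male", "female")) -> list[LifetimePoint]:
    """Lifetime points lying exactly on a logit-linear surface.

    The direct oracle for the lifetime regression stage: with these points
    the saturated fit recovers ``coefs`` to rounding error.
    """
    points = []
    for sex in sexes:
        for group, mid in LIFETIME_GROUPS.items():
            q = float(coefs.q0(mid, sex))
            points.append(LifetimePoint(
                sex=sex, age_group=group, age_mid=mid, q0=q,
                lower=max(q - ci_halfwidth, 0.0),
                upper=min(q + ci_halfwidth, 1.0),
            ))
    return points


def write_fixtures(outdir: str | Path, truth: GroundTruth | None = None,
                   ci_halfwidth: float = 0.03, h_fine: float = 0.0025,
                   location: str = "Germany") -> dict[str, Path]:
    """Write a complete fixture set (GBD CSV, lifetime CSV, truth CSV)."""
    truth = truth or default_ground_truth()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    solution = solve_truth(truth, h_fine=h_fine)
    table = emit_gbd_tables(solution, truth.noise, truth.seed,
                            location=location,
                            years=range(truth.year_span[0],
                                        truth.year_span[1] + 1))
    paths = {
        "gbd": outdir / "gbd_extract.csv",
        "lifetime": outdir / "lifetime_prevalence.csv",
        "truth": outdir / "ground_truth.csv",
    }
    table.to_csv(paths["gbd"])
    write_lifetime_table(
        emit_lifetime_table(solution, ci_halfwidth), paths["lifetime"])
    solution.iloc[::100].to_csv(paths["truth"], index=False)
    return paths
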