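"""Remission inversion: closed forms, ODE oracle, bootstrap behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from migraine_states.io import GbdTable
from migraine_states.remission import (RemissionCurve, UndefinedRateError,
                                       estimate_remission, remission_from_pde,
                                       resample_remission)
from migraine_states.surfaces import SurfaceSpec, fit_surface
from migraine_states.synthetic import (constant_ground_truth,
                                       emit_gbd_tables, solve_truth)

SPEC = SurfaceSpec()


def _surfaces_for(table, sex="female"):
    f = table.frame
    sub = f[f["sex"] == sex]
    prev = fit_surface(sub[sub["measure"] == "prevalence"], SPEC)
    inc = fit_surface(sub[sub["measure"] == "incidence"], SPEC)
    return prev, inc


def test_no_inflow_steady_state_is_zero():
    assert remission_from_pde(p=0.5, i=0.0, dp_da=0.0) == 0.0


def test_steady_state_balance():
    assert remission_from_pde(p=0.2, i=0.01, dp_da=0.0) == pytest.approx(0.04)


@given(p=st.floats(0.01, 0.99), i=st.floats(0.0, 0.2))
@settings(derandomize=True, max_examples=50)
def test_steady_state_closed_form(p, i):
    """With no age/time gradient the inversion is exactly i(1-p)/p."""
    assert remission_from_pde(p, i, 0.0, 0.0) == pytest.approx(
        i * (1 - p) / p, rel=1e-12)


@pytest.mark.parametrize("p", [0.0, -0.1, 1.0, 1.2])
def test_degenerate_prevalence_rejected(p):
    with pytest.raises(UndefinedRateError):
        remission_from_pde(p, 0.01, 0.0)


def test_forward_ode_oracle_recovers_rate_exactly():
    """dp/da = i(1-p) - r p integrated forward, then inverted at age 40."""
    i_true, r_true = 0.02, 0.05

    def rhs(a, p):
        return i_true * (1 - p) - r_true * p

    sol = solve_ivp(rhs, (0.0, 40.0), [0.0], rtol=1e-12, atol=1e-14,
                    dense_output=True)
    p40 = float(sol.sol(40.0)[0])
    dp_da = rhs(40.0, p40)
    r_hat = remission_from_pde(p40, i_true, dp_da)
    assert r_hat == pytest.approx(r_true, abs=1e-6)


def test_surface_stage_recovers_constant_rate(constant_world, constant_table):
    """Noiseless emitted table -> fitted surfaces -> r within 10% (30-60)."""
    truth, _ = constant_world
    ages = np.arange(30.0, 61.0, 5.0)
    for sex in ("male", "female"):
        prev, inc = _surfaces_for(constant_table, sex)
        curve = estimate_remission(prev, inc, ages, 2019)
        r_true = np.asarray(truth.r(ages, sex), float)
        assert np.max(np.abs(curve.rate - r_true) / r_true) < 0.10


def test_mismatched_surfaces_rejected(constant_table):
    prev, _ = _surfaces_for(constant_table, "female")
    _, inc = _surfaces_for(constant_table, "male")
    with pytest.raises(ValueError, match="sex"):
        estimate_remission(prev, inc, [40.0], 2019)


def test_zero_incidence_declining_prevalence_gives_positive_rates():
    ages = np.arange(20.0, 81.0, 5.0)
    years = np.arange(1990, 2000)
    aa, tt = np.meshgrid(ages, years, indexing="ij")
    from scipy.special import expit
    p_vals = expit(1.0 - 0.03 * aa)
    rows = []
    for measure, vals in (("prevalence", p_vals),
                          ("incidence", np.full_like(p_vals, 1e-9))):
        rows.append(np.column_stack([
            np.full(aa.size, measure, object), np.full(aa.size, "Germany", object),
            np.full(aa.size, "female", object), tt.ravel(), aa.ravel(),
            vals.ravel(), vals.ravel(), vals.ravel()]))
    import pandas as pd
    df = pd.DataFrame(np.vstack(rows), columns=[
        "measure", "location", "sex", "year", "age_label", "value",
        "lower", "upper"])
    for c in ("year", "value", "lower", "upper"):
        df[c] = df[c].astype(float)
    df["age_mid"] = df["age_label"].astype(float)
    spec = SurfaceSpec(age_degree=3, age_range=None)
    prev = fit_surface(df[df["measure"] == "prevalence"], spec)
    inc = fit_surface(df[df["measure"] == "incidence"], spec)
    curve = estimate_remission(prev, inc, np.arange(30.0, 71.0, 10.0), 1995)
    assert (curve.rate > 0).all()


def test_ages_must_increase():
    with pytest.raises(ValueError):
        RemissionCurve("female", "Germany", 2019,
                       ages=[40.0, 30.0], rate=[0.1, 0.1])


class TestResampling:

    def test_zero_variance_collapses_band(self, constant_table):
        f = constant_table.frame
        sub = GbdTable(f[f["sex"] == "female"])  # lower == value == upper
        est = resample_remission(sub, SPEC, np.arange(30.0, 61.0, 10.0),
                                 2019, n_resamples=10, seed=5)
        np.testing.assert_allclose(est.lower.rate, est.point.rate, rtol=1e-12)
        np.testing.assert_allclose(est.upper.rate, est.point.rate, rtol=1e-12)

    def test_seeded_determinism(self, constant_world):
        _, solution = constant_world
        table = emit_gbd_tables(solution, noise=0.05, seed=3)
        sub = GbdTable(table.frame[table.frame["sex"] == "male"])
        ages = np.arange(30.0, 61.0, 10.0)
        a = resample_remission(sub, SPEC, ages, 2019, n_resamples=20, seed=11)
        b = resample_remission(sub, SPEC, ages, 2019, n_resamples=20, seed=11)
        np.testing.assert_array_equal(a.point.rate, b.point.rate)
        np.testing.assert_array_equal(a.lower.rate, b.lower.rate)
        np.testing.assert_array_equal(a.upper.rate, b.upper.rate)

    def test_band_ordering_and_widening_with_noise(self, constant_world):
        _, solution = constant_world
        ages = np.arange(30.0, 61.0, 10.0)
        widths = {}
        for noise in (0.02, 0.10):
            table = emit_gbd_tables(solution, noise=noise, seed=3)
            sub = GbdTable(table.frame[table.frame["sex"] == "male"])
            est = resample_remission(sub, SPEC, ages, 2019,
                                     n_resamples=60, seed=11)
            assert (est.lower.rate <= est.point.rate).all()
            assert (est.point.rate <= est.upper.rate).all()
            widths[noise] = est.upper.rate - est.lower.rate
        assert (widths[0.10] >= widths[0.02]).all()

    def test_n_resamples_guard(self, constant_table):
        sub = GbdTable(constant_table.frame[
            constant_table.frame["sex"] == "male"])
        with pytest.raises(ValueError):
            resample_remission(sub, SPEC, [40.0], 2019, n_resamples=1)


@pytest.mark.parametrize("scale", [0.5, 2.0])
def test_scale_equivariance_of_rate_ratio(scale):
    """Scaling incidence leaves the recovered r/i ratio near the truth."""
    i_true, r_true = 0.02 * scale, 0.05
    truth = constant_ground_truth(i=i_true, r=r_true)
    solution = solve_truth(truth)
    table = emit_gbd_tables(solution, noise=0.0, seed=0)
    prev, inc = _surfaces_for(table, "female")
    ages = np.arange(30.0, 61.0, 5.0)
    curve = estimate_remission(prev, inc, ages, 2019)
    i_hat = inc.predict(ages, np.full_like(ages, 2019.0))
    ratio = curve.rate / i_hat
    assert np.max(np.abs(ratio - r_true / i_true) / (r_true / i_true)) < 0.10
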