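"""Gf scoring, correlations, Bayes factors, regressions and power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmlearn import (ConfigError, correlation_bf_log3, correlation_with_ci,
                     gf_composite, joint_regression, min_detectable_r,
                     power_at, robust_regression_check)
from wmlearn.associations import correlation_bf_log3_analytic


# ---------------------------------------------------------------------------
# Gf composite
# ---------------------------------------------------------------------------

def test_composite_of_identical_tasks_is_single_zscore():
    x = np.array([40.0, 55.0, 60.0, 72.0])
    out = gf_composite(x, x)
    z = (x - x.mean()) / x.std(ddof=1)
    assert np.allclose(out["composite"], z)


def test_composite_mean_zero(rng):
    out = gf_composite(rng.uniform(20, 90, 40), rng.uniform(20, 90, 40))
    assert abs(out["composite"].mean()) < 1e-12


def test_composite_two_participant_hand_computation():
    # task1 = (40, 60), task2 = (50, 70): each z pair is (-1/sqrt2, 1/sqrt2)
    out = gf_composite([40.0, 60.0], [50.0, 70.0])
    expected = np.array([-1.0, 1.0]) / math.sqrt(2.0)
    assert np.allclose(out["composite"], expected)


def test_composite_rejects_constant_task():
    with pytest.raises(ConfigError):
        gf_composite([50.0, 50.0, 50.0], [10.0, 20.0, 30.0])


# ---------------------------------------------------------------------------
# correlations + bootstrap
# ---------------------------------------------------------------------------

def test_perfect_correlation_degenerate_interval(rng):
    x = rng.normal(size=30)
    res = correlation_with_ci(x, x, n_boot=500, seed=0)
    assert res.estimate == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)
    res_neg = correlation_with_ci(x, -x, n_boot=200, seed=0, compute_bf=False)
    assert res_neg.estimate == pytest.approx(-1.0)


def test_null_correlation_interval_covers_zero(rng):
    x = rng.normal(size=5000)
    y = rng.normal(size=5000)
    res = correlation_with_ci(x, y, n_boot=1000, seed=3)
    assert abs(res.estimate) < 0.05
    assert res.ci_low < 0.0 < res.ci_high
    assert res.bf_log3 < 0  # large-n null data favor H0


def test_bootstrap_is_seeded(rng):
    x, y = rng.normal(size=(2, 60))
    a = correlation_with_ci(x, y, n_boot=400, seed=9)
    b = correlation_with_ci(x, y, n_boot=400, seed=9)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def test_degenerate_input_rejected():
    with pytest.raises(ConfigError):
        correlation_with_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0],
                            n_boot=10, seed=0)


def test_bootstrap_coverage_near_nominal():
    """95% percentile intervals cover the true correlation at close to the
    nominal rate over replicated bivariate-normal cohorts (n = 87)."""
    rho, n, reps = 0.4, 87, 1000
    rng = np.random.default_rng(77)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    hits = 0
    for i in range(reps):
        xy = rng.standard_normal((n, 2)) @ chol.T
        res = correlation_with_ci(xy[:, 0], xy[:, 1], n_boot=600,
                                  seed=i, compute_bf=False)
        hits += res.ci_low <= rho <= res.ci_high
    assert 0.92 <= hits / reps <= 0.97


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def test_bf_quadrature_matches_analytic_route():
    for r in (0.0, 0.1, -0.33, 0.6, 0.96):
        assert correlation_bf_log3(r, 87) == pytest.approx(
            correlation_bf_log3_analytic(r, 87), abs=1e-6)


def test_bf_zero_sample_correlation_favors_null():
    assert correlation_bf_log3(0.0, 87) < 0


@given(r=st.floats(0.01, 0.9))
@settings(deadline=None, max_examples=25)
def test_bf_is_even_in_r(r):
    assert correlation_bf_log3(r, 60) == pytest.approx(
        correlation_bf_log3(-r, 60), abs=1e-9)


def test_bf_monotone_in_magnitude_and_n():
    rs = [0.1, 0.2, 0.3, 0.5, 0.7]
    vals = [correlation_bf_log3(r, 87) for r in rs]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    ns = [10, 30, 87, 200]
    vals_n = [correlation_bf_log3(0.3, n) for n in ns]
    assert all(b > a for a, b in zip(vals_n, vals_n[1:]))


def test_bf_input_validation():
    with pytest.raises(ConfigError):
        correlation_bf_log3(1.0, 87)
    with pytest.raises(ConfigError):
        correlation_bf_log3(0.3, 3)
    with pytest.raises(ConfigError):
        correlation_bf_log3(0.3, 87, prior_width=0.0)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def test_regression_orthogonal_predictors_identity(rng):
    n = 400
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    # orthogonalize and standardize
    b = b - a * (a @ b) / (a @ a)
    a = (a - a.mean()) / a.std(ddof=1)
    b = (b - b.mean()) / b.std(ddof=1)
    y = 0.4 * a + 0.25 * b + rng.standard_normal(n)
    tab = joint_regression(y, a, b)
    for name, x in (("rate", a), ("final", b)):
        simple_r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert tab.loc[name, "delta_r2"] == pytest.approx(simple_r2, abs=0.01)


def test_regression_exact_linear_dependence(rng):
    n = 60
    final = rng.standard_normal(n)
    rate = rng.standard_normal(n)
    gf = 2.0 * final
    tab = joint_regression(gf, rate, final)
    assert tab.loc["final", "coef"] == pytest.approx(2.0, abs=1e-10)
    assert tab.loc["rate", "delta_r2"] == pytest.approx(0.0, abs=1e-10)


def test_regression_matches_normal_equations(rng):
    n = 87
    rate = rng.standard_normal(n)
    final = 0.3 * rate + rng.standard_normal(n)
    gf = -0.2 * rate + 0.5 * final + rng.standard_normal(n)
    tab = joint_regression(gf, rate, final)
    X = np.column_stack([np.ones(n), rate, final])
    beta = np.linalg.solve(X.T @ X, X.T @ gf)
    assert tab.loc["rate", "coef"] == pytest.approx(beta[1], abs=1e-10)
    assert tab.loc["final", "coef"] == pytest.approx(beta[2], abs=1e-10)
    # semi-partial contributions are nonnegative and bounded by full R^2
    assert (tab["delta_r2"] >= -1e-12).all()
    assert (tab["delta_r2"] <= tab["r2_full"] + 1e-12).all()


def test_robust_matches_ols_on_clean_data(rng):
    n = 300
    rate = rng.standard_normal(n)
    final = rng.standard_normal(n)
    gf = -0.3 * rate + 0.5 * final + 0.5 * rng.standard_normal(n)
    ols = joint_regression(gf, rate, final)
    rob = robust_regression_check(gf, rate, final)
    for name in ("rate", "final"):
        assert rob.loc[name, "coef"] == pytest.approx(
            ols.loc[name, "coef"], rel=0.10)


def test_robust_resists_leverage_point(rng):
    n = 60
    rate = rng.standard_normal(n)
    final = rng.standard_normal(n)
    gf = 0.5 * final + 0.3 * rng.standard_normal(n)
    clean = joint_regression(gf, rate, final).loc["final", "coef"]
    gf_c, final_c = gf.copy(), final.copy()
    final_c[0], gf_c[0] = 6.0, -8.0      # one extreme high-leverage point
    contaminated = joint_regression(gf_c, rate, final_c).loc["final", "coef"]
    robust = robust_regression_check(gf_c, rate, final_c).loc["final", "coef"]
    assert abs(robust - clean) < abs(contaminated - clean)


def test_robust_constant_response_gives_zero_slopes(rng):
    rate = rng.standard_normal(20)
    final = rng.standard_normal(20)
    rob = robust_regression_check(np.ones(20), rate, final)
    assert np.allclose(rob["coef"], 0.0)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def test_power_null_case_equals_alpha():
    # at rho = 0 "power" degenerates to the two-sided type-I rate
    assert power_at(87, 0.0, 0.05) == pytest.approx(0.05, abs=1e-9)
    assert power_at(40, 0.0, 0.10) == pytest.approx(0.10, abs=1e-9)


def test_power_increases_with_n():
    assert power_at(10_000, 0.1) > power_at(100, 0.1) > power_at(10, 0.1)
    assert power_at(100_000, 0.3) > 0.999999


def test_min_detectable_inverts_power():
    r = min_detectable_r(87, 0.80, 0.05)
    assert power_at(87, r, 0.05) == pytest.approx(0.80, abs=1e-9)


def test_power_matches_monte_carlo():
    """Fisher-z power at n=87, r=0.30 agrees with a 20000-replicate
    simulated rejection rate of the two-sided alpha=.05 test."""
    n, rho, reps = 87, 0.30, 20_000
    rng = np.random.default_rng(5)
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    z = rng.standard_normal((reps, n, 2)) @ chol.T
    zc = z - z.mean(axis=1, keepdims=True)
    num = np.sum(zc[..., 0] * zc[..., 1], axis=1)
    den = np.sqrt(np.sum(zc[..., 0]**2, axis=1) * np.sum(zc[..., 1]**2, axis=1))
    r = num / den
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    from scipy import stats as sps
    crit = sps.t.ppf(0.975, n - 2)
    mc_power = np.mean(np.abs(tstat) > crit)
    assert power_at(n, rho, 0.05) == pytest.approx(mc_power, abs=0.01)
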