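import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ectomark.errors import DegenerateDataError, InputError
from ectomark.survival_core import (
    fit_cox,
    kaplan_meier,
    logrank_scan,
    logrank_test,
)

# 8-patient two-group fixture with ties (times in months)
FIXTURE_TIME = np.array([5.0, 8.0, 8.0, 12.0, 16.0, 16.0, 20.0, 30.0])
FIXTURE_EVENT = np.array([1, 1, 0, 1, 1, 1, 0, 1])
FIXTURE_GROUP = np.array([1, 0, 1, 1, 0, 1, 0, 0])


def logrank_oracle(time, event, group):
    """Independent brute-force O/E/V accumulation over distinct event times."""
    O = E = V = 0.0
    for t in sorted({t for t, e in zip(time, event) if e == 1}):
        n = sum(ti >= t for ti in time)
        n1 = sum(ti >= t and gi == 1 for ti, gi in zip(time, group))
        d = sum(ti == t and ei == 1 for ti, ei in zip(time, event))
        d1 = sum(
            ti == t and ei == 1 and gi == 1 for ti, ei, gi in zip(time, event, group)
        )
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


# --- Kaplan-Meier ----------------------------------------------------------

def test_km_all_censored_is_unit():
    km = kaplan_meier([3.0, 5.0, 9.0], [0, 0, 0])
    assert km.event_times.size == 0
    assert km.survival_at(100.0) == 1.0


def test_km_hand_computed_product_limit():
    km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
    assert np.allclose(km.event_times, [1.0, 3.0])
    assert np.allclose(km.survival, [2 / 3, 0.0])
    assert km.survival_at(0.5) == 1.0
    assert km.survival_at(2.5) == pytest.approx(2 / 3)
    assert km.survival_at(3.0) == 0.0


def test_km_invariant_to_record_duplication(rng):
    t = rng.exponential(10, 40) + 0.1
    e = (rng.random(40) < 0.6).astype(int)
    km1 = kaplan_meier(t, e)
    km2 = kaplan_meier(np.r_[t, t], np.r_[e, e])
    assert np.allclose(km1.survival, km2.survival)
    assert np.allclose(km1.event_times, km2.event_times)


@settings(derandomize=True, deadline=None, max_examples=30)
@given(st.lists(st.tuples(st.floats(0.1, 50), st.booleans()), min_size=2, max_size=40))
def test_km_monotone_and_censoring_tail_invariant(records):
    t = np.array([r[0] for r in records])
    e = np.array([int(r[1]) for r in records])
    km = kaplan_meier(t, e)
    assert np.all(np.diff(km.survival) <= 1e-12)
    assert (km.survival <= 1.0 + 1e-12).all()
    # a censored record beyond the last event time contributes only its
    # presence in earlier risk sets, never a step: its exact position is
    # irrelevant to the curve
    km2 = kaplan_meier(np.r_[t, t.max() + 1.0], np.r_[e, 0])
    km3 = kaplan_meier(np.r_[t, t.max() + 1000.0], np.r_[e, 0])
    assert np.allclose(km2.survival, km3.survival)
    assert np.array_equal(km2.event_times, km3.event_times)


def test_km_empty_input_refused():
    with pytest.raises(InputError):
        kaplan_meier([], [])


# --- log-rank --------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    t = [2.0, 4.0, 6.0, 2.0, 4.0, 6.0]
    e = [1, 0, 1, 1, 0, 1]
    g = [0, 0, 0, 1, 1, 1]
    r = logrank_test(t, e, g)
    assert r.chi_square == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0)


def test_logrank_matches_brute_force_oracle():
    r = logrank_test(FIXTURE_TIME, FIXTURE_EVENT, FIXTURE_GROUP)
    expected = logrank_oracle(FIXTURE_TIME, FIXTURE_EVENT, FIXTURE_GROUP)
    assert r.chi_square == pytest.approx(expected, abs=1e-10)
    assert r.observed.sum() == pytest.approx(r.expected.sum(), abs=1e-10)


def test_logrank_matches_lifelines():
    from lifelines.statistics import multivariate_logrank_test

    rng = np.random.default_rng(5)
    t = rng.exponential(20, 60).round(0) + 1.0
    e = (rng.random(60) < 0.7).astype(int)
    g = rng.integers(0, 3, 60)
    r = logrank_test(t, e, g)
    ll = multivariate_logrank_test(t, g, e)
    assert r.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
    assert r.degrees_of_freedom == 2


def test_logrank_group_relabel_invariance():
    r1 = logrank_test(FIXTURE_TIME, FIXTURE_EVENT, FIXTURE_GROUP)
    r2 = logrank_test(FIXTURE_TIME, FIXTURE_EVENT, 1 - FIXTURE_GROUP)
    assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-12)


def test_logrank_permutation_consistency(rng):
    n = 30
    t = rng.exponential(20, n) + 0.5
    e = (rng.random(n) < 0.8).astype(int)
    g = rng.random(n) < 0.5
    obs = logrank_scan(t, e, g[None, :])
    perms = np.array([rng.permutation(g) for _ in range(10_000)])
    res = logrank_scan(t, e, perms)
    ok = res["evaluable"]
    p_perm = float(np.mean(res["chi_square"][ok] >= obs["chi_square"][0] - 1e-12))
    p_asym = float(obs["p"][0])
    mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / 10_000)
    assert abs(p_perm - p_asym) < mc_err + 0.02  # MC error + chi2 approximation


def test_logrank_degeneracies_raise():
    with pytest.raises(DegenerateDataError):
        logrank_test([1.0, 2.0], [1, 1], [0, 0])  # single group
    with pytest.raises(DegenerateDataError):
        logrank_test([1.0, 2.0], [0, 0], [0, 1])  # zero events


def test_logrank_scan_matches_single_tests(rng):
    t = rng.exponential(15, 50) + 0.1
    e = (rng.random(50) < 0.7).astype(int)
    x = rng.normal(size=50)
    thresholds = np.percentile(x, [20, 50, 80])
    high = x[None, :] > thresholds[:, None]
    batch = logrank_scan(t, e, high)
    for i in range(3):
        single = logrank_test(t, e, high[i].astype(int))
        assert batch["chi_square"][i] == pytest.approx(single.chi_square, abs=1e-10)


# --- Cox -------------------------------------------------------------------

def test_cox_matches_lifelines_with_ties():
    import lifelines
    import pandas as pd

    rng = np.random.default_rng(1)
    n = 120
    x = rng.normal(size=(n, 2))
    t = np.maximum(np.ceil(rng.exponential(20 * np.exp(-0.5 * x[:, 0]), n)), 1.0)
    e = (rng.random(n) < 0.7).astype(int)
    fit = fit_cox(x, t, e, names=["x0", "x1"])
    cph = lifelines.CoxPHFitter()
    cph.fit(
        pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]}),
        duration_col="t",
        event_col="e",
    )
    assert np.allclose(fit.coefficients, cph.params_.values, atol=1e-5)
    assert np.allclose(fit.standard_errors, cph.standard_errors_.values, atol=1e-5)
    assert fit.converged


def test_cox_recovers_two_group_hazard_ratio():
    rng = np.random.default_rng(9)
    n = 2000
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (0.02 * 2.5**x))
    e = np.ones(n, dtype=int)
    cens = rng.exponential(80, n)
    e[t > cens] = 0
    t = np.minimum(t, cens)
    fit = fit_cox(x[:, None], t, e)
    assert 2.2 < fit.hazard_ratios[0] < 2.8


def test_cox_null_calibration():
    inside = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        x = rng.normal(size=300)
        t = rng.exponential(30, 300)
        e = (rng.random(300) < 0.7).astype(int)
        fit = fit_cox(x[:, None], t, e)
        if abs(fit.coefficients[0]) < 3 * fit.standard_errors[0]:
            inside += 1
    assert inside >= 95


def test_cox_efron_equals_breslow_without_ties(rng):
    x = rng.normal(size=(80, 2))
    t = rng.exponential(10, 80)  # continuous: no ties
    e = (rng.random(80) < 0.8).astype(int)
    f1 = fit_cox(x, t, e, tie_method="efron")
    f2 = fit_cox(x, t, e, tie_method="breslow")
    assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-10)


def test_cox_scale_equivariance(rng):
    x = rng.normal(size=60)
    t = rng.exponential(10 * np.exp(-0.3 * x))
    e = np.ones(60, dtype=int)
    f1 = fit_cox(x[:, None], t, e)
    f2 = fit_cox((10 * x)[:, None], t, e)
    assert f2.coefficients[0] == pytest.approx(f1.coefficients[0] / 10, abs=1e-8)


def test_cox_refusals_and_separation():
    t = np.arange(1.0, 41.0)
    e = np.ones(40, dtype=int)
    with pytest.raises(InputError, match="constant"):
        fit_cox(np.ones((40, 1)), t, e)
    with pytest.raises(DegenerateDataError):
        fit_cox(np.arange(40.0)[:, None], t, np.zeros(40, dtype=int))
    with pytest.raises(InputError, match="rank"):
        x = np.arange(40.0)
        fit_cox(np.column_stack([x, 2 * x]), t, e)
    # perfect separation: covariate strictly orders event times
    xs = np.linspace(0, 1, 40)
    fs = fit_cox(xs[:, None], 100 - 90 * xs, e)
    assert fs.monotone_likelihood and not fs.converged


def test_cox_hazard_ratio_is_exp_coefficient(rng):
    x = rng.normal(size=(50, 1))
    t = rng.exponential(10, 50)
    e = (rng.random(50) < 0.6).astype(int)
    fit = fit_cox(x, t, e)
    assert np.allclose(fit.hazard_ratios, np.exp(fit.coefficients))
    assert ((fit.p_values >= 0) & (fit.p_values <= 1)).all()
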