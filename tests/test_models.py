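"""Contracts of the regression/test primitives against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pigmentmr import models
from pigmentmr.models import (
    FitError,
    compare_nested,
    confounder_tests,
    f_from_chi2,
    fit_logistic,
    fit_multinomial,
    fit_propensity,
    pseudo_r2_delta,
    weighted_least_squares,
)


def _expand_2x2(a, b, c, d):
    """cases exposed/unexposed = a/c; controls exposed/unexposed = b/d."""
    y = np.r_[np.ones(a + c), np.zeros(b + d)]
    x = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
    return y, pd.DataFrame({"x": x})


def test_logistic_2x2_matches_cross_product_or():
    y, X = _expand_2x2(509, 622, 987, 967)
    fit = fit_logistic(y, X)
    or_hat = fit.summary_table().iloc[0]["estimate"]
    assert or_hat == pytest.approx(509 * 967 / (622 * 987), abs=1e-8)


def test_logistic_balanced_table_is_null():
    y, X = _expand_2x2(50, 50, 50, 50)
    tab = fit_logistic(y, X).summary_table()
    assert tab.iloc[0]["estimate"] == pytest.approx(1.0, abs=1e-8)
    assert tab.iloc[0]["p_value"] == pytest.approx(1.0, abs=1e-6)


def test_logistic_separation_fails_loudly():
    y = np.r_[np.ones(20), np.zeros(20)]
    X = pd.DataFrame({"sep": np.r_[np.ones(20), np.zeros(20)]})
    with pytest.raises(FitError):
        fit_logistic(y, X)


def test_logistic_ci_brackets_estimate():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"z": rng.normal(size=500)})
    y = (rng.random(500) < 1 / (1 + np.exp(-0.4 * X["z"]))).astype(float)
    tab = fit_logistic(y, X).summary_table()
    assert (tab["ci_low"] <= tab["estimate"]).all()
    assert (tab["estimate"] <= tab["ci_high"]).all()
    assert (tab["estimate"] > 0).all()
    assert tab["p_value"].between(0, 1).all()


def test_multinomial_two_categories_reduces_to_logistic():
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"z": rng.normal(size=300), "w": rng.normal(size=300)})
    y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 * X["z"] - 0.2 * X["w"])))).astype(int)
    lf = fit_logistic(y, X)
    mf = fit_multinomial(y.to_numpy(), X)
    assert np.abs(mf.params.iloc[:, 0].to_numpy() - lf.params.to_numpy()).max() < 1e-6


def _mnlogit_newton_oracle(y, X, n_cats, tol=1e-12, iters=200):
    """Independent multinomial-logit ML fit from the score equations."""
    n, k = X.shape
    J = n_cats - 1
    beta = np.zeros(k * J)
    Y = np.zeros((n, J))
    for j in range(J):
        Y[:, j] = y == (j + 1)
    for _ in range(iters):
        eta = X @ beta.reshape(J, k).T  # n x J
        denom = 1.0 + np.exp(eta).sum(axis=1)
        P = np.exp(eta) / denom[:, None]
        grad = np.concatenate([X.T @ (Y[:, j] - P[:, j]) for j in range(J)])
        H = np.zeros((k * J, k * J))
        for j in range(J):
            for l in range(J):
                w = P[:, j] * ((j == l) - P[:, l])
                H[j * k:(j + 1) * k, l * k:(l + 1) * k] = X.T @ (X * w[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta.reshape(J, k).T  # k x J


def test_multinomial_matches_independent_newton_oracle():
    """60-row fixture, 3 categories: coefficients agree with a from-scratch
    Newton solver on the multinomial score equations to 1e-6."""
    rng = np.random.default_rng(42)
    n = 60
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.integers(0, 2, n).astype(float)})
    y = rng.integers(0, 3, n)
    y[:3] = [0, 1, 2]  # every category present
    mf = fit_multinomial(y, X)
    Xd = np.column_stack([np.ones(n), X["x1"], X["x2"]])
    oracle = _mnlogit_newton_oracle(y, Xd, 3)
    assert np.abs(mf.params.to_numpy() - oracle).max() < 1e-6


def test_multinomial_empty_category_rejected():
    y = pd.Series(pd.Categorical(["a", "b"] * 20, categories=["a", "b", "c"]))
    with pytest.raises(FitError, match="empty"):
        fit_multinomial(y, pd.DataFrame({"z": np.arange(40.0)}))


def test_wls_two_point_line_exact():
    fit = weighted_least_squares([1, 2, 3], [2, 4, 6], [1, 1, 1])
    assert fit.intercept == pytest.approx(0.0, abs=1e-10)
    assert fit.slope == pytest.approx(2.0, abs=1e-10)


def test_wls_constant_y_zero_slope():
    fit = weighted_least_squares([1, 2, 3, 4], [5, 5, 5, 5], [1, 2, 3, 4])
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.intercept == pytest.approx(5.0, abs=1e-12)


def test_wls_matches_grid_oracle():
    """5 weighted points: the WLS solution beats/matches every (a, b) on a
    fine grid around it for the weighted SSE, and equals the normal-equation
    oracle within 1e-6."""
    x = np.array([0.1, 0.5, 1.0, 1.7, 2.4])
    y = np.array([0.3, 0.2, 0.9, 1.1, 2.0])
    w = np.array([1.0, 4.0, 0.5, 2.0, 1.0])
    fit = weighted_least_squares(x, y, w)
    # normal equations oracle
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    ab = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    assert fit.intercept == pytest.approx(ab[0], abs=1e-6)
    assert fit.slope == pytest.approx(ab[1], abs=1e-6)
    sse = lambda a, b: (w * (y - a - b * x) ** 2).sum()
    best = sse(fit.intercept, fit.slope)
    for da in np.linspace(-0.01, 0.01, 11):
        for db in np.linspace(-0.01, 0.01, 11):
            assert best <= sse(fit.intercept + da, fit.slope + db) + 1e-12


def test_wls_equal_weights_equals_ols():
    rng = np.random.default_rng(3)
    x = rng.normal(size=20)
    y = 1.5 + 0.7 * x + rng.normal(size=20)
    f1 = weighted_least_squares(x, y, np.ones(20))
    f2 = weighted_least_squares(x, y, np.full(20, 13.7))  # scale-invariant
    res = stats.linregress(x, y)
    for f in (f1, f2):
        assert f.slope == pytest.approx(res.slope, abs=1e-10)
        assert f.intercept == pytest.approx(res.intercept, abs=1e-10)
        assert f.se_slope == pytest.approx(res.stderr, abs=1e-10)


def test_wls_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        weighted_least_squares([1, 2], [1, 2], [1, 1])
    with pytest.raises(ValueError):
        weighted_least_squares([2, 2, 2], [1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError):
        weighted_least_squares([1, 2, 3], [1, 2, 3], [1, 0, 1])


@pytest.mark.parametrize(
    "chi2, k, expected", [(12.0, 4, 4.0), (0.0, 3, 0.0), (7.3, 2, 7.3)]
)
def test_f_from_chi2(chi2, k, expected):
    assert f_from_chi2(chi2, k) == pytest.approx(expected)


def test_f_from_chi2_rejects_degenerate():
    with pytest.raises(ValueError):
        f_from_chi2(1.0, 1)
    with pytest.raises(ValueError):
        f_from_chi2(-1.0, 3)


def test_pseudo_r2_delta_identical_models_zero():
    assert pseudo_r2_delta(-100.0, -100.0, -150.0) == pytest.approx(0.0)


def test_compare_nested_likelihood_never_decreases(scored_small):
    """Adding the GPS to the propensity-only model cannot lower the
    likelihood, and the comparison reports a non-negative chi-square."""
    s = scored_small
    c = s["cohort"]
    full = fit_logistic(
        c.outcome, pd.DataFrame({"gps": s["gps"], "propensity": s["propensity"].values})
    )
    reduced = fit_logistic(c.outcome, pd.DataFrame({"propensity": s["propensity"].values}))
    assert full.llf >= reduced.llf - 1e-9
    comp = compare_nested(full.llf, reduced.llf, 1, 2, reduced.llnull)
    assert comp.chi_square >= 0
    assert comp.f_stat == comp.chi_square  # k=2
    assert 0 <= comp.p_value <= 1


def test_compare_nested_rejects_non_nested():
    with pytest.raises(ValueError):
        compare_nested(-110.0, -100.0, 1, 2, -150.0)
    with pytest.raises(ValueError):
        compare_nested(-100.0, -100.0, 0, 2, -150.0)


def test_propensity_mean_equals_case_fraction(scored_small):
    """ML logistic with intercept: fitted probabilities average to the
    observed case fraction (score equation)."""
    s = scored_small
    c = s["cohort"]
    prop = s["propensity"]
    assert prop.values.mean() == pytest.approx(c.outcome.mean(), abs=1e-8)
    assert ((prop.values > 0) & (prop.values < 1)).all()
    assert {"age", "bmi", "pc1", "pc2", "pc3"}.issubset(prop.terms)


def test_propensity_adjustment_recovers_confounded_effect():
    """With a strong age confounder linking an exposure and the outcome, the
    propensity-adjusted OR is closer to the (null) truth than the crude OR."""
    rng = np.random.default_rng(5)
    n = 4000
    age = rng.normal(60, 10, n)
    expo = 0.05 * (age - 60) + rng.normal(size=n)  # exposure driven by age
    p = 1 / (1 + np.exp(-(0.06 * (age - 60))))     # outcome driven by age only
    y = (rng.random(n) < p).astype(float)
    crude = fit_logistic(y, pd.DataFrame({"e": expo})).params["e"]
    cov = pd.DataFrame(
        {
            "age": age,
            "bmi": rng.normal(26, 4, n),
            "smoking": pd.Categorical(rng.choice(["never", "former", "current"], n)),
            "education": pd.Categorical(
                rng.choice(["a", "b", "c"], n), ordered=True
            ),
            "centre": pd.Categorical(rng.choice(["x", "y"], n)),
            "pc1": rng.normal(size=n),
            "pc2": rng.normal(size=n),
            "pc3": rng.normal(size=n),
        }
    )
    prop = fit_propensity(cov, pd.Series(y))
    adj = fit_logistic(
        pd.Series(y), pd.DataFrame({"e": expo, "prop": prop.values})
    ).params["e"]
    assert abs(adj) < abs(crude)


def test_confounder_tests_hand_chi_square(scored_small):
    """2x4 contingency fixture matches the hand-computed Pearson statistic."""
    table = np.array([[10, 10, 10, 10], [10, 10, 10, 30]])
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    hand = ((table - expected) ** 2 / expected).sum()
    # expand to unit records
    quart, values = [], []
    for i in range(2):
        for j in range(4):
            quart += [j + 1] * table[i, j]
            values += [f"lvl{i}"] * table[i, j]
    tab = confounder_tests(
        pd.Series(quart, dtype=float), pd.DataFrame({"conf": values}), {"conf": "categorical"}
    )
    assert tab.iloc[0]["statistic"] == pytest.approx(hand, abs=1e-10)
    chk = stats.chi2_contingency(table.T, correction=False)[0]
    assert tab.iloc[0]["statistic"] == pytest.approx(chk, abs=1e-10)


def test_confounder_tests_constant_confounder_degenerate():
    q = pd.Series([1.0, 2.0, 3.0, 4.0] * 10)
    tab = confounder_tests(q, pd.DataFrame({"c": ["same"] * 40, "x": [3.3] * 40}),
                           {"c": "categorical", "x": "continuous"})
    assert (tab["statistic"] == 0).all()
    assert (tab["flag"] == "degenerate").all()


def test_confounder_tests_anova_matches_scipy(scored_small):
    s = scored_small
    c = s["cohort"]
    controls = c.control_mask
    q = s["quartiles"][controls]
    tab = confounder_tests(q, c.covariates.loc[controls.to_numpy(), ["age"]], {"age": "continuous"})
    groups = [
        c.covariates.loc[controls.to_numpy(), "age"][q == lvl].to_numpy()
        for lvl in sorted(q.unique())
    ]
    f, p = stats.f_oneway(*groups)
    assert tab.iloc[0]["statistic"] == pytest.approx(f)
    assert tab.iloc[0]["p_value"] == pytest.approx(p)
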