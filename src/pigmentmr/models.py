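"""Regression and test primitives for the case-control analysis.

Thin, contract-checked wrappers around statsmodels (Logit, MNLogit, WLS) and
scipy tests, returning the quantities the pipeline reports: odds ratios /
relative risk ratios with 95% Wald intervals, likelihood-ratio chi-squares and
the derived F statistic chi2/(k-1), McFadden pseudo-R^2 differences against a
shared null, and the case-control propensity score used for adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FitError",
    "LogisticFit",
    "MultinomialFit",
    "WlsFit",
    "ModelComparison",
    "PropensityScore",
    "fit_logistic",
    "fit_multinomial",
    "weighted_least_squares",
    "f_from_chi2",
    "pseudo_r2_delta",
    "compare_nested",
    "fit_propensity",
    "confounder_tests",
    "build_covariate_design",
]

MAX_ITER = 100
TOL = 1e-8
_Z95 = stats.norm.ppf(0.975)


class FitError(RuntimeError):
    """Model failed to converge (separation, collinearity, empty category)."""


def _check_converged(result, terms) -> None:
    if not result.mle_retvals.get("converged", False):
        raise FitError(f"logistic fit did not converge; terms: {list(terms)}")
    se = np.sqrt(np.diag(result.cov_params()))
    if not np.all(np.isfinite(se)) or (se > 1e3).any():
        bad = np.asarray(terms)[np.argmax(np.where(np.isfinite(se), se, np.inf))]
        raise FitError(f"quasi-separation: unbounded standard error for term {bad!r}")


@dataclass
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    llnull: float
    n: int
    n_iter: int

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def summary_table(self) -> pd.DataFrame:
        """term / OR / 95% Wald CI / two-tailed p, one row per non-intercept term."""
        se = self.se
        z = self.params / se
        p = 2 * stats.norm.sf(np.abs(z))
        tab = pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": np.exp(self.params.to_numpy()),
                "ci_low": np.exp(self.params.to_numpy() - _Z95 * se.to_numpy()),
                "ci_high": np.exp(self.params.to_numpy() + _Z95 * se.to_numpy()),
                "p_value": p,
            }
        ).reset_index(drop=True)
        return tab[tab["term"] != "const"].reset_index(drop=True)


def _design(X: pd.DataFrame | pd.Series, add_const: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    return X


def fit_logistic(outcome, X, add_const: bool = True) -> LogisticFit:
    """Maximum-likelihood binary logistic regression (Newton-Raphson).

    Convergence requires successive log-likelihood change < 1e-8 within 100
    iterations; separation or collinearity raises :class:`FitError` naming the
    offending term.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    Xd = _design(X, add_const)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, Xd)
            res = model.fit(method="newton", maxiter=MAX_ITER, tol=TOL, disp=0)
        except Exception as exc:  # singular matrix, perfect separation
            raise FitError(f"logistic fit failed ({exc}); terms: {list(Xd.columns)}") from exc
    _check_converged(res, Xd.columns)
    lln = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    return LogisticFit(
        params=pd.Series(res.params, index=Xd.columns),
        cov=pd.DataFrame(res.cov_params(), index=Xd.columns, columns=Xd.columns),
        llf=float(res.llf),
        llnull=float(lln),
        n=len(y),
        n_iter=int(res.mle_retvals.get("iterations", 0)),
    )


@dataclass
class MultinomialFit:
    """Multinomial logit with the first (darkest) category as reference.

    ``params`` has one column per non-reference category, rows = design terms;
    exponentiated coefficients are relative risk ratios (RRR).
    """

    params: pd.DataFrame
    cov: np.ndarray
    llf: float
    llnull: float
    n: int
    categories: list

    def rrr_table(self, term: str) -> pd.DataFrame:
        """RRR with 95% Wald CI and p for one design term, per non-ref category."""
        k = self.params.shape[0]
        rows = []
        term_i = list(self.params.index).index(term)
        for j, cat in enumerate(self.categories[1:]):
            b = self.params.iloc[term_i, j]
            se = np.sqrt(self.cov[j * k + term_i, j * k + term_i])
            z = b / se
            rows.append(
                {
                    "category": cat,
                    "term": term,
                    "estimate": np.exp(b),
                    "ci_low": np.exp(b - _Z95 * se),
                    "ci_high": np.exp(b + _Z95 * se),
                    "p_value": 2 * stats.norm.sf(abs(z)),
                }
            )
        return pd.DataFrame(rows)


def fit_multinomial(outcome, X, add_const: bool = True) -> MultinomialFit:
    """ML multinomial logistic regression; reference = first declared category.

    ``outcome`` may be an ordered pandas Categorical (reference = first
    category, the darkest) or integer codes 0..K-1 (reference = 0).
    """
    if isinstance(outcome, pd.Series) and isinstance(outcome.dtype, pd.CategoricalDtype):
        codes = outcome.cat.codes.to_numpy()
        categories = list(outcome.cat.categories)
        if (codes == -1).any():
            raise ValueError("outcome contains missing categories")
    else:
        codes = np.asarray(outcome, dtype=int)
        categories = sorted(np.unique(codes).tolist())
    counts = np.bincount(codes, minlength=len(categories))
    if (counts == 0).any():
        empty = categories[int(np.argmin(counts))]
        raise FitError(f"empty outcome category: {empty!r}")
    Xd = _design(X, add_const)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(codes, Xd).fit(method="newton", maxiter=MAX_ITER, tol=TOL, disp=0)
        except Exception as exc:
            raise FitError(f"multinomial fit failed ({exc}); terms: {list(Xd.columns)}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError(f"multinomial fit did not converge; terms: {list(Xd.columns)}")
    lln = sm.MNLogit(codes, np.ones((len(codes), 1))).fit(disp=0).llf
    params = pd.DataFrame(
        np.asarray(res.params), index=Xd.columns, columns=[str(c) for c in categories[1:]]
    )
    return MultinomialFit(
        params=params,
        cov=np.asarray(res.cov_params()),
        llf=float(res.llf),
        llnull=float(lln),
        n=len(codes),
        categories=categories,
    )


@dataclass(frozen=True)
class WlsFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_intercept: float
    p_slope: float
    n: int


def weighted_least_squares(x, y, weights) -> WlsFit:
    """Closed-form weighted simple linear regression.

    Standard errors use the weighted residual variance on n-2 degrees of
    freedom; p-values are two-tailed t tests. Needs >= 3 points, positive
    weights and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(x) < 3:
        raise ValueError("weighted least squares needs at least 3 points")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    X = np.column_stack([np.ones_like(x), x])
    res = sm.WLS(y, X, weights=w).fit()
    a, b = res.params
    se_a, se_b = res.bse
    p_a, p_b = res.pvalues
    return WlsFit(float(a), float(b), float(se_a), float(se_b), float(p_a), float(p_b), len(x))


def f_from_chi2(chi_square: float, k_categories: int) -> float:
    """F statistic convention for phenotype models: chi-square / (k - 1)."""
    if k_categories < 2:
        raise ValueError("phenotype must have at least 2 categories")
    if chi_square < 0:
        raise ValueError("chi-square must be non-negative")
    return chi_square / (k_categories - 1)


def pseudo_r2_delta(llf_full: float, llf_reduced: float, llf_null: float) -> float:
    """Difference of McFadden pseudo-R^2 (percent) between two nested models
    evaluated against one shared intercept-only null."""
    r2_full = 1.0 - llf_full / llf_null
    r2_reduced = 1.0 - llf_reduced / llf_null
    return 100.0 * (r2_full - r2_reduced)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison of nested models, Table-1/2 style."""

    chi_square: float
    df: int
    f_stat: float
    p_value: float
    delta_r2: float


def compare_nested(
    llf_full: float,
    llf_reduced: float,
    df_diff: int,
    k_categories: int,
    llf_null: float,
) -> ModelComparison:
    """LR chi-square, F = chi2/(k-1), p and McFadden delta-R^2 (percent)."""
    if df_diff < 1:
        raise ValueError("models are not nested (no extra parameters)")
    chi2 = 2.0 * (llf_full - llf_reduced)
    if chi2 < -1e-6:
        raise ValueError("full model has lower likelihood; models are not nested")
    chi2 = max(chi2, 0.0)
    return ModelComparison(
        chi_square=chi2,
        df=df_diff,
        f_stat=f_from_chi2(chi2, k_categories),
        p_value=float(stats.chi2.sf(chi2, df=df_diff)),
        delta_r2=pseudo_r2_delta(llf_full, llf_reduced, llf_null),
    )


PROPENSITY_TERMS = ("centre", "pc1", "pc2", "pc3", "age", "education", "bmi", "smoking")


def build_covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for the propensity model: age/BMI/PCs linear, centre and
    smoking dummy-coded, education dummy-coded with the lowest level as
    reference. No intercept column (added at fit time)."""
    cols = {}
    cols["age"] = covariates["age"].astype(float)
    cols["bmi"] = covariates["bmi"].astype(float)
    for pc in ("pc1", "pc2", "pc3"):
        cols[pc] = covariates[pc].astype(float)
    for name in ("centre", "smoking", "education"):
        c = covariates[name]
        if not isinstance(c.dtype, pd.CategoricalDtype):
            c = c.astype("category")
        dummies = pd.get_dummies(c, prefix=name, drop_first=True, dtype=float)
        for col in dummies.columns:
            cols[col] = dummies[col]
    return pd.DataFrame(cols, index=covariates.index)


@dataclass
class PropensityScore:
    """Fitted probability of being a case given the design covariates."""

    values: pd.Series
    terms: list[str]
    fit: LogisticFit


def fit_propensity(covariates: pd.DataFrame, outcome: pd.Series) -> PropensityScore:
    """Logistic case-status model on centre, ancestry PCs, age, education,
    BMI and smoking; the fitted probability is entered downstream as a single
    linear adjustment covariate. Complete-case on the covariates."""
    X = build_covariate_design(covariates)
    ok = ~X.isna().any(axis=1) & ~outcome.isna()
    fit = fit_logistic(outcome[ok], X[ok])
    eta = fit.params["const"] + X[ok].to_numpy() @ fit.params.drop("const").to_numpy()
    prob = 1.0 / (1.0 + np.exp(-eta))
    values = pd.Series(np.nan, index=outcome.index, name="propensity")
    values[ok] = prob
    return PropensityScore(values=values, terms=list(X.columns), fit=fit)


def confounder_tests(
    quartiles: pd.Series,
    confounders: pd.DataFrame,
    types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Association of each potential confounder with GPS quartile.

    Categorical confounders: Pearson chi-square on the quartile x category
    contingency table (no continuity correction). Continuous confounders:
    one-way ANOVA across quartiles. Tests whose expected chi-square counts
    include a zero are skipped with a flag instead of reporting a statistic.
    """
    if confounders.shape[1] == 0:
        raise ValueError("confounder table is empty")
    types = types or {}
    rows = []
    q = quartiles.dropna()
    for name in confounders.columns:
        col = confounders.loc[q.index, name]
        kind = types.get(name)
        if kind is None:
            kind = (
                "continuous"
                if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8
                else "categorical"
            )
        ok = ~col.isna()
        if kind == "continuous":
            groups = [col[ok][q[ok] == level].to_numpy(dtype=float) for level in sorted(q.unique())]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2 or all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
                stat, p, flag = 0.0, 1.0, "degenerate"
            else:
                f = stats.f_oneway(*groups)
                stat, p, flag = float(f.statistic), float(f.pvalue), ""
                if np.isnan(stat):  # zero within-group variance everywhere
                    stat, p, flag = 0.0, 1.0, "degenerate"
            rows.append({"confounder": name, "test": "anova", "statistic": stat,
                         "p_value": p, "flag": flag})
        else:
            tab = pd.crosstab(q[ok], col[ok].astype(str))
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                rows.append({"confounder": name, "test": "chi2", "statistic": 0.0,
                             "p_value": 1.0, "flag": "degenerate"})
                continue
            expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.to_numpy().sum()
            if (expected == 0).any():
                warnings.warn(f"zero expected count for confounder {name}; test skipped")
                rows.append({"confounder": name, "test": "chi2", "statistic": np.nan,
                             "p_value": np.nan, "flag": "zero_expected_cell"})
                continue
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            rows.append({"confounder": name, "test": "chi2", "statistic": float(chi2),
                         "p_value": float(p), "flag": ""})
    return pd.DataFrame(rows)
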