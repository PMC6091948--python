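"""Mendelian-randomization orchestration.

A genetic pigmentation score (GPS) is a valid instrument for phototype when
(1) it is associated with the phototype traits in controls, (2) it is
independent of the confounders of the phototype-cancer relationship, and
(3) it affects cancer only through phototype. Criterion 1 is tested with
multinomial trait-on-GPS models, criterion 2 with chi-square/ANOVA scans of
risk factors across GPS quartiles, and criterion 3 with MR-Egger regression:
per-SNP cancer associations regressed on per-SNP trait associations, weighted
by inverse outcome variance, whose intercept estimates average directional
pleiotropy and whose slope estimates the causal phototype effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import SnpPanel, assign_quartiles, oriented_dosages
from .models import (
    FitError,
    ModelComparison,
    compare_nested,
    confounder_tests,
    fit_logistic,
    fit_multinomial,
    weighted_least_squares,
)

__all__ = [
    "EggerResult",
    "Criterion1Trait",
    "CriteriaReport",
    "criterion1",
    "criterion2",
    "per_snp_summary",
    "mr_egger",
    "gps_cancer",
    "phototype_cancer",
]


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger fit: alpha = intercept (average directional pleiotropy, the
    bias MR would incur), beta = slope (causal effect of the phototype trait
    on cancer per trait-category step)."""

    alpha: float
    se_alpha: float
    p_alpha: float
    beta: float
    se_beta: float
    p_beta: float
    n_snps: int
    trait: str = ""
    cancer_type: str = ""


@dataclass
class Criterion1Trait:
    trait: str
    comparison: ModelComparison
    rrr_per_unit: pd.DataFrame
    rrr_by_quartile: pd.DataFrame | None = None


@dataclass
class CriteriaReport:
    criterion1: dict[str, Criterion1Trait]
    criterion2: pd.DataFrame
    criterion3: dict[str, EggerResult]
    alpha_level: float = 0.05

    @property
    def criterion1_pass(self) -> bool:
        return all(t.comparison.p_value < self.alpha_level for t in self.criterion1.values())

    @property
    def criterion2_pass(self) -> bool:
        tab = self.criterion2
        m = int((~tab["p_value"].isna()).sum())
        if m == 0:
            return True
        return bool((tab["p_value"].dropna() >= self.alpha_level / m).all())

    @property
    def criterion3_pass(self) -> bool:
        # Bonferroni across the per-trait Egger intercepts, like criterion 2
        m = max(len(self.criterion3), 1)
        return all(e.p_alpha >= self.alpha_level / m for e in self.criterion3.values())

    def flags(self) -> dict[str, bool]:
        return {
            "criterion1_pass": self.criterion1_pass,
            "criterion2_pass": self.criterion2_pass,
            "criterion3_pass": self.criterion3_pass,
        }


def criterion1(
    gps: pd.Series,
    traits: pd.DataFrame,
    propensity: pd.Series,
    quartiles: pd.Series | None = None,
) -> dict[str, Criterion1Trait]:
    """GPS-phototype association in controls (all inputs already controls-only).

    Per trait: multinomial model of trait on GPS + propensity score versus
    propensity score alone; reports RRR per GPS unit for each non-reference
    (lighter) category, the likelihood-ratio chi-square, F = chi2/(k-1), its
    p-value and the McFadden delta-R^2; optionally repeats with GPS quartiles
    (Q1 reference) for the dose-response pattern.
    """
    if gps.dropna().nunique() < 2:
        raise ValueError("GPS is degenerate (constant); criterion 1 undefined")
    out: dict[str, Criterion1Trait] = {}
    base = pd.DataFrame({"gps": gps, "propensity": propensity})
    for trait in traits.columns:
        y = traits[trait]
        ok = ~(base.isna().any(axis=1) | y.isna())
        k = y.cat.categories.size if isinstance(y.dtype, pd.CategoricalDtype) else y.nunique()
        full = fit_multinomial(y[ok], base[ok])
        reduced = fit_multinomial(y[ok], base.loc[ok, ["propensity"]])
        df_diff = k - 1  # one GPS coefficient per non-reference category
        comp = compare_nested(full.llf, reduced.llf, df_diff, k, reduced.llnull)
        rrr = full.rrr_table("gps")
        rrr.insert(0, "trait", trait)
        block = Criterion1Trait(trait=trait, comparison=comp, rrr_per_unit=rrr)
        if quartiles is not None:
            qd = pd.get_dummies(quartiles[ok].astype("Int64"), prefix="q", dtype=float)
            qd = qd.drop(columns=qd.columns[0])  # Q1 reference
            qd["propensity"] = propensity[ok]
            qfit = fit_multinomial(y[ok], qd)
            qrows = []
            for term in [c for c in qd.columns if c.startswith("q_")]:
                t = qfit.rrr_table(term)
                t.insert(0, "trait", trait)
                qrows.append(t)
            block.rrr_by_quartile = pd.concat(qrows, ignore_index=True)
        out[trait] = block
    return out


def criterion2(
    quartiles: pd.Series,
    risk_factors: pd.DataFrame,
    types: dict[str, str] | None = None,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> tuple[pd.DataFrame, bool]:
    """GPS independence from cancer risk factors, in controls.

    Runs the chi-square/ANOVA scan over the risk-factor list and applies a
    Bonferroni family rule at level ``alpha`` (configurable off). Returns the
    per-factor table and the overall pass flag.
    """
    if risk_factors.shape[1] == 0:
        raise ValueError("risk-factor list is empty")
    tab = confounder_tests(quartiles, risk_factors, types)
    m = int((~tab["p_value"].isna()).sum())
    cut = alpha / m if (bonferroni and m) else alpha
    passed = bool((tab["p_value"].dropna() >= cut).all())
    tab["significant"] = tab["p_value"] < cut
    return tab, passed


def per_snp_summary(
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    trait: pd.Series,
    outcome: pd.Series,
    propensity: pd.Series,
    controls_mask: pd.Series,
) -> pd.DataFrame:
    """Per-SNP summary statistics for MR-Egger.

    beta_exposure: ordinal-as-linear regression of the trait category index on
    oriented dosage, in controls. beta_outcome: per-SNP logistic log-OR of
    case status on oriented dosage, adjusted for the propensity score. SNPs
    failing either fit (e.g. monomorphic) are dropped with a warning.
    """
    od = oriented_dosages(genotypes, panel)
    tidx = (
        trait.cat.codes.astype(float).replace(-1, np.nan)
        if isinstance(trait.dtype, pd.CategoricalDtype)
        else trait.astype(float)
    )
    rows = []
    for snp in od.columns:
        d = od[snp]
        try:
            ok = controls_mask & ~(d.isna() | tidx.isna())
            x = d[ok].to_numpy()
            y = tidx[ok].to_numpy()
            if len(x) < 3 or np.ptp(x) == 0:
                raise FitError("degenerate dosage in controls")
            exp_fit = stats.linregress(x, y)
            out_ok = ~(d.isna() | propensity.isna() | outcome.isna())
            if np.ptp(d[out_ok].to_numpy()) == 0:
                raise FitError("degenerate dosage")
            X = pd.DataFrame({"dosage": d[out_ok], "propensity": propensity[out_ok]})
            lfit = fit_logistic(outcome[out_ok], X)
            rows.append(
                {
                    "snp_id": snp,
                    "beta_exposure": float(exp_fit.slope),
                    "se_exposure": float(exp_fit.stderr),
                    "beta_outcome": float(lfit.params["dosage"]),
                    "se_outcome": float(lfit.se["dosage"]),
                }
            )
        except FitError as exc:
            warnings.warn(f"SNP {snp} dropped from summary statistics: {exc}")
    return pd.DataFrame(rows)


def mr_egger(summary: pd.DataFrame, trait: str = "", cancer_type: str = "") -> EggerResult:
    """MR-Egger regression on per-SNP summary statistics.

    Weighted least squares of beta_outcome on beta_exposure with weights
    1/se_outcome^2, after re-orienting each SNP so every beta_exposure is
    non-negative (both betas flip together; the slope is invariant, and the
    intercept's sign becomes interpretable as directional pleiotropy).
    """
    if len(summary) < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    if (summary["se_outcome"] <= 0).any():
        raise ValueError("outcome standard errors must be positive")
    sign = np.where(summary["beta_exposure"].to_numpy() < 0, -1.0, 1.0)
    x = summary["beta_exposure"].to_numpy() * sign
    y = summary["beta_outcome"].to_numpy() * sign
    w = 1.0 / summary["se_outcome"].to_numpy() ** 2
    fit = weighted_least_squares(x, y, w)
    return EggerResult(
        alpha=fit.intercept,
        se_alpha=fit.se_intercept,
        p_alpha=fit.p_intercept,
        beta=fit.slope,
        se_beta=fit.se_slope,
        p_beta=fit.p_slope,
        n_snps=len(summary),
        trait=trait,
        cancer_type=cancer_type,
    )


def _strata_spec(covariates: pd.DataFrame, cancer_type: str) -> dict[str, pd.Series]:
    age = covariates["age"]
    bmi = covariates["bmi"]
    spec = {
        "all": pd.Series(True, index=covariates.index),
        "age_lt_65": age < 65,
        "age_ge_65": age >= 65,
        "bmi_lt_25": bmi < 25,
        "bmi_ge_25": bmi >= 25,
    }
    if cancer_type == "breast" and "menopause" in covariates:
        meno = covariates["menopause"].astype(str)
        spec["premenopausal"] = meno == "pre"
        spec["postmenopausal"] = meno == "post"
    return spec


def gps_cancer(
    gps: pd.Series,
    outcome: pd.Series,
    propensity: pd.Series,
    covariates: pd.DataFrame | None = None,
    cancer_type: str = "breast",
    score_name: str = "gps",
    min_stratum: int = 20,
) -> pd.DataFrame:
    """Propensity-adjusted logistic OR per score unit, overall and by stratum
    (age <65/>=65, BMI <25/>=25, menopausal status for breast cancer).

    Strata with fewer than ``min_stratum`` subjects still get a row, flagged
    ``small_stratum``.
    """
    strata = (
        _strata_spec(covariates, cancer_type)
        if covariates is not None
        else {"all": pd.Series(True, index=gps.index)}
    )
    rows = []
    for name, mask in strata.items():
        ok = mask & ~(gps.isna() | propensity.isna() | outcome.isna())
        n_cases = int(outcome[ok].sum())
        n_controls = int((1 - outcome[ok]).sum())
        row = {
            "score": score_name,
            "stratum": name,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "warning": "small_stratum" if (n_cases + n_controls) < min_stratum else "",
        }
        try:
            fit = fit_logistic(
                outcome[ok], pd.DataFrame({"score": gps[ok], "propensity": propensity[ok]})
            )
            tab = fit.summary_table().set_index("term")
            row.update(
                estimate=tab.loc["score", "estimate"],
                ci_low=tab.loc["score", "ci_low"],
                ci_high=tab.loc["score", "ci_high"],
                p_value=tab.loc["score", "p_value"],
            )
        except (FitError, ValueError) as exc:
            row.update(estimate=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan)
            row["warning"] = (row["warning"] + f" fit_failed:{exc}").strip()
        rows.append(row)
    return pd.DataFrame(rows)


def phototype_cancer(
    traits: pd.DataFrame,
    outcome: pd.Series,
    propensity: pd.Series,
) -> pd.DataFrame:
    """Self-reported phototype vs cancer: per-trait logistic with the darkest
    category as reference, propensity-adjusted, with per-model likelihood-ratio
    chi-square, F = chi2/(k-1), p and McFadden delta-R^2.
    """
    rows = []
    for trait in traits.columns:
        y = traits[trait]
        ok = ~(y.isna() | propensity.isna() | outcome.isna())
        cats = list(y.cat.categories)
        dummies = pd.get_dummies(y[ok], prefix=trait, dtype=float)
        dummies = dummies.drop(columns=f"{trait}_{cats[0]}")
        X = dummies.copy()
        X["propensity"] = propensity[ok]
        full = fit_logistic(outcome[ok], X)
        reduced = fit_logistic(outcome[ok], pd.DataFrame({"propensity": propensity[ok]}))
        comp = compare_nested(full.llf, reduced.llf, len(cats) - 1, len(cats), reduced.llnull)
        counts_case = y[ok & (outcome == 1)].value_counts().reindex(cats).fillna(0).astype(int)
        counts_ctrl = y[ok & (outcome == 0)].value_counts().reindex(cats).fillna(0).astype(int)
        tab = full.summary_table().set_index("term")
        for ci, cat in enumerate(cats):
            term = f"{trait}_{cat}"
            ref = ci == 0
            rows.append(
                {
                    "trait": trait,
                    "category": cat,
                    "n_cases": int(counts_case[cat]),
                    "n_controls": int(counts_ctrl[cat]),
                    "estimate": 1.0 if ref else tab.loc[term, "estimate"],
                    "ci_low": np.nan if ref else tab.loc[term, "ci_low"],
                    "ci_high": np.nan if ref else tab.loc[term, "ci_high"],
                    "p_value": np.nan if ref else tab.loc[term, "p_value"],
                    "chi_square": comp.chi_square if ref else np.nan,
                    "f_stat": comp.f_stat if ref else np.nan,
                    "model_p": comp.p_value if ref else np.nan,
                    "delta_r2": comp.delta_r2 if ref else np.nan,
                }
            )
    return pd.DataFrame(rows)
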