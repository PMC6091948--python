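"""Monte-Carlo harnesses: null calibration, coverage and Egger recovery.

These drive the same package functions the pipeline uses (simulator, allele
orientation, GPS, propensity adjustment, MR-Egger) over many replicate seeds
to measure type-I error, confidence-interval coverage and estimator bias
under known truth. Replicate seeds are spawned deterministically from one
base seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import genetics, models, mr
from .simulate import SimParams, simulate_cohort

__all__ = [
    "replicate_seeds",
    "gps_cancer_replicate",
    "null_calibration",
    "egger_summary_simulation",
]


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """n distinct deterministic child seeds below 2**31."""
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def gps_cancer_replicate(params: SimParams) -> dict:
    """One pipeline pass: simulate, orient, score, adjust, test GPS-cancer.

    Returns the per-unit log-OR estimate, its Wald CI and p, so callers can
    accumulate rejection rates and CI coverage over replicates.
    """
    cohort = simulate_cohort(params)
    controls = cohort.control_mask
    panel = genetics.SnpPanel.from_ids(list(cohort.genotypes.columns))
    panel, scan = genetics.orient_alleles(
        cohort.genotypes[controls.to_numpy()], cohort.traits[controls.to_numpy()], panel
    )
    gps = genetics.build_gps(cohort.genotypes, panel)
    prop = models.fit_propensity(cohort.covariates, cohort.outcome)
    fit = models.fit_logistic(
        cohort.outcome, pd.DataFrame({"gps": gps, "propensity": prop.values})
    )
    tab = fit.summary_table().set_index("term")
    return {
        "or": float(tab.loc["gps", "estimate"]),
        "ci_low": float(tab.loc["gps", "ci_low"]),
        "ci_high": float(tab.loc["gps", "ci_high"]),
        "p": float(tab.loc["gps", "p_value"]),
    }


def null_calibration(
    base_params: SimParams, n_replicates: int, base_seed: int, alpha: float = 0.05
) -> dict:
    """Type-I error and CI coverage of the GPS-cancer Wald test under the null
    (no causal effect, no pleiotropy). Truth for coverage is OR = 1."""
    seeds = replicate_seeds(base_seed, n_replicates)
    rejections = 0
    covered = 0
    pvals = []
    for s in seeds:
        rep = gps_cancer_replicate(replace(base_params, seed=int(s)))
        rejections += rep["p"] < alpha
        covered += rep["ci_low"] <= 1.0 <= rep["ci_high"]
        pvals.append(rep["p"])
    return {
        "n_replicates": n_replicates,
        "type1_error": rejections / n_replicates,
        "ci_coverage": covered / n_replicates,
        "p_values": np.array(pvals),
    }


def criteria_null_calibration(
    n_replicates: int,
    base_seed: int,
    n_cases: int = 1000,
    n_controls: int = 1000,
) -> dict:
    """Calibration of the criterion-1 and criterion-2 tests under their nulls.

    The cohort is simulated with zero SNP-trait effects and scored with
    predetermined (+1) orientations, so the GPS is a fixed instrument with no
    real trait association and no confounder association: both criteria's
    p-values should then be uniform. (Data-driven orientation fitted on the
    same controls would add a winner's-curse selection effect; see the methods
    notes.) Returns pooled p-value arrays.
    """
    c1_pvals, c2_pvals = [], []
    for s in replicate_seeds(base_seed, n_replicates):
        params = SimParams(
            n_cases=n_cases, n_controls=n_controls,
            snp_trait_effects=np.zeros((17, 5)), seed=int(s),
        )
        cohort = simulate_cohort(params)
        controls = cohort.control_mask
        panel = genetics.SnpPanel.from_ids(list(cohort.genotypes.columns))
        panel.table["orientation"] = 1
        gps = genetics.build_gps(cohort.genotypes, panel)
        quart = genetics.assign_quartiles(gps, controls)
        prop = models.fit_propensity(cohort.covariates, cohort.outcome)
        c1 = mr.criterion1(
            gps[controls], cohort.traits[controls.to_numpy()], prop.values[controls]
        )
        c1_pvals.extend(b.comparison.p_value for b in c1.values())
        risk = cohort.covariates.loc[controls.to_numpy(), ["age", "bmi", "smoking", "education"]]
        tab, _ = mr.criterion2(quart[controls], risk)
        c2_pvals.extend(tab["p_value"].dropna().tolist())
    return {
        "criterion1_p": np.array(c1_pvals),
        "criterion2_p": np.array(c2_pvals),
        "n_replicates": n_replicates,
    }


def egger_summary_simulation(
    n_replicates: int,
    base_seed: int,
    n_snps: int = 17,
    causal_slope: float = 0.1,
    pleiotropy: float = 0.0,
    se_outcome: float = 0.05,
    se_range: tuple[float, float] = (0.1, 0.5),
) -> pd.DataFrame:
    """Summary-level MR-Egger recovery experiment.

    Per replicate: draw per-SNP exposure effects, set the true per-SNP outcome
    effect to ``causal_slope * beta_exposure + pleiotropy`` and observe it
    with Gaussian noise at the per-SNP outcome SE; fit MR-Egger and record
    alpha and beta. Unbiasedness holds when mean(alpha) ~= pleiotropy and
    mean(beta) ~= causal_slope.
    """
    rows = []
    for s in replicate_seeds(base_seed, n_replicates):
        rng = np.random.default_rng(int(s))
        beta_exp = rng.uniform(se_range[0], se_range[1], n_snps) * rng.choice(
            [-1.0, 1.0], n_snps
        )
        se_out = np.full(n_snps, se_outcome)
        true_out = causal_slope * beta_exp + pleiotropy * np.sign(beta_exp)
        beta_out = true_out + rng.normal(0.0, se_out)
        summ = pd.DataFrame(
            {
                "snp_id": [f"snp{i}" for i in range(n_snps)],
                "beta_exposure": beta_exp,
                "se_exposure": np.full(n_snps, 0.01),
                "beta_outcome": beta_out,
                "se_outcome": se_out,
            }
        )
        res = mr.mr_egger(summ)
        rows.append({"alpha": res.alpha, "beta": res.beta,
                     "p_alpha": res.p_alpha, "p_beta": res.p_beta})
    return pd.DataFrame(rows)
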