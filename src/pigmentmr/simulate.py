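"""Synthetic case-control cohorts with the structure the phototype MR analysis assumes.

The generator mirrors a Spanish multicentre case-control design: ~17 biallelic
pigmentation SNPs, five ordered phototype traits driven by those SNPs through a
cumulative-logit (proportional-odds) model, a configurable trait->cancer causal
effect, configurable direct SNP->cancer (pleiotropic) effects, shared
confounders (age, BMI, smoking, education, recruitment centre, ancestry PCs),
and controls frequency-matched to cases on (centre, 5-year age band).

Trait categories are ordered darkest -> lightest throughout; a positive
SNP-trait effect pushes carriers of the effect allele toward the lighter end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitDef",
    "SimParams",
    "CohortTable",
    "MatchingError",
    "default_trait_defs",
    "default_panel_ids",
    "default_params",
    "simulate_cohort",
    "matched_control_check",
]

# Canonical phototype traits (Fitzpatrick-style), darkest category first.
TRAIT_NAMES = ("hair", "skin", "eye", "freckles", "tanning")

_TRAIT_CATEGORIES = {
    "hair": ("dark", "light_brown", "blonde"),
    "skin": ("dark", "light_brown", "fair"),
    "eye": ("dark", "light_green", "blue_grey"),
    "freckles": ("no", "yes"),
    "tanning": ("tan_no_burn", "rarely_burn", "burn_then_tan", "burn_no_tan"),
}

# Baseline category probabilities for controls (darkest -> lightest).
_TRAIT_BASELINES = {
    "hair": (0.787, 0.128, 0.085),
    "skin": (0.158, 0.380, 0.462),
    "eye": (0.507, 0.342, 0.151),
    "freckles": (0.744, 0.256),
    "tanning": (0.390, 0.197, 0.242, 0.171),
}

# rs identifiers of well-known pigmentation loci, used as default panel labels.
_DEFAULT_SNP_IDS = (
    "rs1805007", "rs1805008", "rs1042602", "rs1126809", "rs12913832",
    "rs16891982", "rs1800407", "rs12203592", "rs1015362", "rs4911414",
    "rs12896399", "rs1393350", "rs35264875", "rs1540771", "rs1805005",
    "rs2378249", "rs683",
)

_DEFAULT_FREQS = (
    0.12, 0.10, 0.29, 0.26, 0.72, 0.75, 0.11, 0.17, 0.33, 0.36,
    0.42, 0.25, 0.22, 0.31, 0.15, 0.13, 0.18,
)

_CENTRES = ("madrid", "barcelona", "cantabria", "navarra", "valencia")
_CENTRE_PROBS = (0.25, 0.22, 0.20, 0.18, 0.15)
_SMOKING = ("never", "former", "current")
_SMOKING_PROBS = (0.45, 0.30, 0.25)
_EDUCATION = ("less_than_primary", "primary", "secondary", "university")
_EDUCATION_PROBS = (0.20, 0.35, 0.30, 0.15)


class MatchingError(RuntimeError):
    """Raised when a (centre, age-band) matching cell cannot be filled."""


@dataclass(frozen=True)
class TraitDef:
    """One ordered phototype trait: name, categories darkest->lightest, baseline probs."""

    name: str
    categories: tuple[str, ...]
    baseline_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.baseline_probs):
            raise ValueError(f"{self.name}: categories/probs length mismatch")
        if len(self.categories) < 2:
            raise ValueError(f"{self.name}: needs >=2 ordered categories")
        p = np.asarray(self.baseline_probs, dtype=float)
        if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: baseline probabilities must be positive and sum to 1")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def cutpoints(self) -> np.ndarray:
        """Cumulative-logit thresholds reproducing the baseline marginals at eta=0."""
        cum = np.cumsum(self.baseline_probs)[:-1]
        return np.log(cum / (1.0 - cum))


def default_trait_defs() -> list[TraitDef]:
    return [
        TraitDef(name, _TRAIT_CATEGORIES[name], _TRAIT_BASELINES[name])
        for name in TRAIT_NAMES
    ]


def default_panel_ids(m_snps: int = 17) -> list[str]:
    if m_snps <= len(_DEFAULT_SNP_IDS):
        return list(_DEFAULT_SNP_IDS[:m_snps])
    extra = [f"rs9{900000 + i}" for i in range(m_snps - len(_DEFAULT_SNP_IDS))]
    return list(_DEFAULT_SNP_IDS) + extra


@dataclass
class SimParams:
    """Generative parameters for one synthetic case-control cohort.

    ``snp_trait_effects`` is the (SNP x trait) matrix of per-effect-allele
    log-odds on the lighter direction of each trait; ``causal_log_or`` is the
    per-category-step log-odds of each trait on cancer (0 = no causal effect);
    ``pleiotropy_log_or`` gives each SNP a direct log-odds on cancer that
    bypasses the traits (the exclusion-restriction violation MR-Egger probes).
    """

    n_cases: int = 2000
    n_controls: int = 2000
    m_snps: int = 17
    effect_allele_freqs: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_FREQS))
    snp_trait_effects: np.ndarray | None = None
    trait_defs: list[TraitDef] = field(default_factory=default_trait_defs)
    causal_log_or: float | np.ndarray = 0.0
    pleiotropy_log_or: np.ndarray | None = None
    confounders_on_cancer: dict[str, float] = field(default_factory=lambda: dict(_CONF_CANCER))
    confounders_on_traits: dict[str, float] = field(default_factory=lambda: dict(_CONF_TRAITS))
    cancer_type: str = "breast"
    match_band_years: int = 5
    missing_rate: float = 0.0
    pool_case_fraction: float = 0.45
    snp_ids: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_allele_freqs = np.asarray(self.effect_allele_freqs, dtype=float)
        if self.effect_allele_freqs.size != self.m_snps:
            raise ValueError("effect_allele_freqs length must equal m_snps")
        if ((self.effect_allele_freqs <= 0) | (self.effect_allele_freqs >= 1)).any():
            raise ValueError("effect allele frequencies must lie strictly in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        n_traits = len(self.trait_defs)
        if self.snp_trait_effects is None:
            self.snp_trait_effects = _default_effect_matrix(self.m_snps, n_traits)
        self.snp_trait_effects = np.asarray(self.snp_trait_effects, dtype=float)
        if self.snp_trait_effects.shape != (self.m_snps, n_traits):
            raise ValueError("snp_trait_effects must have shape (m_snps, n_traits)")
        if self.pleiotropy_log_or is None:
            self.pleiotropy_log_or = np.zeros(self.m_snps)
        self.pleiotropy_log_or = np.asarray(self.pleiotropy_log_or, dtype=float)
        if self.pleiotropy_log_or.size != self.m_snps:
            raise ValueError("pleiotropy_log_or length must equal m_snps")
        self.causal_log_or = np.broadcast_to(
            np.asarray(self.causal_log_or, dtype=float), (n_traits,)
        ).copy()
        if self.cancer_type not in ("breast", "prostate"):
            raise ValueError("cancer_type must be 'breast' or 'prostate'")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.match_band_years < 1:
            raise ValueError("match_band_years must be >= 1")
        if self.snp_ids is None:
            self.snp_ids = default_panel_ids(self.m_snps)
        if len(self.snp_ids) != self.m_snps:
            raise ValueError("snp_ids length must equal m_snps")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.trait_defs]


# Modest default confounding: age/BMI/smoking/education/centre shift cancer
# risk; centre and ancestry (PC1) shift phototype. Genotypes stay independent
# of every confounder, as Mendelian randomization assumes.
_CONF_CANCER = {
    "age": 0.020, "bmi": 0.020, "smoking_former": 0.10, "smoking_current": 0.25,
    "education": -0.08, "centre": 0.05, "pc1": 0.0, "pc2": 0.0, "pc3": 0.0,
}
_CONF_TRAITS = {
    "age": 0.0, "bmi": 0.0, "smoking_former": 0.0, "smoking_current": 0.0,
    "education": 0.0, "centre": 0.08, "pc1": 0.15, "pc2": 0.0, "pc3": 0.0,
}


def _default_effect_matrix(
    m_snps: int, n_traits: int, primary: float = 0.4, secondary: float = 0.15
) -> np.ndarray:
    """Round-robin assignment: SNP j mainly raises the lighter direction of
    trait j mod n_traits, with a weaker effect on the next trait — pigmentation
    loci typically act on several pigmentation traits at once."""
    mat = np.zeros((m_snps, n_traits))
    for j in range(m_snps):
        mat[j, j % n_traits] = primary
        mat[j, (j + 1) % n_traits] = secondary
    return mat


def default_params(**overrides) -> SimParams:
    """The default study conditions: 2000+2000 subjects, 17 SNPs, per-allele
    trait effects 0.12, no causal trait->cancer effect, no pleiotropy."""
    return SimParams(**overrides)


@dataclass
class CohortTable:
    """One simulated (or loaded) cohort.

    genotypes: subject x SNP effect-allele dosages, float 0/1/2 with NaN missing.
    traits: ordered categoricals, one column per phototype trait.
    covariates: age, bmi, smoking, education, centre, pc1-pc3, menopause.
    outcome: int8 Series, 1 = case, 0 = control.
    """

    genotypes: pd.DataFrame
    traits: pd.DataFrame
    covariates: pd.DataFrame
    outcome: pd.Series
    cancer_type: str = "breast"

    def __post_init__(self) -> None:
        idx = self.genotypes.index
        for part in (self.traits, self.covariates):
            if not part.index.equals(idx):
                raise ValueError("cohort tables must share one subject index")
        if not self.outcome.index.equals(idx):
            raise ValueError("outcome index mismatch")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def case_mask(self) -> pd.Series:
        return self.outcome == 1

    @property
    def control_mask(self) -> pd.Series:
        return self.outcome == 0

    def trait_indices(self) -> pd.DataFrame:
        """Ordered category index (0 = darkest) per trait; NaN where missing."""
        out = {}
        for name in self.traits.columns:
            out[name] = self.traits[name].cat.codes.astype(float).replace(-1, np.nan)
        return pd.DataFrame(out, index=self.traits.index)

    def validate(self) -> None:
        g = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid dosage at subject {self.genotypes.index[bad[0]]}, "
                f"SNP {self.genotypes.columns[bad[1]]}"
            )
        if (self.covariates["age"] <= 0).any():
            raise ValueError("ages must be positive")
        if not set(self.outcome.unique()) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 59.0, 13.0, 20.0, 85.0


def _draw_ages(rng: np.random.Generator, n: int, lo: float = _AGE_LO, hi: float = _AGE_HI):
    # truncated normal: recruitment window (or one matching band) with no point mass
    return stats.truncnorm.rvs(
        (lo - _AGE_MEAN) / _AGE_SD, (hi - _AGE_MEAN) / _AGE_SD,
        loc=_AGE_MEAN, scale=_AGE_SD, size=n, random_state=rng,
    )


def _draw_covariates(
    rng: np.random.Generator,
    n: int,
    cancer_type: str,
    age: np.ndarray | None = None,
    centre: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covariate draw; ``age``/``centre`` may be fixed for stratified sampling."""
    if age is None:
        age = _draw_ages(rng, n)
    bmi = np.clip(rng.normal(26.5, 4.2, n), 16.0, 48.0)
    smoking = rng.choice(len(_SMOKING), size=n, p=_SMOKING_PROBS)
    education = rng.choice(len(_EDUCATION), size=n, p=_EDUCATION_PROBS)
    if centre is None:
        centre = rng.choice(len(_CENTRES), size=n, p=_CENTRE_PROBS)
    pcs = rng.normal(0.0, 1.0, (n, 3))
    cov = pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "smoking": pd.Categorical.from_codes(smoking, categories=list(_SMOKING)),
            "education": pd.Categorical.from_codes(
                education, categories=list(_EDUCATION), ordered=True
            ),
            "centre": pd.Categorical.from_codes(centre, categories=list(_CENTRES)),
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
        }
    )
    if cancer_type == "breast":
        post = (age >= 51.0) ^ (rng.random(n) < 0.05)
        cov["menopause"] = pd.Categorical.from_codes(
            post.astype(int), categories=["pre", "post"]
        )
    else:
        cov["menopause"] = pd.Categorical(
            [None] * n, categories=["pre", "post"]
        )
    return cov


def _confounder_lp(cov: pd.DataFrame, eff: dict[str, float]) -> np.ndarray:
    """Linear predictor contribution of the shared confounders (centred scales)."""
    smoking = cov["smoking"].cat.codes.to_numpy()
    centre = cov["centre"].cat.codes.to_numpy()
    # centre enters as a symmetric gradient across centres so its mean is ~0
    centre_grad = centre - (len(_CENTRES) - 1) / 2.0
    lp = (
        eff["age"] * (cov["age"].to_numpy() - 59.0)
        + eff["bmi"] * (cov["bmi"].to_numpy() - 26.5)
        + eff["smoking_former"] * (smoking == 1)
        + eff["smoking_current"] * (smoking == 2)
        + eff["education"] * (cov["education"].cat.codes.to_numpy() - 1.5)
        + eff["centre"] * centre_grad
        + eff["pc1"] * cov["pc1"].to_numpy()
        + eff["pc2"] * cov["pc2"].to_numpy()
        + eff["pc3"] * cov["pc3"].to_numpy()
    )
    return lp


def _lp_offset(params: SimParams) -> float:
    """Approximate population mean of the cancer linear predictor, so the pool
    case fraction stays near ``pool_case_fraction`` regardless of effects."""
    mean_idx = np.array(
        [float(np.arange(t.n_categories) @ np.asarray(t.baseline_probs)) for t in params.trait_defs]
    )
    eff = params.confounders_on_cancer
    conf_mean = (
        eff["smoking_former"] * _SMOKING_PROBS[1]
        + eff["smoking_current"] * _SMOKING_PROBS[2]
        + eff["education"] * (np.arange(4) @ np.asarray(_EDUCATION_PROBS) - 1.5)
        + eff["centre"]
        * ((np.arange(len(_CENTRES)) - (len(_CENTRES) - 1) / 2.0) @ np.asarray(_CENTRE_PROBS))
    )
    return float(
        params.causal_log_or @ mean_idx
        + params.pleiotropy_log_or @ (2.0 * params.effect_allele_freqs)
        + conf_mean
    )


def _draw_batch(
    rng: np.random.Generator,
    n: int,
    params: SimParams,
    age: np.ndarray | None = None,
    centre: np.ndarray | None = None,
) -> tuple:
    """Draw n subjects: genotypes, trait indices, covariates, case indicator."""
    geno = rng.binomial(2, params.effect_allele_freqs, size=(n, params.m_snps)).astype(float)
    cov = _draw_covariates(rng, n, params.cancer_type, age=age, centre=centre)
    conf_trait = _confounder_lp(cov, params.confounders_on_traits)
    eta = geno @ params.snp_trait_effects  # n x n_traits, lighter direction
    trait_idx = np.empty((n, len(params.trait_defs)), dtype=np.int64)
    for t, tdef in enumerate(params.trait_defs):
        theta = tdef.cutpoints()
        u = rng.random(n)
        lin = eta[:, t] + conf_trait
        # P(Y <= c) = sigmoid(theta_c - lin); category = #thresholds passed
        cum = _sigmoid(theta[None, :] - lin[:, None])
        trait_idx[:, t] = (u[:, None] > cum).sum(axis=1)
    lp = (
        trait_idx @ params.causal_log_or
        + geno @ params.pleiotropy_log_or
        + _confounder_lp(cov, params.confounders_on_cancer)
    )
    base = np.log(params.pool_case_fraction / (1.0 - params.pool_case_fraction))
    p_case = _sigmoid(base + lp - _lp_offset(params))
    case = rng.random(n) < p_case
    return geno, trait_idx, cov, case


def _age_band(age: np.ndarray, width: int) -> np.ndarray:
    return (np.asarray(age) // width).astype(int)


def simulate_cohort(params: SimParams, max_match_draws: int = 10_000) -> CohortTable:
    """Simulate a frequency-matched case-control cohort.

    Subjects are drawn from the generative model until ``n_cases`` cases
    accrue; controls are then sampled stratified on (centre, age band) so the
    control distribution over matching cells equals the cases'. Raises
    :class:`MatchingError` naming the first cell that cannot be filled within
    ``max_match_draws`` additional candidate draws. Fully reproducible from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n_traits = len(params.trait_defs)
    width = params.match_band_years

    genos, traits, covs, cases = [], [], [], []
    n_case_acc = 0
    pool_target = int(
        max(params.n_cases / max(params.pool_case_fraction - 0.05, 0.05),
            params.n_controls / max(0.95 - params.pool_case_fraction, 0.05))
        * 1.3
    ) + 200
    drawn = 0
    while n_case_acc < params.n_cases:
        batch = min(pool_target, 20_000)
        g, t, c, is_case = _draw_batch(rng, batch, params)
        genos.append(g); traits.append(t); covs.append(c); cases.append(is_case)
        n_case_acc += int(is_case.sum())
        drawn += batch
        if drawn > 50 * pool_target:
            raise MatchingError("could not accrue the requested number of cases")

    geno = np.concatenate(genos)
    trait_idx = np.concatenate(traits)
    cov = pd.concat(covs, ignore_index=True)
    case = np.concatenate(cases)

    case_pos = np.flatnonzero(case)[: params.n_cases]
    ctrl_pool = np.flatnonzero(~case)

    bands = _age_band(cov["age"].to_numpy(), width)
    centres = cov["centre"].cat.codes.to_numpy().astype(np.int64)
    cell_key = centres * 1000 + bands

    case_cells, case_counts = np.unique(cell_key[case_pos], return_counts=True)
    # largest-remainder apportionment of n_controls across the case cells
    quota = params.n_controls * case_counts / params.n_cases
    want = np.floor(quota).astype(int)
    rem = params.n_controls - want.sum()
    order = np.argsort(-(quota - want), kind="stable")
    want[order[:rem]] += 1

    ctrl_sel: list[np.ndarray] = []
    attempts = np.zeros(len(case_cells), dtype=int)
    pool_by_cell = {k: ctrl_pool[cell_key[ctrl_pool] == k] for k in case_cells}
    unfilled = [i for i in range(len(case_cells)) if want[i] > 0]
    for i in list(unfilled):
        have = pool_by_cell[case_cells[i]]
        if len(have) >= want[i]:
            ctrl_sel.append(have[: want[i]])
            unfilled.remove(i)
    # fill remaining deficits by targeted stratified draws: candidate subjects
    # conditioned on the cell's centre and age band, kept when they turn out
    # to be controls (this is exactly stratified control sampling)
    extra_geno, extra_traits, extra_covs = [], [], []
    n_extra = 0
    for i in list(unfilled):
        cell = case_cells[i]
        centre_code, band = int(cell // 1000), int(cell % 1000)
        lo = max(band * width, _AGE_LO)
        hi = min(band * width + width, _AGE_HI)
        if lo >= hi:
            raise MatchingError(
                f"cannot fill matching cell (centre={_CENTRES[centre_code]}, "
                f"age_band=[{band * width},{band * width + width})): "
                "band lies outside the recruitment age window"
            )
        while len(pool_by_cell[cell]) < want[i]:
            if attempts[i] >= max_match_draws:
                raise MatchingError(
                    f"cannot fill matching cell (centre={_CENTRES[centre_code]}, "
                    f"age_band=[{band * width},{band * width + width})) "
                    f"after {attempts[i]} candidate draws"
                )
            batch = int(min(max(2 * (want[i] - len(pool_by_cell[cell])), 50),
                            max_match_draws - attempts[i]))
            ages = _draw_ages(rng, batch, lo, hi)
            centres_fixed = np.full(batch, centre_code)
            g, t, c, is_case = _draw_batch(rng, batch, params, age=ages, centre=centres_fixed)
            keep = np.flatnonzero(~is_case) + len(geno) + n_extra
            pool_by_cell[cell] = np.concatenate([pool_by_cell[cell], keep])
            attempts[i] += batch
            extra_geno.append(g); extra_traits.append(t); extra_covs.append(c)
            n_extra += batch
        ctrl_sel.append(pool_by_cell[cell][: want[i]])
        unfilled.remove(i)
    if extra_geno:
        geno = np.concatenate([geno] + extra_geno)
        trait_idx = np.concatenate([trait_idx] + extra_traits)
        cov = pd.concat([cov] + extra_covs, ignore_index=True)

    ctrl_pos = np.concatenate(ctrl_sel) if ctrl_sel else np.array([], dtype=int)
    sel = np.concatenate([case_pos, ctrl_pos])
    outcome = np.concatenate(
        [np.ones(len(case_pos), dtype=np.int8), np.zeros(len(ctrl_pos), dtype=np.int8)]
    )

    geno = geno[sel]
    if params.missing_rate > 0:
        mask = rng.random(geno.shape) < params.missing_rate
        geno = geno.copy()
        geno[mask] = np.nan

    ids = pd.Index([f"S{i:06d}" for i in range(len(sel))], name="subject_id")
    genotypes = pd.DataFrame(geno, index=ids, columns=list(params.snp_ids))
    trait_cols = {}
    for t, tdef in enumerate(params.trait_defs):
        trait_cols[tdef.name] = pd.Categorical.from_codes(
            trait_idx[sel, t], categories=list(tdef.categories), ordered=True
        )
    traits_df = pd.DataFrame(trait_cols, index=ids)
    cov_df = cov.iloc[sel].reset_index(drop=True)
    cov_df.index = ids
    outcome_s = pd.Series(outcome, index=ids, name="outcome")
    return CohortTable(genotypes, traits_df, cov_df, outcome_s, params.cancer_type)


def matched_control_check(
    cohort: CohortTable, band: int = 5, tol: float = 0.10
) -> pd.DataFrame:
    """Per-(centre, age-band) case/control counts and a matching flag.

    A cell is ``matched`` when its control/case ratio lies within ``tol``
    (relative) of the cohort-wide control/case ratio. Cells with cases but no
    controls are always flagged.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    centre = cohort.covariates["centre"].astype(str)
    bands = _age_band(cohort.covariates["age"].to_numpy(), band)
    df = pd.DataFrame(
        {"centre": centre.to_numpy(), "age_band": bands, "case": cohort.outcome.to_numpy()}
    )
    tab = (
        df.groupby(["centre", "age_band"], observed=True)["case"]
        .agg(n_cases="sum", n_total="count")
        .reset_index()
    )
    tab["n_controls"] = tab["n_total"] - tab["n_cases"]
    tab = tab.drop(columns="n_total")
    total_cases = int(tab["n_cases"].sum())
    total_controls = int(tab["n_controls"].sum())
    global_ratio = total_controls / max(total_cases, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tab["n_controls"] / tab["n_cases"]
    tab["ratio"] = ratio
    rel = np.abs(ratio - global_ratio) / global_ratio if global_ratio > 0 else np.inf
    tab["matched"] = (tab["n_cases"] == 0) | ((rel <= tol) & np.isfinite(ratio))
    return tab
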