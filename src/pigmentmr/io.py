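"""Cohort file formats, run configuration and pipeline orchestration.

All tables are UTF-8 TSV with a header row and ``NA`` as the missing token.
A cohort is three files: ``genotypes.tsv`` (subject x SNP dosages 0/1/2/NA),
``phenotypes.tsv`` (the five ordered phototype traits plus covariates) and
``outcome.tsv`` (case/control status and cancer type). ``run_pipeline``
executes the full analysis: QC -> scores -> MR criteria 1-3 -> association
tables, writing every result as TSV plus a machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetics, mr, models
from .simulate import (
    _CENTRES,
    _EDUCATION,
    _SMOKING,
    _TRAIT_CATEGORIES,
    CohortTable,
    SimParams,
    simulate_cohort,
)

__all__ = [
    "CohortValidationError",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "descriptive_table",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger("pigmentmr")

NA = "NA"
_FLOAT_FMT = "%.10g"

_COVARIATE_CATEGORIES = {
    "smoking": list(_SMOKING),
    "education": list(_EDUCATION),
    "centre": list(_CENTRES),
    "menopause": ["pre", "post"],
}


class CohortValidationError(ValueError):
    """All input-validation failures, aggregated into one report."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        msg = f"{len(problems)} validation problem(s):\n" + "\n".join(
            f"  - {p}" for p in problems[:50]
        )
        super().__init__(msg)


def write_cohort(cohort: CohortTable, outdir) -> dict[str, Path]:
    """Write genotypes/phenotypes/outcome TSVs; returns the three paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "outcome": outdir / "outcome.tsv",
    }
    geno = cohort.genotypes.astype("Int64")  # nullable ints keep the NA token clean
    geno.to_csv(paths["genotypes"], sep="\t", na_rep=NA)
    pheno = pd.concat([cohort.traits, cohort.covariates], axis=1)
    pheno.to_csv(paths["phenotypes"], sep="\t", na_rep=NA, float_format=_FLOAT_FMT)
    out = pd.DataFrame(
        {
            "outcome": np.where(cohort.outcome == 1, "case", "control"),
            "cancer_type": cohort.cancer_type,
        },
        index=cohort.outcome.index,
    )
    out.to_csv(paths["outcome"], sep="\t", na_rep=NA)
    return paths


def read_cohort(
    genotypes_path,
    phenotypes_path,
    outcome_path,
    trait_categories: dict[str, list[str]] | None = None,
) -> CohortTable:
    """Read and validate the three cohort TSVs.

    Validation problems (bad dosage values, unknown trait/covariate category
    labels, subject-ID mismatches between files) are aggregated and raised
    together as one :class:`CohortValidationError`.
    """
    trait_categories = trait_categories or {
        k: list(v) for k, v in _TRAIT_CATEGORIES.items()
    }
    problems: list[str] = []
    geno = pd.read_csv(genotypes_path, sep="\t", index_col="subject_id", na_values=[NA])
    pheno = pd.read_csv(phenotypes_path, sep="\t", index_col="subject_id", na_values=[NA])
    out = pd.read_csv(outcome_path, sep="\t", index_col="subject_id", na_values=[NA])

    for name, other in (("phenotypes", pheno), ("outcome", out)):
        missing = geno.index.difference(other.index)
        extra = other.index.difference(geno.index)
        for s in missing[:10]:
            problems.append(f"subject {s} present in genotypes but absent in {name}")
        for s in extra[:10]:
            problems.append(f"subject {s} present in {name} but absent in genotypes")

    g = geno.apply(pd.to_numeric, errors="coerce")
    bad = (~g.isna()) & ~g.isin([0, 1, 2])
    coerce_fail = g.isna() & ~geno.isna()
    for mask, why in ((bad, "dosage outside {0,1,2}"), (coerce_fail, "non-numeric dosage")):
        if mask.to_numpy().any():
            for subj, snp in zip(*np.nonzero(mask.to_numpy())):
                problems.append(
                    f"{why} at subject {geno.index[subj]}, SNP {geno.columns[snp]}: "
                    f"{geno.iloc[subj, snp]!r}"
                )
                if len(problems) > 200:
                    break

    trait_cols = {}
    for trait, cats in trait_categories.items():
        if trait not in pheno.columns:
            problems.append(f"phenotype file missing trait column {trait!r}")
            continue
        col = pheno[trait]
        unknown = col.dropna()[~col.dropna().isin(cats)]
        for subj, val in unknown.head(10).items():
            problems.append(f"unknown {trait} category {val!r} for subject {subj}")
        trait_cols[trait] = pd.Categorical(col, categories=cats, ordered=True)

    cov_cols = {}
    for name in ("age", "bmi", "pc1", "pc2", "pc3"):
        if name in pheno.columns:
            cov_cols[name] = pd.to_numeric(pheno[name], errors="coerce")
        else:
            problems.append(f"phenotype file missing covariate column {name!r}")
    for name, cats in _COVARIATE_CATEGORIES.items():
        if name not in pheno.columns:
            problems.append(f"phenotype file missing covariate column {name!r}")
            continue
        col = pheno[name]
        unknown = col.dropna()[~col.dropna().isin(cats)]
        for subj, val in unknown.head(10).items():
            problems.append(f"unknown {name} category {val!r} for subject {subj}")
        ordered = name == "education"
        cov_cols[name] = pd.Categorical(col, categories=cats, ordered=ordered)

    if "outcome" in out.columns:
        unknown = out["outcome"].dropna()[~out["outcome"].dropna().isin(["case", "control"])]
        for subj, val in unknown.head(10).items():
            problems.append(f"unknown outcome label {val!r} for subject {subj}")
    else:
        problems.append("outcome file missing 'outcome' column")

    if problems:
        raise CohortValidationError(problems)

    idx = geno.index
    cancer_type = str(out["cancer_type"].iloc[0]) if "cancer_type" in out.columns else "breast"
    return CohortTable(
        genotypes=g.astype(float),
        traits=pd.DataFrame(trait_cols, index=idx),
        covariates=pd.DataFrame(cov_cols, index=idx).loc[
            :, ["age", "bmi", "smoking", "education", "centre", "pc1", "pc2", "pc3", "menopause"]
        ],
        outcome=pd.Series(
            (out.loc[idx, "outcome"] == "case").astype(np.int8), index=idx, name="outcome"
        ),
        cancer_type=cancer_type,
    )


def read_genotypes_vcf(path, panel) -> pd.DataFrame:
    """Optional VCF genotype input (requires cyvcf2).

    GT fields are converted to effect-allele dosage using the panel's
    effect/other alleles: the dosage counts effect-allele copies among the
    two called alleles (0-based allele indices; missing calls give NA).
    Variants are matched by ID to panel snp_ids; a panel SNP whose effect
    allele matches neither REF nor ALT raises an error.
    """
    from cyvcf2 import VCF

    alleles = panel.table.set_index("snp_id")[["effect_allele", "other_allele"]]
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: dict[str, np.ndarray] = {}
    for var in vcf:
        if var.ID not in alleles.index:
            continue
        eff = alleles.loc[var.ID, "effect_allele"]
        if eff == var.REF:
            eff_idx = 0
        elif var.ALT and eff == var.ALT[0]:
            eff_idx = 1
        else:
            raise ValueError(
                f"effect allele {eff!r} for {var.ID} matches neither "
                f"REF {var.REF!r} nor ALT {var.ALT!r}"
            )
        gts = np.asarray(var.genotype.array())[:, :2]
        dosage = (gts == eff_idx).sum(axis=1).astype(float)
        dosage[(gts < 0).any(axis=1)] = np.nan
        rows[var.ID] = dosage
    missing = [s for s in alleles.index if s not in rows]
    if missing:
        raise ValueError(f"panel SNPs absent from VCF: {missing}")
    out = pd.DataFrame(rows, index=pd.Index(samples, name="subject_id"))
    return out[list(alleles.index)]


def descriptive_table(
    traits: pd.DataFrame, outcome: pd.Series, decimals: int = 1
) -> pd.DataFrame:
    """Counts and percentages per phototype category among cases and controls.

    Denominators are the non-missing subjects per phenotype within each arm;
    percentages are rounded to ``decimals`` places (1 for Table-1 style, 2
    for Table-2 style outputs).
    """
    rows = []
    for trait in traits.columns:
        y = traits[trait]
        for arm, mask in (("case", outcome == 1), ("control", outcome == 0)):
            denom = int(y[mask].notna().sum())
            counts = y[mask].value_counts()
            for cat in (y.cat.categories if isinstance(y.dtype, pd.CategoricalDtype)
                        else sorted(y.dropna().unique())):
                n = int(counts.get(cat, 0))
                pct = round(100.0 * n / denom, decimals) if denom else np.nan
                rows.append(
                    {"phenotype": trait, "category": cat, "arm": arm,
                     "count": n, "percent": pct}
                )
    long = pd.DataFrame(rows)
    wide = long.pivot(
        index=["phenotype", "category"], columns="arm", values=["count", "percent"]
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    order = pd.MultiIndex.from_frame(
        long[["phenotype", "category"]].drop_duplicates()
    )  # keep declared category order
    wide = wide.loc[order]
    return wide.reset_index()[
        ["phenotype", "category", "count_case", "percent_case",
         "count_control", "percent_control"]
    ]


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of (input paths, simulation block)."""

    genotypes: str | None = None
    phenotypes: str | None = None
    outcome: str | None = None
    simulation: dict | None = None
    seed: int = 0
    outdir: str = "results"
    hwe_threshold: float = 1e-4
    ld_threshold: float = 0.8
    scan_threshold: float = 0.05
    alpha_level: float = 0.05
    traits: list[str] | None = None

    def __post_init__(self) -> None:
        has_paths = any(p is not None for p in (self.genotypes, self.phenotypes, self.outcome))
        if has_paths and self.simulation is not None:
            raise ValueError("config must give input paths OR a simulation block, not both")
        if not has_paths and self.simulation is None:
            raise ValueError("config must give input paths or a simulation block")
        if has_paths and not all((self.genotypes, self.phenotypes, self.outcome)):
            raise ValueError("all three input paths (genotypes, phenotypes, outcome) are required")
        for name in ("hwe_threshold", "ld_threshold", "scan_threshold", "alpha_level"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "genotypes": self.genotypes, "phenotypes": self.phenotypes,
            "outcome": self.outcome, "simulation": self.simulation,
            "seed": self.seed, "outdir": self.outdir,
            "hwe_threshold": self.hwe_threshold, "ld_threshold": self.ld_threshold,
            "scan_threshold": self.scan_threshold, "alpha_level": self.alpha_level,
            "traits": self.traits,
        }

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output directory is
        excluded: equal hashes must mean identical result files)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    cohort: CohortTable
    panel: genetics.SnpPanel
    scan: pd.DataFrame
    gps: pd.Series
    quartiles: pd.Series
    trait_scores: dict[str, pd.Series]
    propensity: models.PropensityScore
    criteria: mr.CriteriaReport
    gps_cancer_table: pd.DataFrame
    phototype_table: pd.DataFrame
    descriptive: pd.DataFrame
    egger_scatter: pd.DataFrame
    summary: dict


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis and (optionally) persist every result table.

    Stages: load/simulate cohort -> HWE filter -> SNP-by-SNP phototype scan
    and allele orientation -> LD pruning -> GPS, quartiles and trait-specific
    scores -> propensity score -> MR criteria 1-3 -> GPS-cancer and
    phototype-cancer association tables -> descriptive table. Determinism:
    a fixed config (hence seed) reproduces byte-identical outputs.
    """
    outdir = Path(config.outdir)
    stage = "load"
    try:
        if config.simulation is not None:
            sim = dict(config.simulation)
            sim.setdefault("seed", config.seed)
            params = SimParams(**sim)
            cohort = simulate_cohort(params)
        else:
            cohort = read_cohort(config.genotypes, config.phenotypes, config.outcome)
        cohort.validate()
        controls = cohort.control_mask
        logger.info("stage load: n=%d (%d cases)", cohort.n, int(cohort.outcome.sum()))

        stage = "qc_hwe"
        panel = genetics.SnpPanel.from_ids(list(cohort.genotypes.columns))
        panel, hwe_results = genetics.hwe_filter(
            cohort.genotypes[controls.to_numpy()], panel, config.hwe_threshold
        )

        stage = "orientation_scan"
        panel, scan = genetics.orient_alleles(
            cohort.genotypes[controls.to_numpy()], cohort.traits[controls.to_numpy()], panel
        )

        stage = "qc_ld"
        panel, ld_results = genetics.ld_prune(
            cohort.genotypes, panel, config.ld_threshold, scan
        )

        stage = "scores"
        gps = genetics.build_gps(cohort.genotypes, panel)
        quartiles = genetics.assign_quartiles(gps, controls)
        trait_names = config.traits or list(cohort.traits.columns)
        trait_scores = {}
        for trait in trait_names:
            try:
                score, members = genetics.trait_score(
                    cohort.genotypes, panel, scan, trait, config.scan_threshold
                )
                trait_scores[trait] = score
            except ValueError as exc:
                logger.warning("trait score %s skipped: %s", trait, exc)

        stage = "propensity"
        propensity = models.fit_propensity(cohort.covariates, cohort.outcome)

        stage = "criterion1"
        c1 = mr.criterion1(
            gps[controls], cohort.traits[controls.to_numpy()],
            propensity.values[controls], quartiles[controls],
        )

        stage = "criterion2"
        risk = cohort.covariates.loc[
            controls.to_numpy(), ["age", "bmi", "smoking", "education"]
        ].copy()
        if cohort.cancer_type == "breast":
            risk["menopause"] = cohort.covariates.loc[controls.to_numpy(), "menopause"]
        c2_table, _ = mr.criterion2(quartiles[controls], risk, alpha=config.alpha_level)

        stage = "criterion3"
        c3 = {}
        scatter_rows = []
        for trait in trait_names:
            stats_df = mr.per_snp_summary(
                cohort.genotypes, panel, cohort.traits[trait],
                cohort.outcome, propensity.values, controls,
            )
            if len(stats_df) >= 3:
                c3[trait] = mr.mr_egger(stats_df, trait, cohort.cancer_type)
                sd = stats_df.copy()
                sd.insert(0, "trait", trait)
                sd["weight"] = 1.0 / sd["se_outcome"] ** 2
                scatter_rows.append(sd)
        egger_scatter = (
            pd.concat(scatter_rows, ignore_index=True) if scatter_rows else pd.DataFrame()
        )
        criteria = mr.CriteriaReport(c1, c2_table, c3, config.alpha_level)

        stage = "associations"
        gps_tables = [
            mr.gps_cancer(gps, cohort.outcome, propensity.values,
                          cohort.covariates, cohort.cancer_type, "gps")
        ]
        for trait, score in trait_scores.items():
            gps_tables.append(
                mr.gps_cancer(score, cohort.outcome, propensity.values,
                              cohort.covariates, cohort.cancer_type, f"score_{trait}")
            )
        gps_cancer_table = pd.concat(gps_tables, ignore_index=True)
        phototype_table = mr.phototype_cancer(
            cohort.traits, cohort.outcome, propensity.values
        )
        descriptive = descriptive_table(cohort.traits, cohort.outcome)

        overall = gps_cancer_table[
            (gps_cancer_table["score"] == "gps") & (gps_cancer_table["stratum"] == "all")
        ].iloc[0]
        summary = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_subjects": cohort.n,
            "n_cases": int(cohort.outcome.sum()),
            "cancer_type": cohort.cancer_type,
            "snps_input": len(cohort.genotypes.columns),
            "snps_included": len(panel.included_ids),
            "hwe_failures": [r.snp_id for r in hwe_results if not r.passed],
            "ld_pruned": [r.pruned_snp for r in ld_results],
            "pseudo_r2": "mcfadden",
            "flags": criteria.flags(),
            "gps_cancer_or": float(overall["estimate"]),
            "gps_cancer_ci": [float(overall["ci_low"]), float(overall["ci_high"])],
            "gps_cancer_p": float(overall["p_value"]),
            "gps_cancer_ci_covers_1": bool(
                overall["ci_low"] <= 1.0 <= overall["ci_high"]
            ),
        }

        result = PipelineResult(
            cohort=cohort, panel=panel, scan=scan, gps=gps, quartiles=quartiles,
            trait_scores=trait_scores, propensity=propensity, criteria=criteria,
            gps_cancer_table=gps_cancer_table, phototype_table=phototype_table,
            descriptive=descriptive, egger_scatter=egger_scatter, summary=summary,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(result.descriptive, outdir / "descriptive.tsv")
        _write_tsv(result.phototype_table, outdir / "phototype_cancer.tsv")
        _write_tsv(result.gps_cancer_table, outdir / "gps_cancer.tsv")
        _write_tsv(result.scan, outdir / "snp_scan.tsv")
        result.panel.to_tsv(outdir / "panel.tsv")
        c1_rows, model_rows = [], []
        for trait, block in result.criteria.criterion1.items():
            c1_rows.append(block.rrr_per_unit)
            if block.rrr_by_quartile is not None:
                c1_rows.append(block.rrr_by_quartile)
            comp = block.comparison
            model_rows.append(
                {"trait": trait, "chi_square": comp.chi_square, "df": comp.df,
                 "f_stat": comp.f_stat, "p_value": comp.p_value, "delta_r2": comp.delta_r2}
            )
        _write_tsv(pd.concat(c1_rows, ignore_index=True), outdir / "criterion1_rrr.tsv")
        _write_tsv(pd.DataFrame(model_rows), outdir / "criterion1_models.tsv")
        _write_tsv(result.criteria.criterion2, outdir / "criterion2.tsv")
        egger_rows = [
            {"trait": e.trait, "cancer_type": e.cancer_type, "n_snps": e.n_snps,
             "alpha": e.alpha, "se_alpha": e.se_alpha, "p_alpha": e.p_alpha,
             "beta": e.beta, "se_beta": e.se_beta, "p_beta": e.p_beta}
            for e in result.criteria.criterion3.values()
        ]
        _write_tsv(pd.DataFrame(egger_rows), outdir / "egger.tsv")
        if len(result.egger_scatter):
            _write_tsv(result.egger_scatter, outdir / "egger_scatter.tsv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)
        with open(outdir / "run.log", "w") as fh:
            fh.write(
                f"config_hash={config.config_hash()}\nseed={config.seed}\n"
                f"hwe_threshold={config.hwe_threshold}\nld_threshold={config.ld_threshold}\n"
                f"scan_threshold={config.scan_threshold}\nalpha_level={config.alpha_level}\n"
                f"pseudo_r2=mcfadden\npropensity_terms={result.propensity.terms}\n"
            )
    return result
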