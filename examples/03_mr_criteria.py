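"""Test the three instrument-validity criteria for the GPS.

(1) GPS-phototype association in controls (multinomial RRR per GPS unit),
(2) GPS independence from cancer risk factors (chi-square/ANOVA by quartile),
(3) no direct GPS-cancer pathway: MR-Egger intercept per trait.
"""

from pigmentmr import SimParams, simulate_cohort
from pigmentmr.genetics import SnpPanel, assign_quartiles, build_gps, orient_alleles
from pigmentmr.models import fit_propensity
from pigmentmr.mr import CriteriaReport, criterion1, criterion2, mr_egger, per_snp_summary

cohort = simulate_cohort(SimParams(n_cases=1500, n_controls=1500, seed=3))
controls = cohort.control_mask

panel = SnpPanel.from_ids(list(cohort.genotypes.columns))
panel, scan = orient_alleles(
    cohort.genotypes[controls.to_numpy()], cohort.traits[controls.to_numpy()], panel
)
gps = build_gps(cohort.genotypes, panel)
quart = assign_quartiles(gps, controls)
prop = fit_propensity(cohort.covariates, cohort.outcome)

c1 = criterion1(gps[controls], cohort.traits[controls.to_numpy()], prop.values[controls])
print("criterion 1 - GPS vs phototype in controls:")
for trait, block in c1.items():
    comp = block.comparison
    light_rrr = block.rrr_per_unit.iloc[-1]
    print(f"  {trait:9s} F={comp.f_stat:6.2f} p={comp.p_value:.2e} "
          f"dR2={comp.delta_r2:.2f}%  lightest-category RRR/unit "
          f"{light_rrr['estimate']:.3f} ({light_rrr['ci_low']:.3f}-{light_rrr['ci_high']:.3f})")

risk = cohort.covariates.loc[controls.to_numpy(), ["age", "bmi", "smoking", "education"]]
c2_table, c2_pass = criterion2(quart[controls], risk)
print(f"\ncriterion 2 - GPS vs risk factors (Bonferroni): pass={c2_pass}")
print(c2_table[["confounder", "test", "statistic", "p_value"]].to_string(index=False))

c3 = {}
for trait in cohort.traits.columns:
    summ = per_snp_summary(cohort.genotypes, panel, cohort.traits[trait],
                           cohort.outcome, prop.values, controls)
    c3[trait] = mr_egger(summ, trait, cohort.cancer_type)
print("\ncriterion 3 - MR-Egger per trait (alpha = directional pleiotropy):")
for trait, e in c3.items():
    print(f"  {trait:9s} alpha={e.alpha:+.4f} (p={e.p_alpha:.3f})  "
          f"beta={e.beta:+.4f} (p={e.p_beta:.3f})  n_snps={e.n_snps}")

report = CriteriaReport(c1, c2_table, c3)
print("\nflags:", report.flags())
print("(all three must hold for the GPS to be a valid instrument for phototype)")
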