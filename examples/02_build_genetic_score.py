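"""QC a SNP panel and build the genetic pigmentation score (GPS).

Runs the QC chain on a simulated cohort: Hardy-Weinberg test per SNP, the
SNP-by-SNP phototype scan that orients each effect allele toward the
"lighter" pole, LD pruning at r^2 > 0.8, then the GPS (sum of oriented
dosages, 0..34 for 17 SNPs) and its control-based quartiles.
"""

from pigmentmr import SimParams, simulate_cohort
from pigmentmr.genetics import (
    SnpPanel, assign_quartiles, build_gps, hwe_filter, ld_prune, orient_alleles,
)

cohort = simulate_cohort(SimParams(n_cases=1000, n_controls=1000, seed=2))
controls = cohort.control_mask.to_numpy()

panel = SnpPanel.from_ids(list(cohort.genotypes.columns))
panel, hwe = hwe_filter(cohort.genotypes[controls], panel)
print(f"HWE: {sum(r.passed for r in hwe)}/{len(hwe)} SNPs pass at p >= 1e-4")

panel, scan = orient_alleles(cohort.genotypes[controls], cohort.traits[controls], panel)
print("orientations (+1 = effect allele is the lighter allele):",
      panel.table["orientation"].tolist())

panel, removed = ld_prune(cohort.genotypes, panel, 0.8, scan)
print(f"LD pruning removed {len(removed)} SNP(s); {len(panel.included_ids)} remain")

gps = build_gps(cohort.genotypes, panel)
quart = assign_quartiles(gps, cohort.control_mask)
print(f"\nGPS range {gps.min():.0f}-{gps.max():.0f} "
      f"(theoretical 0-{2 * len(panel.included_ids)}), mean {gps.mean():.2f}")
print("control quartile sizes:",
      quart[cohort.control_mask].value_counts().sort_index().tolist())
print("(higher GPS = genetically lighter phototype; quartile cut-points come "
      "from controls)")
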