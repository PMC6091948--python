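"""Run the whole analysis end-to-end and read the machine summary.

One call executes: simulation (or file input), HWE filter, phototype scan +
allele orientation, LD pruning, GPS + quartiles + trait-specific scores,
propensity score, criteria 1-3, and the GPS-cancer / phototype-cancer
association tables. All result TSVs land in the output directory.
"""

import json

from pigmentmr import RunConfig, run_pipeline

config = RunConfig(
    simulation={"n_cases": 1000, "n_controls": 1000},
    seed=5,
    outdir="scratch/example_run",
)
result = run_pipeline(config)

print(json.dumps(result.summary, indent=2, sort_keys=True))
print("\nGPS-cancer association by stratum:")
gps_rows = result.gps_cancer_table.query("score == 'gps'")
print(gps_rows[["stratum", "n_cases", "n_controls", "estimate", "ci_low",
                "ci_high", "p_value"]].to_string(index=False))
print("\n(an OR per GPS unit with CI covering 1 in every stratum reproduces the "
      "no-association conclusion; criteria flags say whether the GPS was a "
      "valid instrument on this dataset)")
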