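import numpy as np
import pytest

from pigmentmr import genetics, models
from pigmentmr.simulate import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def cohort_small():
    """One moderate simulated cohort (600+600, defaults) shared across tests."""
    return simulate_cohort(SimParams(n_cases=600, n_controls=600, seed=2024))


@pytest.fixture(scope="session")
def scored_small(cohort_small):
    """QC'd panel, scan, GPS, quartiles and propensity for the shared cohort."""
    c = cohort_small
    controls = c.control_mask
    panel = genetics.SnpPanel.from_ids(list(c.genotypes.columns))
    panel, hwe = genetics.hwe_filter(c.genotypes[controls.to_numpy()], panel)
    panel, scan = genetics.orient_alleles(
        c.genotypes[controls.to_numpy()], c.traits[controls.to_numpy()], panel
    )
    gps = genetics.build_gps(c.genotypes, panel)
    quart = genetics.assign_quartiles(gps, controls)
    prop = models.fit_propensity(c.covariates, c.outcome)
    return {
        "cohort": c,
        "panel": panel,
        "scan": scan,
        "gps": gps,
        "quartiles": quart,
        "propensity": prop,
    }
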