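"""SNP QC, allele orientation and score construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pigmentmr import genetics
from pigmentmr.genetics import (
    SnpPanel,
    assign_quartiles,
    build_gps,
    hwe_test,
    ld_prune,
    orient_alleles,
    oriented_dosages,
    trait_score,
)
from pigmentmr.simulate import SimParams, simulate_cohort


@pytest.mark.parametrize(
    "counts, chi2, passes, mono",
    [
        ((25, 50, 25), 0.0, True, False),      # exact HWE proportions
        ((50, 0, 50), 100.0, False, False),    # total heterozygote deficit
        ((0, 0, 120), 0.0, True, True),        # monomorphic
        ((120, 0, 0), 0.0, True, True),
    ],
)
def test_hwe_known_counts(counts, chi2, passes, mono):
    res = hwe_test(counts, "rs1")
    assert res.chi_square == pytest.approx(chi2, abs=1e-10)
    assert res.passed is passes
    assert res.monomorphic is mono
    if not passes:
        assert res.p_value < 1e-4


@given(
    st.tuples(
        st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
    ).filter(lambda c: sum(c) > 0)
)
@settings(max_examples=200, derandomize=True)
def test_hwe_probability_contract(counts):
    res = hwe_test(counts)
    assert 0.0 <= res.p_value <= 1.0
    assert res.chi_square >= 0.0
    assert res.passed == (res.p_value >= 1e-4)


def _panel_for(genotypes):
    return SnpPanel.from_ids(list(genotypes.columns))


def test_ld_prune_removes_duplicated_column(cohort_small):
    g = cohort_small.genotypes.copy()
    g["dup"] = g[g.columns[0]]
    panel, results = ld_prune(g, _panel_for(g), 0.8)
    assert len(results) == 1
    assert results[0].r_squared == pytest.approx(1.0)
    assert len(panel.included_ids) == len(g.columns) - 1


def test_ld_prune_independent_snps_untouched():
    for seed in (1, 2, 3):
        c = simulate_cohort(SimParams(n_cases=1000, n_controls=1000, seed=seed))
        panel, results = ld_prune(c.genotypes, _panel_for(c.genotypes), 0.8)
        assert results == []
        assert len(panel.included_ids) == 17


def test_ld_prune_engineered_pair_18_to_17():
    """An 18-SNP panel with one pair at r^2 ~ 0.9 prunes to exactly 17,
    keeping the member with the stronger phototype-scan association."""
    c = simulate_cohort(SimParams(n_cases=1000, n_controls=1000, seed=4))
    rng = np.random.default_rng(4)
    g = c.genotypes.copy()
    src = g.columns[0]
    twin = g[src].to_numpy().copy()
    flip = rng.random(len(twin)) < 0.04  # ~4% regenotyped -> r^2 just below 1
    twin[flip] = rng.binomial(2, 0.12, flip.sum())
    g["rs_twin"] = twin
    r2 = np.corrcoef(g[src], g["rs_twin"])[0, 1] ** 2
    assert 0.8 < r2 < 0.99
    panel = _panel_for(g)
    controls = c.control_mask.to_numpy()
    _, scan = orient_alleles(g[controls], c.traits[controls], panel)
    pruned, results = ld_prune(g, panel, 0.8, scan)
    assert len(results) == 1
    assert len(pruned.included_ids) == 17
    # tie-break: the removed SNP has the weaker best single-trait p
    best = scan.groupby("snp_id")["p_value"].min()
    kept = src if results[0].pruned_snp == "rs_twin" else "rs_twin"
    assert best[results[0].pruned_snp] >= best[kept]


def test_ld_prune_all_missing_column_rejected(cohort_small):
    g = cohort_small.genotypes.copy()
    g[g.columns[3]] = np.nan
    with pytest.raises(ValueError, match=g.columns[3]):
        ld_prune(g, _panel_for(g), 0.8)


def test_orientation_sign_follows_trait_effect():
    """Default simulation at study scale: every effect allele pushes lighter,
    so all orientations must come out +1."""
    c = simulate_cohort(SimParams(n_cases=1500, n_controls=1500, seed=2))
    controls = c.control_mask.to_numpy()
    panel, scan = orient_alleles(c.genotypes[controls], c.traits[controls], _panel_for(c.genotypes))
    assert (panel.table["orientation"] == 1).all()
    assert set(scan.columns) >= {"snp_id", "trait", "beta", "se", "p_value"}
    assert len(scan) == 17 * 5


def test_orientation_flip_invariance(cohort_small):
    """Relabelling effect/other alleles (g -> 2-g) flips the orientation but
    leaves oriented dosages and the GPS unchanged."""
    c = cohort_small
    controls = c.control_mask.to_numpy()
    panel = _panel_for(c.genotypes)
    p1, _ = orient_alleles(c.genotypes[controls], c.traits[controls], panel)
    flipped = c.genotypes.copy()
    flip_snps = list(flipped.columns[::2])
    flipped[flip_snps] = 2.0 - flipped[flip_snps]
    p2, _ = orient_alleles(flipped[controls], c.traits[controls], panel)
    for snp in flip_snps:
        assert p2.orientations[snp] == -p1.orientations[snp]
    pd.testing.assert_frame_equal(
        oriented_dosages(c.genotypes, p1), oriented_dosages(flipped, p2)
    )
    pd.testing.assert_series_equal(build_gps(c.genotypes, p1), build_gps(flipped, p2))


def test_orientation_recovery_under_random_signs():
    """Known random orientation vector, |effect| = 0.3 per allele, n = 2000
    controls: at least 16 of 17 orientations recovered."""
    rng = np.random.default_rng(99)
    signs = rng.choice([-1.0, 1.0], 17)
    effects = np.zeros((17, 5))
    for j in range(17):
        effects[j, j % 5] = 0.3 * signs[j]
    p = SimParams(n_cases=2000, n_controls=2000, snp_trait_effects=effects, seed=99)
    c = simulate_cohort(p)
    controls = c.control_mask.to_numpy()
    panel, _ = orient_alleles(c.genotypes[controls], c.traits[controls], _panel_for(c.genotypes))
    recovered = (panel.table["orientation"].to_numpy() == signs).sum()
    assert recovered >= 16


def test_orientation_zero_variance_flagged(cohort_small):
    g = cohort_small.genotypes.copy()
    mono = g.columns[5]
    g[mono] = 0.0
    controls = cohort_small.control_mask.to_numpy()
    panel, _ = orient_alleles(g[controls], cohort_small.traits[controls], _panel_for(g))
    row = panel.table.set_index("snp_id").loc[mono]
    assert row["orientation"] == 1
    assert bool(row["uninformative"])


def test_gps_endpoints_and_row_sums():
    ids = [f"rs{i}" for i in range(3)]
    panel = SnpPanel.from_ids(ids)
    panel.table["orientation"] = 1
    g = pd.DataFrame([[0, 1, 2], [1, 1, 1], [2, 0, 0]], columns=ids,
                     index=pd.Index(["a", "b", "c"], name="subject_id"), dtype=float)
    assert build_gps(g, panel).tolist() == [3.0, 3.0, 2.0]
    zeros = pd.DataFrame(np.zeros((2, 3)), columns=ids)
    full = pd.DataFrame(np.full((2, 3), 2.0), columns=ids)
    assert build_gps(zeros, panel).tolist() == [0.0, 0.0]
    assert build_gps(full, panel).tolist() == [6.0, 6.0]


def test_gps_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    ids = [f"rs{i}" for i in range(17)]
    g = pd.DataFrame(rng.integers(0, 3, (100, 17)).astype(float), columns=ids)
    panel = SnpPanel.from_ids(ids)
    panel.table["orientation"] = rng.choice([-1, 1], 17)
    gps = build_gps(g, panel)
    orient = panel.orientations
    for i in range(100):  # naive per-subject loop
        total = 0.0
        for snp in ids:
            d = g.iloc[i][snp]
            total += d if orient[snp] == 1 else 2 - d
        assert gps.iloc[i] == total


def test_gps_complete_case_on_missing():
    ids = ["rs1", "rs2"]
    panel = SnpPanel.from_ids(ids)
    panel.table["orientation"] = 1
    g = pd.DataFrame([[1.0, np.nan], [2.0, 0.0]], columns=ids)
    gps = build_gps(g, panel)
    assert np.isnan(gps.iloc[0]) and gps.iloc[1] == 2.0


@given(st.integers(0, 16), st.integers(0, 2))
@settings(max_examples=50, derandomize=True)
def test_gps_monotone_in_oriented_dosage(snp_idx, new_dosage):
    """Raising one oriented dosage by d raises the GPS by exactly d."""
    rng = np.random.default_rng(123)
    ids = [f"rs{i}" for i in range(17)]
    g = pd.DataFrame(rng.integers(0, 3, (5, 17)).astype(float), columns=ids)
    panel = SnpPanel.from_ids(ids)
    panel.table["orientation"] = 1
    before = build_gps(g, panel)
    delta = new_dosage - g.iloc[2, snp_idx]
    g.iloc[2, snp_idx] = new_dosage
    after = build_gps(g, panel)
    assert after.iloc[2] - before.iloc[2] == pytest.approx(delta)


def test_trait_score_full_threshold_equals_gps(scored_small):
    s = scored_small
    score, members = trait_score(s["cohort"].genotypes, s["panel"], s["scan"], "eye", 1.0)
    assert members == s["panel"].included_ids
    pd.testing.assert_series_equal(
        score, s["gps"], check_names=False
    )


def test_trait_score_zero_threshold_rejected(scored_small):
    s = scored_small
    with pytest.raises(ValueError, match="threshold"):
        trait_score(s["cohort"].genotypes, s["panel"], s["scan"], "eye", 0.0)


def test_trait_score_membership_recovers_driving_snps():
    """When only SNPs 0-4 drive hair, the hair score membership at n=4000 is
    exactly those SNPs (strict scan threshold keeps noise SNPs out)."""
    effects = np.zeros((17, 5))
    effects[:5, 0] = 0.4           # hair
    for j in range(5, 17):
        effects[j, 1 + (j % 4)] = 0.4  # other traits only
    p = SimParams(n_cases=2000, n_controls=2000, snp_trait_effects=effects, seed=17)
    c = simulate_cohort(p)
    controls = c.control_mask.to_numpy()
    panel, scan = orient_alleles(c.genotypes[controls], c.traits[controls], _panel_for(c.genotypes))
    _, members = trait_score(c.genotypes, panel, scan, "hair", threshold=1e-3)
    assert members == list(c.genotypes.columns[:5])


def test_quartiles_exact_quartering():
    gps = pd.Series(np.arange(1.0, 9.0))
    q = assign_quartiles(gps)
    assert q.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]


def test_quartiles_constant_rejected():
    with pytest.raises(ValueError, match="distinct"):
        assign_quartiles(pd.Series(np.full(100, 7.0)))


def test_quartiles_balanced_on_control_reference(scored_small):
    s = scored_small
    controls = s["cohort"].control_mask
    q = s["quartiles"][controls]
    frac = q.value_counts(normalize=True).sort_index()
    # integer GPS ties share the lower quartile, so each cell holds 25% up to
    # the largest single-value tie mass
    tie_width = s["gps"][controls].value_counts(normalize=True).max()
    assert len(frac) == 4
    assert ((frac - 0.25).abs() <= tie_width + 1e-12).all()
    # ties share the lower quartile: quartile is monotone in gps
    joined = pd.DataFrame({"gps": s["gps"][controls], "q": q}).sort_values("gps")
    assert joined["q"].is_monotonic_increasing


def test_qc_rerun_is_noop(scored_small):
    """Re-running HWE + LD pruning on an already-pruned panel changes nothing."""
    s = scored_small
    c = s["cohort"]
    controls = c.control_mask.to_numpy()
    panel2, hwe = genetics.hwe_filter(c.genotypes[controls], s["panel"])
    assert panel2.included_ids == s["panel"].included_ids
    panel3, ld = ld_prune(c.genotypes, panel2, 0.8, s["scan"])
    assert ld == []
    assert panel3.included_ids == s["panel"].included_ids
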