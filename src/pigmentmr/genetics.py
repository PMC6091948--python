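"""SNP QC and genetic pigmentation score construction.

Pipeline order is fixed: Hardy-Weinberg filtering, then LD pruning
(r^2 > 0.8 removes one member of each redundant pair), then data-driven
allele orientation (a SNP-by-SNP scan of each variant against the five
phototype traits decides which allele counts toward the "lighter" pole),
then score building: the genetic pigmentation score (GPS) is the plain sum
of oriented dosages over the included SNPs, and five trait-specific
sub-scores restrict the sum to SNPs whose scan association with that trait
is significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpPanel",
    "HweResult",
    "LdResult",
    "hwe_test",
    "hwe_filter",
    "ld_prune",
    "orient_alleles",
    "oriented_dosages",
    "build_gps",
    "trait_score",
    "assign_quartiles",
]

HWE_THRESHOLD = 1e-4
LD_THRESHOLD = 0.8
SCAN_THRESHOLD = 0.05


@dataclass
class SnpPanel:
    """Annotation for the SNP instrument panel.

    ``table`` columns: snp_id, effect_allele, other_allele, literature_traits
    (comma-joined), included (bool), orientation (+1/-1, NaN until fitted).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "other_allele"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            dup = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id in panel: {dup}")
        self.table = self.table.reset_index(drop=True)
        if "literature_traits" not in self.table:
            self.table["literature_traits"] = ""
        if "included" not in self.table:
            self.table["included"] = True
        if "orientation" not in self.table:
            self.table["orientation"] = np.nan

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def included_ids(self) -> list[str]:
        return self.table.loc[self.table["included"], "snp_id"].tolist()

    @property
    def orientations(self) -> pd.Series:
        return self.table.set_index("snp_id")["orientation"]

    def copy(self) -> "SnpPanel":
        return SnpPanel(self.table.copy())

    @classmethod
    def from_ids(cls, snp_ids, effect_alleles=None, other_alleles=None) -> "SnpPanel":
        n = len(snp_ids)
        return cls(
            pd.DataFrame(
                {
                    "snp_id": list(snp_ids),
                    "effect_allele": list(effect_alleles) if effect_alleles is not None else ["A"] * n,
                    "other_allele": list(other_alleles) if other_alleles is not None else ["G"] * n,
                }
            )
        )

    @classmethod
    def read_tsv(cls, path) -> "SnpPanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"snp_id": str}))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass(frozen=True)
class HweResult:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg proportions."""

    snp_id: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    chi_square: float
    p_value: float
    passed: bool
    monomorphic: bool = False


@dataclass(frozen=True)
class LdResult:
    snp_a: str
    snp_b: str
    r_squared: float
    pruned_snp: str


def hwe_test(counts, snp_id: str = "", threshold: float = HWE_THRESHOLD) -> HweResult:
    """Test genotype counts (hom-ref, het, hom-alt) against p^2 / 2pq / q^2.

    The allele frequency is estimated from the counts themselves, leaving one
    degree of freedom. A monomorphic SNP (one allele absent) trivially fits
    HWE and is reported as passing with chi-square 0 and a monomorphic flag.
    """
    n_rr, n_ra, n_aa = (int(c) for c in counts)
    if min(n_rr, n_ra, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_rr + n_ra + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_rr + n_ra) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HweResult(snp_id, n_rr, n_ra, n_aa, 0.0, 1.0, True, monomorphic=True)
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_rr, n_ra, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(snp_id, n_rr, n_ra, n_aa, chi2, p_value, p_value >= threshold)


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    d = dosages[~np.isnan(dosages)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_filter(
    genotypes: pd.DataFrame, panel: SnpPanel, threshold: float = HWE_THRESHOLD
) -> tuple[SnpPanel, list[HweResult]]:
    """Run the HWE test on every panel SNP and drop failures from the panel."""
    panel = panel.copy()
    results = []
    for snp in panel.included_ids:
        res = hwe_test(_genotype_counts(genotypes[snp].to_numpy(dtype=float)), snp, threshold)
        results.append(res)
        if not res.passed:
            panel.table.loc[panel.table["snp_id"] == snp, "included"] = False
    return panel, results


def _pairwise_r2(genotypes: pd.DataFrame, snps: list[str]) -> pd.DataFrame:
    g = genotypes[snps].astype(float)
    for snp in snps:
        if g[snp].isna().all():
            raise ValueError(f"SNP {snp} has no non-missing dosages")
    return g.corr(min_periods=2) ** 2


def ld_prune(
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    threshold: float = LD_THRESHOLD,
    scan: pd.DataFrame | None = None,
) -> tuple[SnpPanel, list[LdResult]]:
    """Greedily remove one SNP from every pair with squared dosage correlation
    above ``threshold`` (pairwise-complete Pearson r^2).

    When a ``scan`` table (per-SNP per-trait p-values, as produced by
    :func:`orient_alleles`) is given, the member with the weaker best
    single-trait association (larger minimum p) is removed; otherwise the SNP
    later in panel order goes.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    panel = panel.copy()
    active = panel.included_ids
    if len(active) < 2:
        raise ValueError("LD pruning needs at least two included SNPs")
    best_p: dict[str, float] = {}
    if scan is not None:
        best_p = scan.groupby("snp_id")["p_value"].min().to_dict()
    results: list[LdResult] = []
    r2 = _pairwise_r2(genotypes, active)
    while True:
        m = r2.to_numpy(copy=True)
        np.fill_diagonal(m, 0.0)
        m = np.nan_to_num(m, nan=0.0)
        if m.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(m), m.shape)
        a, b = r2.index[i], r2.columns[j]
        if best_p:
            drop = a if best_p.get(a, 1.0) > best_p.get(b, 1.0) else b
        else:
            drop = b if active.index(a) < active.index(b) else a
        results.append(LdResult(a, b, float(m[i, j]), drop))
        panel.table.loc[panel.table["snp_id"] == drop, "included"] = False
        active = [s for s in active if s != drop]
        r2 = r2.loc[active, active]
    return panel, results


def _scan_one(dosage: np.ndarray, trait_idx: np.ndarray) -> tuple[float, float, float]:
    """Ordinal-as-linear single-SNP fit: slope, SE and p of trait index on dosage."""
    ok = ~(np.isnan(dosage) | np.isnan(trait_idx))
    x, y = dosage[ok], trait_idx[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0:
        return 0.0, np.inf, 1.0
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(sigma2 / sxx) if sigma2 > 0 else 0.0
    if se == 0.0:
        return slope, 0.0, 0.0 if slope != 0 else 1.0
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return slope, se, p


def orient_alleles(
    genotypes: pd.DataFrame, traits: pd.DataFrame, panel: SnpPanel
) -> tuple[SnpPanel, pd.DataFrame]:
    """Data-driven allele orientation: the SNP-by-SNP phototype scan.

    For each included SNP, the ordered category index (0 = darkest) of every
    trait is regressed on the raw effect-allele dosage in the supplied
    subjects (the analysis uses controls only). The trait with the smallest
    p-value decides the orientation: +1 when the effect allele pushes toward
    the lighter pole, -1 otherwise, so that oriented dosages always count
    "lighter" alleles. SNPs with zero dosage variance keep +1 and are
    flagged uninformative.

    Returns the panel with fitted orientations plus the full scan table
    (snp_id, trait, beta, se, p_value).
    """
    panel = panel.copy()
    rows = []
    orientations = {}
    uninformative = {}
    for snp in panel.included_ids:
        dosage = genotypes[snp].to_numpy(dtype=float)
        best_p, best_beta = np.inf, 0.0
        informative = np.ptp(dosage[~np.isnan(dosage)]) > 0 if (~np.isnan(dosage)).any() else False
        for trait in traits.columns:
            tvals = traits[trait]
            idx = (
                tvals.cat.codes.astype(float).replace(-1, np.nan).to_numpy()
                if isinstance(tvals.dtype, pd.CategoricalDtype)
                else tvals.to_numpy(dtype=float)
            )
            beta, se, p = _scan_one(dosage, idx)
            rows.append(
                {"snp_id": snp, "trait": trait, "beta": beta, "se": se, "p_value": p}
            )
            if p < best_p or (p == best_p and abs(beta) > abs(best_beta)):
                best_p, best_beta = p, beta
        if not informative:
            orientations[snp] = 1
            uninformative[snp] = True
        else:
            orientations[snp] = 1 if best_beta >= 0 else -1
            uninformative[snp] = False
    scan = pd.DataFrame(rows)
    panel.table["orientation"] = panel.table["snp_id"].map(orientations)
    panel.table["uninformative"] = panel.table["snp_id"].map(uninformative)
    return panel, scan


def oriented_dosages(genotypes: pd.DataFrame, panel: SnpPanel) -> pd.DataFrame:
    """Dosage of the "lighter" allele per included SNP: g when orientation +1, 2-g when -1."""
    snps = panel.included_ids
    orient = panel.orientations.loc[snps]
    if orient.isna().any():
        missing = orient.index[orient.isna()][0]
        raise ValueError(f"orientation not fitted for SNP {missing}; run orient_alleles first")
    g = genotypes[snps].to_numpy(dtype=float)
    flipped = np.where(orient.to_numpy()[None, :] > 0, g, 2.0 - g)
    return pd.DataFrame(flipped, index=genotypes.index, columns=snps)


def build_gps(genotypes: pd.DataFrame, panel: SnpPanel) -> pd.Series:
    """Genetic pigmentation score: sum of oriented dosages over included SNPs.

    Complete-case: any missing included dosage makes the subject's GPS NaN.
    For complete genotypes the score is an integer in [0, 2m].
    """
    od = oriented_dosages(genotypes, panel)
    gps = od.sum(axis=1, skipna=False)
    gps.name = "gps"
    return gps


def trait_score(
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    scan: pd.DataFrame,
    trait: str,
    threshold: float = SCAN_THRESHOLD,
) -> tuple[pd.Series, list[str]]:
    """Trait-specific sub-score: oriented-dosage sum over SNPs whose scan
    association with ``trait`` has p < ``threshold``. Returns (score, members)."""
    if threshold <= 0:
        raise ValueError("trait-score threshold must be positive; raise it to admit SNPs")
    hits = scan[(scan["trait"] == trait) & (scan["p_value"] < threshold)]["snp_id"]
    members = [s for s in panel.included_ids if s in set(hits)]
    if not members:
        raise ValueError(
            f"no SNP passes the scan threshold {threshold} for trait {trait!r}; "
            "consider raising the threshold"
        )
    sub = panel.copy()
    sub.table["included"] = sub.table["snp_id"].isin(members) & sub.table["included"]
    score = build_gps(genotypes, sub)
    score.name = f"score_{trait}"
    return score, members


def assign_quartiles(gps: pd.Series, reference: pd.Series | np.ndarray | None = None) -> pd.Series:
    """Quartile (1-4) of each GPS value, cut at the reference subset's
    25/50/75 empirical percentiles (the analysis cuts on controls).

    Intervals are half-open upward: Q1 is gps <= c25, Q2 is c25 < gps <= c50,
    etc., so ties share the lower quartile. NaN GPS stays NaN.
    """
    ref = gps if reference is None else gps[np.asarray(reference, dtype=bool)]
    ref = ref.dropna()
    if ref.nunique() < 4:
        raise ValueError(
            f"GPS reference distribution has only {ref.nunique()} distinct values; "
            "quartiles are undefined"
        )
    cuts = np.percentile(ref.to_numpy(), [25, 50, 75])
    vals = gps.to_numpy(dtype=float)
    q = np.full(len(vals), np.nan)
    ok = ~np.isnan(vals)
    q[ok] = 1.0 + (vals[ok] > cuts[0]) + (vals[ok] > cuts[1]) + (vals[ok] > cuts[2])
    out = pd.Series(q, index=gps.index, name="quartile")
    return out
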