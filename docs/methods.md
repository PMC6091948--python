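# Methods

## Model and procedure

The analysis treats the five phototype traits (hair colour, skin colour, eye
colour, freckling, tanning response) as ordered categoricals, darkest
category first, and a ~17-SNP pigmentation panel as candidate instruments.
The stages run in a fixed order:

1. **Hardy-Weinberg QC.** Per SNP, a 1-df χ² goodness-of-fit of the observed
   genotype counts against p²/2pq/q² with the allele frequency estimated from
   the same counts; SNPs with p < 10⁻⁴ are excluded. Monomorphic SNPs
   trivially satisfy HWE and are kept but flagged. The test runs on controls.
2. **SNP-by-SNP phototype scan and allele orientation.** For each SNP and
   each trait, the trait's category index (0 = darkest) is regressed linearly
   on the raw effect-allele dosage in controls (ordinal-as-linear). The trait
   with the smallest p decides the orientation: +1 when the coefficient
   points to the lighter pole, −1 otherwise; oriented dosage is g or 2−g
   accordingly. Zero-variance SNPs keep +1 and are flagged uninformative.
   The scan model is a deliberate simplification — one signed coefficient per
   (SNP, trait) is exactly what a sign decision and the Egger x-axis need;
   a multinomial scan would give one coefficient per category and no unique
   sign. The rule "smallest p across the five traits" makes orientation
   deterministic and lets the orienting trait differ from the literature
   annotation, which mirrors how such scores behave in practice.
3. **LD pruning.** Pairwise squared Pearson correlation of dosages on
   pairwise-complete cases; while any pair exceeds r² = 0.8, the member whose
   best single-trait scan association is weaker (larger minimum p) is
   removed. Orientation is a per-SNP property, so running the scan before or
   after pruning gives identical results for the surviving SNPs, and
   re-running the QC chain on pruned output is a no-op.
4. **Scores.** GPS = sum of oriented dosages over included SNPs;
   complete-case (any missing included dosage gives a missing GPS; optional
   mean imputation exists but is off by default). Trait-specific sub-scores
   restrict the sum to SNPs whose scan association with that trait has
   p < 0.05 (threshold configurable). Quartile cut-points are the 25/50/75
   empirical percentiles **of controls**, applied to everyone, with half-open
   intervals so ties share the lower quartile.
5. **Propensity score.** Logistic regression of case status on recruitment
   centre, three ancestry PCs, age, education, BMI and smoking (dummy coding,
   lowest category as reference); the fitted probability enters all
   downstream models as a single linear covariate. By the logistic score
   equations its mean equals the case fraction — a cheap internal check.
6. **Criteria.** Criterion 1: per trait, multinomial logit of trait on
   GPS + propensity vs propensity alone; likelihood-ratio χ², the reported
   F statistic is χ²/(k−1) with k the trait's category count, and ΔR² is the
   difference of McFadden pseudo-R² of the two models against a shared
   intercept-only null, reported in percent. Criterion 2: χ² (categorical)
   or one-way ANOVA (continuous) of each risk factor across GPS quartiles in
   controls; the family flag uses Bonferroni at level 0.05. Criterion 3:
   MR-Egger per (trait, cancer): x = per-SNP ordinal-as-linear trait
   coefficient (controls), y = per-SNP propensity-adjusted logistic log-OR,
   weights 1/se(y)²; before fitting, any SNP with x < 0 has both x and y
   flipped (all-positive-exposure convention), which leaves the slope
   invariant and gives the intercept its directional-pleiotropy meaning.
   The per-trait Egger intercept tests are Bonferroni-combined into the
   criterion-3 family flag, matching the criterion-2 multiplicity rule.
7. **Associations.** Logistic OR per score unit adjusted for the propensity
   score, overall and within strata (age <65/≥65, BMI <25/≥25, menopausal
   status for the breast cohort); strata under 20 subjects are reported but
   flagged. Phototype-cancer models use dummy-coded categories with the
   darkest as reference and report the same F/ΔR² comparison.

## Synthetic cohort generator

The generator emulates the multicentre case-control structure the analysis
assumes. Genotypes are independent binomial(2, f) draws (default frequencies
0.10-0.75 across the 17 panel SNPs). Each trait follows a proportional-odds
(cumulative-logit) model: thresholds reproduce the baseline category
probabilities (taken from the controls-only marginals of the published
cohort) and the linear predictor adds SNP effects and confounder terms, with
positive values pushing toward lighter categories. Default SNP-trait
architecture: each SNP carries +0.4 per allele on one primary trait and
+0.15 on a neighbouring trait (pigmentation loci are typically pleiotropic
across pigmentation traits; effects of this size make criterion 1 clearly
detectable at the default 2000+2000 sample, as in the real cohort). Cancer
liability is a logistic model with a per-category-step causal trait effect
(default 0 — the null the study concluded), per-SNP direct pleiotropic
effects (default 0), and confounder effects (age, BMI, smoking, education,
centre on cancer; centre and PC1 on traits). Age is a normal(59, 13)
truncated to the 20-85 recruitment window; menopause is deterministic in age
(≥51 ⇒ post) with 5% noise.

Cases accrue by rejection sampling from the liability model; controls are
then sampled **stratified** on (centre, 5-year age band) to the case
distribution, with largest-remainder apportionment of the control total.
Cells the initial pool cannot fill are completed by targeted draws
conditioned on the cell; a cell still unfilled after 10,000 targeted
candidate draws raises an error naming the cell. Stratified sampling is
stricter than the marginal frequency matching of the original design — it
forces every cell ratio to the global ratio, which makes the matching check
trivially sharp and the age/centre confounding exactly balanced.

What the generator does **not** emulate: exome-chip marker content, real LD
structure (SNPs are independent, so LD pruning is exercised with engineered
near-duplicates), real Spanish allele frequencies, survival/latency, or
self-selection of controls. Passing tests therefore demonstrate the
statistical machinery under the assumed data-generating process, not
robustness to the idiosyncrasies of real cohort data.

## Numerical choices

- Logistic/multinomial fits: Newton-Raphson, log-likelihood tolerance 1e-8,
  max 100 iterations; non-convergence, separation (unbounded SE) and empty
  categories raise explicit errors naming the term.
- Wald 95% CIs throughout (exp(b ± 1.96·se)); two-tailed p-values.
- WLS standard errors use the weighted residual variance on n−2 df with
  t-based p-values; weights are scale-invariant.
- Pseudo-R²: McFadden against a shared intercept-only null. The original
  report never names its R² variant, so the choice is logged in every run's
  metadata ("pseudo_r2": "mcfadden") and the printed R² values of the source
  tables are not comparison targets.
- Pearson χ² without continuity correction; tests with a zero expected cell
  are skipped with a flag; constant confounders report statistic 0.
- Quartile ties share the lower quartile; fewer than 4 distinct reference
  values is an error.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; replicate seeds are spawned deterministically
  and stay below 2³¹. A fixed config reproduces byte-identical output files,
  and the config hash (which excludes the output directory) is stamped into
  every run.

## Monte-Carlo problem sizes

Null calibration (type-I error and CI coverage of the GPS-cancer Wald test)
uses 500 replicates of 2000+2000 subjects with 17 SNPs. The criterion-1/2
calibration uses 200 replicates at 1000+1000 — enough to detect meaningful
departures from uniformity while keeping the default suite quick. Egger
recovery uses 1000 summary-level replicates. Structural checks (18→17
pruning, orientation recovery) run once at 1000-2000 subjects per arm.

## Known limitations

- **Orientation circularity.** Orientation is fitted on the same controls
  criterion 1 is tested on. Under a complete null this selection inflates the
  GPS-phototype association (a winner's-curse effect); the calibration
  harness therefore verifies test uniformity with predetermined orientations,
  and criterion-1 conclusions should be read as conditional on the
  orientation step — a property shared with any data-driven score of this
  kind.
- The ordinal-as-linear exposure coefficient for 3- and 4-category traits is
  one of several defensible choices for Egger's x-axis; results for those
  traits depend on it.
- No robust/clustered SEs, no Firth correction, no IVW/median/mode MR
  estimators (Egger only), no imputation from reference panels, and ancestry
  PCs are consumed as given covariates rather than estimated.
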