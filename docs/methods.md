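# Methods

This note records the models, parameter choices, numerical decisions,
and limitations behind `microdii`, in the order the pipeline runs.

## DII scoring (`microdii.dii`)

The Dietary Inflammatory Index treats each food parameter's intake as
a draw against a global reference distribution: the standardized
intake z = (x − μ)/σ is mapped to a doubled-and-centered normal
percentile p = 2Φ(z) − 1 ∈ (−1, 1) and weighted by the parameter's
inflammatory effect score S. The total is the sum over supplied
parameters. Consequences used as test invariants: the score is 0 when
every intake equals its global mean, each contribution is bounded by
|S|, and the score is strictly monotone in any single intake with the
sign of its S.

Choices:

- **Reference constants.** `data/dii_reference_27.csv` carries the 27
  parameters shared by the VioScreen and DHQII instruments;
  `data/dii_reference_45.csv` the full published index. Global
  means/SDs and effect scores are the standard index-development
  values from the nutrition literature. The documented score range of
  the full index (−8.87 to +7.98) is treated as a documented bound for
  realistic diets, not a derived constant: the theoretical extreme
  (Σ|S| ≈ 12.7) is only approached by diets at the far tails of every
  parameter simultaneously.
- **Energy screen.** Subjects outside the inclusive [500, 5000]
  kcal/day window are excluded — the standard FFQ plausibility rule.
- **Energy correction** (per 1000 kcal density) is applied only to the
  dietary statistics (tertile ANOVA/t-tests, Spearman matrix) and the
  per-nutrient enzyme models, never inside the DII formula itself.
- **Missing intakes** contribute 0 and decrement the per-subject
  parameter count n, which is reported; no imputation.
- **Tertiles** are rank-based; when N mod 3 ≠ 0 the extra members go
  to the higher tertiles (47 → 15/16/16), ties broken by stable
  subject-ID order so repeated runs agree.
- Chi-square tests are Pearson without continuity correction (3-level
  factor); Spearman p-values use scipy's t-approximation with
  midranks; the tertile-1-vs-rest comparison is a pooled-variance
  t-test, defined as (t=0, p=1) when both groups are constant and
  equal.

## Count-table preparation (`microdii.prep`)

- **Decontamination** is prevalence-based: per feature, a 2×2
  presence/absence table (present = count > 0) of controls × specimens
  is scored with the one-sided tail probability in the
  "control-enriched" direction — Fisher's exact test when any expected
  cell is below 5, otherwise half the two-sided chi-square p (or its
  complement when the direction is specimen-enriched). Features
  scoring below 0.5 are removed. Features present everywhere or
  nowhere carry no directional signal and score 1.
- **Sample filter**: library size strictly below 10 reads.
- **Feature filter**: "relative abundance < 1%" is read per-sample —
  a feature is retained iff it reaches ≥ 1% of the library in at least
  one sample, which keeps low-prevalence but locally abundant taxa; a
  `global_mean` mode thresholds the across-sample mean instead. Both
  readings are exposed because the underlying rule is ambiguous in
  common usage.
- **CSS normalization**: per sample, the scaling factor is the sum of
  counts at or below the sample's q-th quantile of positive counts;
  values are scaled by 1000. The default quantile is data-driven and
  deterministic: per-sample quantile curves of positive counts are
  compared to their across-sample median reference, and the smallest
  grid quantile at which the median absolute deviation begins growing
  sharply (relative increase > 0.1) is chosen, falling back to 0.5.
  q = 1 reduces to total-sum scaling. A log2(x+1) view feeds the
  Gaussian models.
- Batch correction is out of scope; the pipeline accepts a `batch`
  column and refuses to model when batch explains >99% of the exposure
  variance rather than silently correcting.

## Diversity (`microdii.diversity`)

Shannon uses the natural log; Simpson is 1 − Σp². Pairwise tertile
comparisons use the Wilcoxon rank-sum test, exact when both groups
have ≤ 25 observations and no ties, otherwise normal approximation
with tie correction. Bray–Curtis operates on CSS-normalized
(untransformed) abundances; unweighted normalized UniFrac operates on
presence/absence against the rooted tree as given (scikit-bio
implementation; tests validate both metrics against brute-force
element/edge enumeration oracles).

PERMANOVA partitions the Gower-centered squared-distance matrix
sequentially — covariates first, the exposure last — and tests the
exposure pseudo-F by Freedman–Lane permutation of the reduced-model
residual matrix, p = (1 + #{F\* ≥ F}) / (1 + n\_perm), 999
permutations by default, seed mandatory. The exposure is the
continuous DII by default; a tertile-contrast mode exists because
either parameterization is defensible. Null simulations (600 reps)
show rejection rates of ~5.3% at α = 0.05 with uniform p throughout
the range.

## Zero-inflated Gaussian modeling (`microdii.zig`)

Per feature, log2(CSS+1) abundance is a mixture of a point mass at
zero — probability logistic in log library size, capturing depth-driven
dropouts — and a Gaussian regression N(x'β, σ²) on the design
(intercept, DII, covariates). EM alternates: responsibilities for zero
observations, weighted least squares for β (weights 1 − r), two to
three Newton steps for the logistic zero model, and a weighted residual
variance. The EM is vectorized across features (shared design, batched
normal solves), so 500 features × 200 samples fit in well under a
second.

Numerical choices: convergence at |Δ log-likelihood| < 1e−4 or 30
iterations (non-converged features are reported but flagged);
probabilities clipped to [1e−10, 1−1e−10]; a 1e−10 ridge on the WLS
normal matrix and 1e−8 on the logistic Hessian; features whose
log-abundance variance is ≤ 1e−12 (constant columns up to float
residue) are skipped with a warning; features with no zeros bypass the
zero model entirely and reproduce OLS exactly (verified to 1e−8).
The exposure test is t = β̂/se(β̂) with weighted residual df
(Σw − p) — the plain plug-in WLS variance. **No empirical-Bayes
variance moderation** is applied; this keeps the estimator simple and
directly testable, at the cost of less stable per-feature variances
than moderated alternatives at very small n. At 200 samples the null
type-I rate is calibrated (≈5%); at 100 samples a ~0.5 percentage
point inflation is visible, the expected finite-sample cost of the
plug-in variance.

BH adjustment is the classic step-up with running-minimum enforcement,
validated against a naive O(n²) oracle and statsmodels. Report sorting
is (adjusted p, |t| descending, feature ID) for determinism; taxa are
labeled at the lowest identifiable rank.

## Predicted functions (`microdii.functions`)

KO/pathway tables are modeled with the same ZIG on log2(x+1); CSS is
off by default since predicted tables are already relative. Gene-set
testing is hypergeometric over-representation (the method behind the
quoted enrichment tooling), not rank-based KS enrichment; the universe
is the set of tested enzymes, the hits are the pre-FDR significant
ones (raw p < 0.05), and BH runs across sets. Per-nutrient models fit
one ZIG family per energy-corrected, Z-scored food parameter with the
enzyme abundance as response (the grammatically ambiguous direction;
the transposed OLS reading is available via
`direction="nutrient_response"`), BH within each family.

## Synthetic cohort (`microdii.synth`)

The generator emulates a 47-subject early-pregnancy cohort:

- **Cohort**: maternal age ~ N(29, 6) clipped to [18, 45], estimated
  gestational age ~ N(10.9, 3) truncated above 4 weeks, BMI ~
  N(29.5, 7), categorical demographics at the cohort's marginal
  proportions, FFQ type ~50/50, sample type 42:5, four batches.
- **Intakes**: a latent diet-quality gradient g ~ N(0, 1) per subject;
  positive g is pro-inflammatory. All 15 vitamin/mineral parameters
  are log-depleted by strength×g (log-normal noise SD 0.3), energy
  declines mildly (−0.25·g on the log scale, base LogNormal(log 1700,
  0.35) clipped to [600, 4800] kcal) mirroring the inverse
  energy-by-tertile pattern, and the remaining parameters vary around
  their global means. At strength 1 the computed DII correlates with g
  at ρ > 0.9 and spans roughly −4 to +4 — the cohort's tertile spread.
- **Counts**: specimen library sizes LogNormal(log 3e4, 0.7); taxon
  probabilities are a softmax of base log-abundances N(0, 1.5) plus
  per-sample noise (SD 0.5); 13 planted taxa carry alternating-sign
  slopes of 0.8 per standardized-DII unit; multinomial sampling; extra
  structural zeros with probability logistic in −log library size
  (≈5% at 30k reads, ≈30% at 1k). Blanks are low biomass
  (LogNormal(log 800, 0.5)) and 99.9% contaminant mass — the standard
  picture of sequencing blanks — while the 10 contaminant taxa are
  nearly absent from specimens (≈5% prevalence), so prevalence-based
  flagging recovers essentially all of them with no false flags.
  A random bifurcating tree with exponential branch lengths and
  7-rank taxonomy strings (~30% unresolved below family) accompany
  the table.
- **Functions**: a sparse binary taxon×KO map (density 0.05), with
  3 private KOs per planted taxon so those functions inherit the
  taxon's DII association exactly; KO abundance = relative abundance ×
  map (×10⁴) with 10% multiplicative noise on non-zero entries;
  pathways aggregate KOs by a seeded assignment over the packaged
  gene-set names.
- The ZIG benchmark (`simulate_zig_dataset`) draws directly from the
  model: 200 samples × 100 features, 10 planted slopes of 0.5,
  exposure SD 2, noise SD 1, library-size-driven zeros (~17% overall).

What the generator does **not** emulate: real taxon co-occurrence and
phylogenetic signal, compositional constraints beyond the multinomial,
overdispersion structure of real 16S counts, realistic KEGG topology,
or batch effects on counts (a batch label exists for confounding
checks only). Passing recovery tests therefore demonstrates that the
estimators work when their assumptions hold — not that real cohorts of
n = 47 provide comparable power.

## Problem sizes used in tests and the acceptance script

Recovery and calibration runs use the sizes stated above (ZIG: 200
samples × 100/500 features, 20 null replicates; decontamination: 20
seeded 47-subject cohorts with 300 taxa; PERMANOVA: 200 null
simulations of 40 samples at 99 permutations). These were chosen as
the smallest sizes at which the estimators' asymptotic behavior is
visible and stable.

## Known limitations

- The ZIG variance is unmoderated and the zero model uses log library
  size only; features observed in very few samples get noisy variance
  estimates.
- PERMANOVA assumes exchangeability of reduced-model residuals; strong
  heteroscedasticity across covariate strata can distort calibration.
- The decontamination score is a tail probability, not a posterior;
  with very few controls its resolution is coarse (multiples of the
  hypergeometric support).
- Count tables are TSV-only (features × samples); BIOM files should be
  exported to TSV upstream.
- The 27-parameter reference covers only the nutrients both FFQ
  instruments report; scores are therefore compressed relative to the
  full 45-parameter index.
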