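# Methods

## Setting

`mrkit` implements two-sample Mendelian randomization (MR) on GWAS summary
statistics. Genetic variants serve as instrumental variables: a SNP that
(i) associates with the exposure, (ii) is independent of confounders, and
(iii) affects the outcome only through the exposure identifies the causal
effect of the exposure on the outcome from two independent GWAS — one for
the SNP–exposure effects `(β_xj, se_xj)` and one for the SNP–outcome
effects `(β_yj, se_yj)`. The package was built around a study design of
the kind used for gut-inflammation exposures (inflammatory bowel disease
and its subtypes, circulating IL-6 and IL-6Rα) against 70 cerebral-cortex
phenotypes (global and 34 regional surface-area and thickness measures),
but every component is generic over exposures and outcomes.

## Harmonization

All estimators consume effect pairs expressed for the *same* effect
allele. Outcome records are mapped onto the exposure's orientation: a
swapped allele pair negates the outcome beta; a strand-complemented pair
is complemented first and then treated the same way. Magnitudes are never
rescaled — harmonization is a pure sign/orientation operation, and every
shared SNP ends up exactly once in the harmonized records or the dropped
list (with a reason).

Palindromic SNPs (A/T, C/G) cannot be oriented from allele letters. They
are oriented by allele frequency — kept when both effect-allele
frequencies fall on the same side of 0.5 — and only when both minor-allele
frequencies are below `palindrome_eaf_limit` (default 0.42, the prevailing
two-sample-MR convention); otherwise dropped as ambiguous. When either
frequency is missing, only exact or swapped same-strand matches are
accepted: a strand flip cannot then be distinguished from opposite-strand
genotyping, and we prefer dropping a SNP to silently mis-orienting it.
Duplicate rsIDs within one file keep the record with the smallest p-value.
Indels and multi-allelic records are rejected at read time; the package is
deliberately SNP-only.

## Instrument selection

Stages run in a fixed order, each only removing SNPs, with an audit count
per stage:

1. **Significance**: exposure p < `p_threshold` (default 5e-8; 5e-6 is the
   conventional relaxation for exposures with too few genome-wide hits,
   retained only together with the F > 10 floor).
2. **LD independence**: greedy clumping — the remaining SNP with the
   smallest p-value becomes an index SNP and removes all same-chromosome
   SNPs within `clump_kb` (default 10000 kb) with pairwise r² ≥ `clump_r2`
   (default 0.001). LD comes from a user-supplied pairwise r² table
   (3-column or square-matrix TSV); absent pairs count as r² = 0. No
   reference-panel processing is performed — supplying the r² table
   replaces a PLINK dependency while preserving the algorithm. Ties on
   p-value break by lexicographic rsID, so output is independent of input
   order.
3. **Confounder exclusion**: a user-supplied `(snp_id, reason)` list
   (e.g. variants associated with obesity, hypertension, smoking or other
   phenotypes that could open alternative causal paths) is subtracted,
   with reasons logged. Database lookups (e.g. PhenoScanner) are the
   user's responsibility; the package consumes the resulting list.
4. **Instrument strength**: per-SNP explained variance is
   `R² = 2·MAF·(1−MAF)·β²` when the allele frequency is known and the
   fallback `R² = β²/(β² + se²·n)` otherwise (the two agree to relative
   order R² under the SE model below). The F-statistic is
   `F = (R²/(1−R²))·(n−k−1)/k`.

The weak-instrument screen drops SNPs with per-SNP F (k = 1) below
`f_min = 10`. This is a deliberate choice: with per-SNP R², setting k to
the set size makes F ≈ χ²/k, so any realistically sized panel of
genome-wide-significant instruments would be declared uniformly "weak" —
the F < 10 rule is calibrated for a single variant's strength. Strength
statistics at k = final set size are still computed and reported alongside
the k = 1 values.

## Estimators

Let `w_j = 1/se_yj²` and `r_j = β_yj/β_xj` (Wald ratios, with weights
`v_j = β_xj²/se_yj²` — the inverse first-order variance of `r_j`).

* **IVW** (primary): weighted regression of β_y on β_x through the origin,
  `β̂ = Σ w β_x β_y / Σ w β_x²`, algebraically identical to the v-weighted
  mean of Wald ratios. Fixed-effects SE is `√(1/Σ w β_x²)`; the
  multiplicative random-effects (mRE) variant multiplies it by
  `√(max(1, Q/(J−1)))` with Q Cochran's statistic, so heterogeneity can
  only widen the interval (the floor at 1 is the conservative convention).
  J = 1 returns the Wald ratio with the first-order delta SE
  `se_y/|β_x|`; the second-order term is omitted (documented constant).
* **Weighted median**: sort ratios ascending, form standardized midpoint
  cumulative weights `s_j = (Σ_{i≤j} v_i − v_j/2)/Σ v`, and linearly
  interpolate r against s at 0.5 (clamping to the extreme ratios outside
  `[s_1, s_J]`). Consistent when instruments carrying ≥ 50% of weight are
  valid. The SE comes from a parametric bootstrap (default 1000 draws of
  both effect vectors from normals at their observed values with their
  SEs); the bootstrap seed is a required argument — there is no implicit
  global randomness anywhere in the package.
* **MR-Egger**: orient every SNP so β_x ≥ 0 (negating both effects where
  needed — making the fit invariant to effect-allele choice), then
  weighted least squares of β_y on β_x with a free intercept. The slope
  estimates the causal effect under InSIDE; the intercept estimates
  average directional pleiotropy. SEs carry the multiplicative
  overdispersion `√(max(1, RSS_w/(J−2)))` and p-values use t(J−2).

P-values are two-sided: standard normal for IVW and the weighted median,
t(J−2) for Egger. These reference distributions follow the originating
methods literature. P-values are floored at 1e-300 to stay inside (0, 1].

The three estimators are exposed both as scikit-learn-style estimator
classes (`IVWEstimator`, `WeightedMedianEstimator`, `EggerRegression`,
with `fit`, `get_params`/`set_params` and trailing-underscore fitted
attributes) and as one-call functions over a `HarmonizedSet`.

## Sensitivity battery

* **Cochran's Q** over Wald ratios, `Q = Σ v_j (r_j − β̂_fixed)²`, p from
  χ²(J−1). Q equals the weighted RSS of the origin-forced regression at
  its solution (asserted as an algebraic identity in the tests). When
  Q's p < 0.05 the primary estimate is the mRE IVW — which the pipeline
  reports as primary in all cases, so heterogeneity can never silently
  sharpen an interval.
* **MR-Egger intercept test**: the intercept component of the Egger fit;
  p < 0.05 flags directional pleiotropy.
* **MR-PRESSO**: the observed statistic is the weighted residual sum of
  squares of each SNP against its leave-one-out IVW prediction. The null
  distribution comes from `n_sim` (default 1000) parametric simulations
  redrawing both effect vectors around the leave-one-out fitted values.
  Per-SNP residual contributions give one-sided outlier p-values,
  Bonferroni-corrected over J (config-switchable; the 0.05 outlier rule
  is then applied to the corrected values); flagged SNPs are removed
  before estimation. When outliers exist, a distortion test compares the
  observed change in the IVW estimate after removal against removing
  random same-size SNP subsets (a permutation convention of this package;
  the originating method bootstraps inlier subsets, and neither the exact
  reference distribution nor its seed is ever printed in applied work).
  A global p of zero exceedances is reported as the upper bound
  `1/n_sim`. With a fixed seed the whole procedure is bit-reproducible.
* **Leave-one-out**: the mRE IVW refit with each SNP removed in turn
  (computed in closed form from partial sums). The analysis passes when
  every refit keeps p below the significance threshold *and* keeps the
  full-set sign. The default threshold is 0.05; for pairs reaching the
  significant tier the pipeline re-evaluates at the level's Bonferroni
  threshold, and a failure there demotes the pair to nominal. Both
  thresholds are config keys because published "Yes/No" leave-one-out
  columns rarely state which was used.
* **Funnel data**: per-SNP `(r_j, |β_xj|/se_yj)` pairs, emitted as a
  table; a matplotlib helper renders the plot but is not part of the
  tested contract.

## Study pipeline and classification

A study is a grid of exposures × outcomes, each outcome assigned to the
regional family (Bonferroni threshold `0.05/68` ≈ 7.35e-4 for a
34-region × 2-measure atlas; the count is configurable) or the global
family (`0.05/2` = 0.025). Per exposure, instruments are selected once;
per pair: harmonize → MR-PRESSO outlier removal → IVW (mRE, primary),
weighted median, MR-Egger → sensitivity battery → classify:

* **significant** — IVW p below the family threshold, WM p < 0.05, WM and
  Egger slopes in the same direction as IVW, Q p ≥ 0.05, Egger-intercept
  p ≥ 0.05, and leave-one-out passed (also at the family threshold).
* **nominal** — IVW p < 0.05 without meeting all of the above.
* **null** — otherwise.

The heterogeneity/pleiotropy gates are included in the significant tier by
default (the stricter reading of the rule, which published significant
rows satisfy); `require_sensitivity_gates=False` gives the
consistency-only reading. Pairs with fewer than three instruments lack the
consistency estimators and cap at nominal (a single-instrument exposure
still yields a Wald ratio, so sparse exposures are processed rather than
dropped). Classification is monotone: improving any one criterion never
demotes a pair. Pairs that cannot be evaluated are reported as
`not_evaluable` with the cause. Reports (`results_long.tsv`, a filtered
significant+nominal table with columns exposure/outcome/beta/se/ivw_p/
q_p/intercept_p/loo, and an audit log) are deterministically ordered, and
identical seeds give byte-identical files. Exposure–outcome sample overlap
is not modelled; a config field records an assumed overlap in the report
metadata for the reader.

## Synthetic GWAS generator

The generator emulates the statistical structure of large summary-level
GWAS without any external data:

* Per-SNP MAF uniform on `maf_range` (default (0.05, 0.40), keeping
  palindromic SNPs frequency-resolvable); standard errors follow
  `se = 1/√(2·maf·(1−maf)·n)`. Default sample sizes (60000 exposure,
  51665 outcome) follow the scale of large disease and imaging GWAS
  meta-analyses.
* Per-SNP explained exposure variance uniform on `exposure_h2_range`
  (default (0.0005, 0.02)): real instrument panels mix a few major loci
  (cis-pQTLs, major disease genes at the percent level) with many
  moderate ones. The spread matters: with near-equal effect sizes,
  exposure-side measurement error dilutes slope-based estimators
  (MR-Egger especially), which would confound a test of the
  implementation with a violation of the estimator's own validity
  conditions. All true instrument effects are positive, i.e. effect
  alleles are exposure-increasing — the orientation under which
  directional pleiotropy is a meaningful concept.
* True outcome effects `c_j = θ·b_j + a_j` with pleiotropy `a_j` per
  regime: `none`, `balanced` (mean 0), `directional` (mean μ ≠ 0, both
  independent of `b_j`, so InSIDE holds and the closed-form IVW bias is
  `μ·Σw b/Σw b²`), or `inside_violating` (`a_j ∝ b_j`).
  `pleiotropy_fraction` restricts the regime to a subset of instruments
  (invalid-instrument designs). Outlier SNPs displace `c_j` by
  `outlier_scale` outcome-SEs (i.e. the same number of ratio-SEs).
* Observed effects are normal draws around the truths; the exposure is a
  continuous unit-variance trait (at summary level a binary exposure's
  log-odds scale is a relabelling). The two samples are independent —
  sample overlap is not simulated.
* Allele columns make a configurable fraction palindromic (A/T) and flip
  a fraction between files (swapped alleles, negated beta, 1−eaf) so
  harmonization is exercised; the effect allele is the minor allele, so
  frequency orientation is exact. Optional LD blocks add equicorrelated
  noise within blocks and emit the pairwise r² table for clumping.
* All randomness flows through one seeded generator per call; fixed seeds
  reproduce outputs byte-for-byte.

What the generator does **not** emulate: realistic allele-frequency
spectra, liability-scale case-control effects, winner's-curse in
instrument discovery, correlated (confounder-driven) pleiotropy, or
exposure–outcome sample overlap. Passing tests therefore demonstrate
correctness and calibration of the *methods* under their stated
assumptions, not robustness of real-data conclusions to those
violations.

## Verification conditions (problem sizes)

The test suite and `scripts/acceptance.py` run the pipeline at desk
scale, chosen so each check is statistically informative while the whole
suite stays fast: 200 random 10-SNP sets for oracle agreement (1e-10),
1000 null replicates at J = 50 for type-I error of IVW and Q, 500
replicates for parameter recovery (θ = 0.2) and for directional-pleiotropy
bias (μ = 0.01) against the closed-form prediction, 500 replicates for
weighted-median coverage with 40% invalid instruments (balanced direct
effects, sd 0.02), 200 replicates for MR-PRESSO detection (one 10-SE
outlier among 20 SNPs) and specificity, 12 replicate 2×6 planted studies
end to end, and 200 all-null replicate studies of 68 regional tests for
family-wise error of the significant tier. In the family-wise-error runs
MR-PRESSO is skipped: on clean data at Bonferroni-corrected outlier α it
is a measured no-op, and the classification outcome is unchanged.

## Numerical choices

Closed-form normal equations throughout (no iterative fitting); leave-one-
out fits by subtraction from global sums; p-values floored at 1e-300;
weighted-median interpolation clamps outside `[s_1, s_J]`; clumping ties
break lexicographically; zero exposure effects raise degenerate-ratio
errors naming the SNP rather than propagating infinities; the weighted
median and MR-PRESSO refuse to run without an explicit seed.

## Known limitations

SNP-only (no indels), no reference-panel LD computation, no VCF ingestion
or liftover, no mode-based/robust-regression estimators beyond the three
above, no multivariable or bidirectional MR, no mediation, and no
correction for sample overlap. The MR-PRESSO distortion test's reference
distribution is a package convention (see above) — its p-values are
comparable within, not across, implementations.
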