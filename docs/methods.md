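# Methods

`gutpheno` implements an integrative disease-prediction workflow for gut
microbiome case-control cohorts: a healthy control group plus one or more
disease groups, a genus-level 16S count table, and a mixed table of
quantitative (nutrient intake, body composition) and qualitative (lifestyle)
phenotype variables.  The question the workflow answers is not "which genera
differ in abundance?" but "how well do genera — alone, and together with
host phenotypes — *predict* each disease?".

## Pipeline

1. **Candidate screening** (`gutpheno.preselect`).  Per disease-vs-control
   contrast: genera by a negative-binomial Wald test on normalized counts
   with Benjamini-Hochberg adjustment (candidates at adjusted p < 0.05);
   quantitative variables by Kruskal-Wallis across all cohort groups
   followed by rank-based many-to-one comparison against the control with
   Holm adjustment (a direct Mann-Whitney when only two groups exist);
   qualitative variables by Pearson's chi-square on the level-by-group
   contingency table.
2. **Community structure** (`gutpheno.diversity`).  Bray-Curtis,
   Jensen-Shannon (base-2 divergence) and raw weighted UniFrac on relative
   abundances; PCoA by Gower double-centering; one-factor PERMANOVA with a
   seeded permutation p-value and R².
3. **Bootstrap variable filtering** (`gutpheno.bootstrap`).  Fifty rounds of
   stratified half-splitting (training half gets the extra sample on odd
   classes).  Each round fits a 100-tree Gini random forest on one candidate
   block (taxa / quantitative / qualitative / integrated), records
   unnormalized mean-decrease-Gini importances, mean |SHAP| on the held-out
   half, the top-10 features, and test ROC/AUC.  The frequency matrix counts
   top-10 membership per feature across rounds.
4. **Final selection and consensus models** (`gutpheno.evaluate`).  Features
   reaching the top ten in at least 25 of 50 rounds for at least one disease
   enter the final model (inclusive threshold).  The consensus model refits
   a forest per half-split resample on the final variables; each sample's
   score is its mean out-of-sample predicted case-probability, so no score
   is ever produced by a model that trained on that sample.  AUC (percent)
   is banded weak [0,60), regular [60,70), good [70,80), excellent [80,100].

## Statistical choices

**Differential abundance.** Size factors are median-of-ratios over taxa
observed in every sample (geometric-mean reference, factors normalized to
geometric mean 1), with a positive-counts fallback when no taxon is
ubiquitous.  Per-taxon dispersion is a pooled within-group moment estimator
with the bias-corrected denominator `mu^2 - var/n`; the plain `mu^2`
denominator biases dispersion downward and measurably inflates the extreme
tail of the Wald statistic (we measured the probability of any BH discovery
on a fully null cohort at ~0.11-0.12 versus the 0.05 BH bound; with the
correction and a t reference it is ~0.03-0.05).  Two-sided p-values
therefore use a t reference with n1+n2-2 degrees of freedom rather than a
normal: dispersions estimated from modest group sizes make the null
statistic t-like.  No dispersion shrinkage across taxa, no fold-change
moderation and no outlier filtering are performed — this is a deliberately
light-weight screen whose calibration and power are verified by simulation,
not a reimplementation of a full differential-abundance framework.  Taxa
present in fewer than 10% of samples are dropped before testing
(configurable).  Taxa with an all-zero group get a signed infinite
fold-change, an undefined p, and are excluded from the BH family.

**Rank-based post hoc.** The many-to-one stage after Kruskal-Wallis is a
Mann-Whitney per disease with Holm adjustment.  A classical many-to-one
procedure assumes normal errors; the rank-based form preserves the intent
(each disease against the same control, familywise-controlled) while
staying nonparametric.

**PERMANOVA.** Pseudo-F is computed directly from the distance matrix
(among/within sums of squared distances); labels are permuted freely
(single-factor design, no strata); p is reported as (1 + exceedances) /
(n_perm + 1) and can never be zero.  R² is independent of the permutation
count.

**Forests.** mtry is tuned on the training half only, by repeated
stratified k-fold CV (default 5 folds x 20 repeats) over the grid
{sqrt(p)/2, sqrt(p), 2 sqrt(p)}; the held-out half never enters tuning.
Gini importance is the cover-weighted impurity decrease summed per tree and
averaged over the forest, *unnormalized*, matching the mean-decrease-Gini
convention; one-hot columns are summed back to their parent variable so
selection operates at the variable level.  Class imbalance is left as-is
(no reweighting): the sensitivity/precision trade-offs on imbalanced test
halves are part of the reported behaviour.  Missing phenotype values are
imputed from the training half only (median; one-hot encoding makes this a
mode for categoricals).

**SHAP.** Attributions use an exact path-dependent tree-Shapley algorithm
(polynomial in tree size) written in-package; conditional expectations
follow the trees' training covers.  Additivity (base value plus
attributions equals the predicted probability) holds to ~1e-15 and the
implementation is verified against a brute-force enumeration over all
feature coalitions on small trees.  SHAP is computed on the held-out half
(out-of-sample attributions) and can be disabled per run when only Gini
importances are needed.

**Ties and determinism.** Top-k ties break by ascending feature name.  All
randomness flows from a single seed through named `SeedSequence` streams:
the generator uses one stream per component (counts, quantitative,
qualitative, tree), the engine one pair of seeds per round.  Two runs with
the same configuration are bit-identical.

## The synthetic cohort generator

The generator (`gutpheno.cohort`) emulates the statistical structure the
analysis assumes, with stored ground truth:

- **Counts**: Dirichlet-multinomial per sample.  The baseline concentration
  vector is a power-law ranked abundance profile; a sample's disease group
  multiplies planted taxa by 2^log2FC.  Total concentration mass governs
  overdispersion (mass 50 in the default cohort, dispersion ~0.02; the
  acceptance experiments use mass 30 for calibration runs and mass 150 for
  recovery runs — all within the range seen in real 16S genus tables).
  Library sizes are uniform in a range (default 5,000-20,000 reads),
  emulating uneven depth without modelling it.
- **Phenotypes**: quantitative variables are Gaussian with group-shifted
  means, redrawn at negative values (intakes and body composition are
  nonnegative); qualitative variables are categorical with group-dependent
  level probabilities.
- **Phylogeny**: random successive coalescence with exponential branch
  lengths, for weighted UniFrac.
- **Default design**: 50 controls and seven disease groups (two IBD
  subtypes at 20 each, psoriasis / rheumatoid arthritis / lupus / type-1
  diabetes at 20, type-2 diabetes at 32), 202 subjects in total; 60 genera
  with four planted mixed-sign effects per disease (|log2FC| 1.4-2.1, some
  genera shared across diseases); 12 quantitative and 4 qualitative
  variables with shifts patterned on a multi-disease cohort (e.g. strong
  anthropometric shifts for type-2 diabetes, all-female lupus group).

What the generator deliberately does **not** emulate: taxon-taxon
correlation beyond compositional closure, phylogenetic signal in planted
effects, covariance between phenotypes and microbiome within a group,
longitudinal or batch structure, and missing data.  Passing recovery tests
therefore demonstrate that the machinery detects the effects it is pointed
at under clean compositional noise — not that the pipeline is robust to
every artefact of real cohort data.

### Planted-effect placement in recovery experiments

Two structural lessons are baked into the recovery fixtures and worth
knowing when designing simulations with this package:

- Planting same-signed fold-changes on taxa that jointly hold a large share
  of the baseline composition (roughly >20-25% after boosting) makes the
  signal compositionally non-identifiable — "5 taxa up" and "everything
  else down" explain the same data, and median-of-ratios normalization can
  resolve the ambiguity either way.  Realistic disease signatures mix
  enriched and depleted genera; so do our fixtures.
- At high overdispersion (Dirichlet mass ~30), depleting a ~1% genus by
  2^2.5 is statistically marginal with 40 samples per group; experiments
  that assume near-certain detection of "strong" effects use the
  moderately-dispersed regime (mass 150).

## Problem sizes

Defaults follow the analysis they implement (50 rounds, 100 trees, 20x5
repeated CV for mtry).  The test-suite and acceptance-script experiments
run the same code paths at reduced cost chosen as part of the experimental
design: mtry tuning off and SHAP off where neither is the property under
measurement, 99-permutation PERMANOVA over 1,000 null datasets,
20-replicate calibration and power runs, 10-cohort recovery and null
experiments at 50 engine rounds each, and 10-seed consensus comparisons at
50 resamples.

## Known limitations

- The Wald screen is a calibrated simplification; it does not reproduce any
  specific differential-abundance package's numbers.
- The consensus score averages a variable number of out-of-sample
  predictions per sample (binomial across resamples); for very small
  cohorts single samples can be held out only a handful of times.
- PERMANOVA assumes exchangeability under the single-factor design; no
  strata or covariates.
- Weighted UniFrac is the raw (unnormalized) variant; values scale with
  branch lengths and are not bounded by 1.
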