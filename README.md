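# gutpheno

Integrative disease prediction from gut microbiota and host phenotypes.

Case-control microbiome studies routinely report genera whose relative
abundance differs between a disease group and healthy controls, but such
taxa rarely survive as clinical markers: gut composition is highly variable
between people and between studies.  `gutpheno` implements the alternative
workflow that treats differentially abundant taxa only as *candidates* and
asks how well they — alone, and integrated with host phenotype variables
(nutrient intake, body composition, lifestyle) — actually **predict** each
disease.  It is aimed at microbiome researchers who have a genus-level 16S
count table, a phenotype table and group labels, and want a reproducible,
seeded pipeline from screening to ROC curves.

## The method

For each disease *d* versus the control group:

1. **Screen candidates.**  Genera: negative-binomial Wald test on
   median-of-ratios-normalized counts, Benjamini–Hochberg adjusted
   (candidate if *p*adj < 0.05).  Quantitative phenotypes: Kruskal–Wallis
   gate across all groups, then a rank-based disease-vs-control comparison
   with Holm adjustment.  Qualitative phenotypes: chi-square test.
2. **Bootstrap forest filtering.**  For *r* = 1…50 rounds: split each class
   randomly in half (train/test), fit a 100-tree Gini random forest on the
   candidate block, and record the 10 features with the largest mean
   decrease in Gini impurity.  Mean |SHAP| values on the test half provide
   an independent importance measure whose per-feature correlation with the
   Gini trajectory validates the ranking.  The **frequency matrix**
   *F*[feature, disease] counts top-10 appearances across the 50 rounds.
3. **Select final variables.**  Keep every feature with
   *F*[feature, d] ≥ 25 for at least one disease ("top-10 in at least half
   the rounds").
4. **Consensus evaluation.**  Refit forests over 50 seeded half-split
   resamples on the final variables; each sample's consensus score is its
   mean predicted case-probability over the resamples in which it was held
   out (every score is out-of-sample).  Report ROC, AUC (percent),
   sensitivity/specificity/precision/recall, and a discrimination band —
   weak [0, 60), regular [60, 70), good [70, 80), excellent [80, 100] —
   comparing taxa-only against integrated models.

Community macrostructure is quantified alongside: Bray–Curtis,
Jensen–Shannon and weighted UniFrac distances on relative abundances, PCoA,
and a PERMANOVA of group effect (pseudo-F, R², permutation p).

A fully parameterized synthetic-cohort generator (Dirichlet–multinomial
counts with planted fold-changes, group-shifted phenotypes, random
phylogeny, stored ground truth) makes every stage testable without any
deposited data; its default design is a 202-subject cohort (50 controls,
seven disease groups).  See `docs/methods.md` for the statistical details
and design decisions.

## Worked example

Run the whole pipeline on the default synthetic cohort (reduced round count
for a quick run):

```sh
gutpheno run --out scratch/demo --seed 2 --n-rounds 8 --threshold 4 --quick
```

which logs each stage and finishes with `pipeline complete: scratch/demo`.
The output directory contains the cohort tables, candidate sets, distance
matrix, PCoA, PERMANOVA, the importance-frequency matrix, final variables
and the comparison report.  For the same run in Python:

```python
>>> import json
>>> report = json.load(open("scratch/demo/comparison_report.json"))
>>> row = report["diseases"]["T2D"]
>>> print(round(row["isolated_auc"], 2), row["isolated_band"])
95.62 excellent
>>> print(round(row["integrated_auc"], 2), row["integrated_band"])
100.0 excellent
>>> [v["variable"] for v in row["top_variables"]][:4]
['bmi', 'fat_mass_pct', 'taxon_04', 'weight_kg']
```

Reading: genera alone already separate the synthetic type-2-diabetes group
from controls (isolated AUC 95.6%), and integrating the planted
anthropometric variables lifts the consensus model to 100% — the direction
the workflow is designed to expose.  `permanova.json` from the same run
shows the group effect explains a modest share of community variation
(R² ≈ 0.19, p = 0.001 on the default cohort) even where prediction works
well — differential structure and predictive power are different
questions.

Each stage is also available as a subcommand (`simulate`, `preselect`,
`diversity`, `bootstrap`, `integrate`, `report`) operating on the TSV/JSON
artifacts, and as plain library calls (`gutpheno.preselect.select_candidates`,
`gutpheno.bootstrap.run_bootstrap_rounds`, ...).

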