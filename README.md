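# histpheno

Statistical curation and validation of **unbalanced historical phenotypic
data from genebank seed regeneration**, built around the workflow used for
multi-decade barley collections: flowering time (FT, days), plant height
(PH, cm) and thousand grain weight (TGW, g) recorded plot by plot whenever an
accession was regenerated.

Such data are severely non-orthogonal: an accession may appear in 1–22 of ~70
years, yearly campaign sizes range from a dozen to thousands of plots, ~1% of
accession-years carry duplicate plots, and which accessions appear in which
years follows genebank entry cohorts rather than any experimental design.
`histpheno` provides the pieces needed to turn such records into reusable
trait estimates, and the simulation machinery to verify that each piece does
what it claims.

## The model

Every analysis rests on one linear mixed model for a plot-level record of
accession *i* in harvest year *y*:

```
value_iyr = mu + g_i + u_y + e_iyr ,   Var(e_iyr) = sigma2_e,y
```

with **year-specific error variances** (seven decades of changing protocols
and weather make residual spread anything but constant).  Three variants are
fitted by REML (average-information updates with EM fallback):

| variant | genotypes | years | used for |
|---|---|---|---|
| BLUE model | fixed | random | adjusted means (BLUEs), outlier screening |
| variance components | random | random | genetic variance, heritability |
| year-fixed | random | fixed | per-year coefficient of variation |

On top of the engine:

* **Outlier curation** (`histpheno.curation`): standardized conditional
  residuals (per-year error SD), re-scaled by 1.4826 x MAD, two-sided normal
  p-values, step-down Bonferroni–Holm at family-wise level 0.05; flagged
  plots are removed and the model refitted on the *enhanced* dataset.
* **Summaries** (`histpheno.genetics_summaries`): entry-mean heritability
  `h2 = s2_G / (s2_G + s2_e_bar / Y_bar)` where `Y_bar` is the average number
  of distinct test years per accession; per-year CV
  `sqrt(s2_e,y) / year mean`; Pearson correlations between year pairs sharing
  >= 50 accessions; origin frequency tables.
* **Validation by resampling** (`histpheno.validation_resampling`): bias of
  variance components and BLUEs under three missing-data scenarios drawn from
  a balanced accession x year grid, and split-half precision of the BLUEs.
* **Synthetic data** (`histpheno.synthetic_data`): generator with known
  ground truth emulating the unbalanced structure (cohort-block missingness,
  duplicate plots, gross-outlier contamination).

## Worked example

The `analysis/` scripts run the whole pipeline on a simulated spring-FT-like
collection (300 accessions, 25 years, cohort-block missingness, 1% gross
outliers at +-8 error SD):

```
$ python analysis/01_simulate_dataset.py
wrote 1518 records for 300 accessions across 25 years -> results/synthetic
true contaminated records: 10

$ python analysis/02_curate_outliers.py
screened 1518 records; flagged 10
true contaminated: 10; caught: 10 (100%); false flags: 0
error variance (mean over years) before -> after: 21.37 -> 16.52

$ python analysis/03_genetic_summaries.py
historical: s2_G=25.44 s2_e_bar=21.48 E_bar=5.02 h2=0.86
enhanced:   s2_G=24.74 s2_e_bar=16.60 E_bar=4.98 h2=0.88
year CV (enhanced): mean 0.070 +- 0.017, range 0.033-0.106
year-pair correlations (>=50 shared accessions): mean r 0.58 over 31 pairs
```

Removing the ten planted gross errors cuts the average error variance from
21.4 to 16.5 squared days and lifts entry-mean heritability from 0.86 to
0.88 — outlier curation pays off directly in the precision of the released
means.  `analysis/04_bias_scenarios.py` shows that subsampling 3 of 6 years
(1,200 points per draw) leaves variance components essentially unbiased even
under clustered missingness, and `analysis/05_split_half_precision.py`
reports a mean split-half BLUE correlation of 0.75 at ~2.5 plots per
accession per half.

The same functionality is scriptable through a thin CLI
(`histpheno simulate|curate|fit-blues|summarize|validate`), which writes a
`manifest.json` with seeds, counts and convergence flags for every run.

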