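# Methods

## Model and estimation

All computations are built on the additive two-way mixed model for plot-level
records,

    value_iyr = mu + g_i + u_y + e_iyr,        e_iyr ~ N(0, sigma2_e,y),

with genotype effects g, year effects u, and a separate residual variance per
harvest year.  There is no genotype-by-year interaction term: with (mostly)
one plot per accession and year, interaction is confounded with error, and the
residual absorbs it.  Growth habits (winter vs spring) are never pooled in one
fit because flowering time is counted from different reference dates.

Variance parameters are estimated by restricted maximum likelihood.  The
implementation works entirely through the mixed-model equations: with
W = [X Z], R = diag(sigma2_e,y) and G the random-effect covariance,

    -2 l_R = (n - p) log 2pi + log|R| + log|G| + log|C| + y'Py,
    C = W'R^-1 W + diag(0, G^-1),   y'Py = y'R^-1 y - theta_hat' W'R^-1 y.

Updates are average-information (AI) steps with step halving; whenever an AI
step would leave the feasible region, fail to improve the restricted
likelihood, or the AI matrix is numerically singular, one EM step is taken
instead (EM is monotone in l_R, which the test suite asserts in pure-EM mode).
Components that reach the variance floor with a downhill gradient are held at
the boundary during AI updates ("boundary fixing"), which is what allows
degenerate toys to converge quickly.  The restricted log-likelihood is exposed
as a public function so that independent grid searches and the optimizer share
one definition; the test suite additionally recomputes it from the explicit
n x n covariance matrix to guard the identity above.

Numerical choices:

* **Stopping rule**: relative log-likelihood change < 1e-8 *and* maximum
  relative parameter change < 1e-6; at most 200 iterations.
* **Variance floor**: 1e-8 x total phenotypic variance.  Floored components
  are reported with a boundary flag and trigger a warning; on noiseless data
  all error variances sit at the floor by construction.
* **Identifiability**: internally, treatment coding with the first sorted
  level as reference; all reported quantities are estimable functions
  (adjusted means mu + g_i, year means mu + u_y), so they are invariant to the
  coding, to record order, and to which level happens to be the reference —
  each invariance is a test.
* **Error strata**: years with fewer than `min_year_n` (default 3) records
  share one pooled error variance rather than receiving their own.  This
  generalizes the manual removal of convergence-breaking sparse years; the
  removal itself is available as an explicit curation step
  (`drop_sparse_years`), never done silently by a reader.
* **Determinism**: fitting uses no randomness; any internal ordering is by
  sorted keys, so re-runs are byte-identical.

The dense-matrix implementation is sized for the validation studies this
package runs (up to a few thousand records and several hundred fixed genotype
effects per fit).  Collections with tens of thousands of accessions would
need genotype absorption / sparse solvers, which are out of scope here.

The engine was cross-checked against an independent REML implementation
(R nlme::lme with varIdent residual weights) on a frozen unbalanced fixture;
restricted log-likelihood, variance components and adjusted means agree to
that implementation's own convergence tolerance, and the frozen reference
values are part of the test suite.

## Outlier curation

Screening is a single detect -> remove -> refit pass of the BLUE model
(genotypes fixed, years random), not an iteration to convergence:

1. conditional residuals are standardized by the *fitted* error SD of their
   year stratum — the model itself declares year-specific variances, so
   studentization by hat-matrix leverage is not applied (a deliberate
   simplification; see limitations);
2. the standardized residuals are centered at their median and rescaled by
   1.4826 x MAD (the constant that makes the MAD consistent for a Gaussian
   SD; the centering uses the actual median rather than assuming 0);
3. two-sided standard-normal p-values enter a step-down Bonferroni–Holm test
   at family-wise level alpha = 0.05.  The family is one trait x habit
   dataset; families are never pooled across traits.

Flagged plots are removed, never corrected or imputed; conservation
(records in = kept + flagged) is asserted end to end.  If the MAD is zero
(degenerate spread) no record can be scored and nothing is flagged, with an
explicit flag on the report.

Two empirical properties are checked by simulation: under a correctly
specified null the family-wise false-flag probability stays below alpha
(500 replicates of 100 genotypes x 8 years at occupancy 0.5 give ~0.04,
comfortably conservative — residual shrinkage makes the nominal p-values
slightly conservative), and a single record shifted by 10 error SD on the
complete 100 x 8 grid is flagged in 100/100 replicates.

**Limitation**: on sparse designs the detector's power degrades for weakly
replicated genotypes.  A genotype observed once absorbs any shift entirely
into its own fixed effect (residual exactly zero — undetectable in
principle), and with two records roughly half the shift is absorbed.  The
power study therefore uses the complete grid, where leverage is homogeneous;
on occupancy-0.5 data the same +10 SD shift is caught in ~97% of cases, with
the misses concentrated in <= 2-record genotypes.

## Heritability, CV and correlations

Entry-mean heritability is computed as

    h2 = s2_G / (s2_G + s2_e_bar / Y_bar)

from the all-random fit, with s2_e_bar the *unweighted* mean of the per-year
error variances and Y_bar the average number of **distinct** years in which a
genotype was tested (duplicate plots within a year do not count twice).  The
formula is exact given its inputs; monotonicity in each argument is a
property test.

The per-year coefficient of variation comes from the year-fixed variant:
cv_y = sqrt(s2_e,y) / (mu + fixed year effect).  The denominator is the
estimated year *mean*, not the centered year effect — a centered effect near
zero would make the CV explode, contradicting the magnitudes this statistic
is expected to take (a few percent for flowering time).  Years with a
non-positive estimated mean (pathological) report an undefined CV with a
warning.

Year-pair correlations average within-year replicates first and then
correlate accession values between the two years of every unordered pair
sharing at least `min_overlap` (default 50) accessions; pairs below the
threshold are excluded from both the table and the pair count.  Origin tables
count accessions by their country string exactly as given (no geocoding or
name normalization), collapse origins past rank 22 into an
"Others (k origins)" row and close with a Total row.

## Resampling studies

The bias study extracts a balanced accession x year grid (accessions with at
least one record in every chosen year, replicates averaged) and deletes data
under three scenarios, each keeping exactly `n_years_kept` (default 3) years
per accession: independent random year draws per accession (S1), 10 random
accession clusters each sharing one random year set (S2), and origin groups
sharing year sets (S3) — the last mimics genebank entry cohorts.  Each
scenario is drawn 100 times; per draw, the variance-component and BLUE models
are refitted and compared with the balanced-grid fits via relative bias
(d_hat - d)/d and the regression of subsample BLUEs on balanced BLUEs
(intercept, slope, R^2).  Year sets for S2/S3 are drawn independently per
cluster.  Non-converged runs are excluded and counted, never imputed.

Split-half precision halves the dataset at the record (plot) level —
accessions with a single record fall into one half and drop out of that run's
correlation — fits the BLUE model in each half, and correlates the BLUEs of
accessions present in both.  One master seed drives all resampling;
per-run seeds are spawned via `numpy.random.SeedSequence`, so every run is
individually reproducible and runs are mutually independent.

## Synthetic data

The generator draws g ~ N(0, s2_G), u ~ N(0, s2_Y) and per-year error
variances uniformly from a range, then applies a missingness pattern
(independent Bernoulli occupancy; cohort blocks in which entry cohorts are
regenerated every `regen_interval` years; or origin-keyed blocks), adds a
second plot to ~1% of accession-years, and optionally contaminates a fraction
of records with +-`outlier_shift_sd` x local error SD mean shifts (the
"gross error" outlier concept).  Everything is recorded in a truth object
from which each generated value is exactly recomputable — a test asserts
bit-exact reconstruction.

The default preset is "spring flowering-time like": mu = 60 days, s2_G = 27,
s2_Y = 49, s2_e,y ~ U[9, 25] (squared days), 200 genotypes x 10 years at
occupancy 0.4 — magnitudes chosen to echo the variance components typical of
multi-decade flowering-time records.  Origins follow a long-tailed Zipf-like
categorical distribution over 30 labels so that origin-table tails and
origin-blocked scenarios are exercised.

What the generator does *not* emulate: genotype-by-year interaction,
non-Gaussian effect distributions, trends in year effects (they are i.i.d.),
measurement-protocol changes over time, and selection of which accessions
get regenerated based on their phenotype.  Passing tests on synthetic data
therefore demonstrate correctness of the estimation and screening machinery
under the stated model, not robustness to every failure mode of real
historical records.

## Problem sizes used in the checks

The simulation studies run at: 500 replicates of 100 genotypes x 8 years
(occupancy 0.5) for false-positive control; 100 replicates of the same grid,
complete, for power; 100 replicates of 200 x 10 (occupancy 0.4) for parameter
recovery; a 400 x 6 balanced grid with 100 draws per scenario for the bias
study.  These sizes give Monte-Carlo margins small enough for the assertions
they feed while keeping a full run of suite plus scripts in a few minutes on
one CPU.
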