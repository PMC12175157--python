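# Methods

This note documents the statistical procedures implemented in `qsarcons`,
the synthetic-data model used to validate them, the default parameter
choices, and the limits of what the tests demonstrate.

## Setting

The package evaluates an *ensemble of ensembles*: M independently developed
regression models predicting one experimental endpoint (TTR binding
activity, % probe displacement, observed range −41.6 to 110.9%). Each model
may carry an applicability domain (AD) mask and an ensemble standard
deviation per compound — the spread of its own sub-models' predictions —
which serves as a distance-to-model (DM) statistic: large spread marks
predictions far from the model's reliable region.

## Consensus averaging

Mode I averages all non-missing predictions per compound; mode II averages
only models whose AD contains the compound and is defined when at least
`min_models` models cover it. A model missing a prediction for a compound
is treated as not covering it, in both modes; this is one reading of how
ensembles trained on different subsets should enter a consensus, and the
alternative (imputation) is deliberately not offered. No performance
weighting is applied anywhere: the consensus is strictly unweighted, which
makes its central property exact rather than empirical — the consensus
residual is the mean of the individual residuals, so by the L2 triangle
inequality the consensus RMSE can never exceed the mean individual RMSE.
How far below it lands depends on the inter-model error correlation.

The Grubbs-refined variant applies the two-sided single-outlier Grubbs test
(default alpha 0.1, critical value from the Student-t formula, verified
against a Monte-Carlo null) to each compound's M predictions and drops at
most one before averaging. With fewer than three models the test is
undefined and the plain mean is used, with a logged warning.

The stringency sweep fits mode II for `min_models` = 2..M and reports R^2,
RMSE and coverage. Coverage is non-increasing by construction; RMSE is
non-increasing only insofar as AD membership tracks prediction difficulty,
which is an empirical property of the masks, not a theorem.

## Bin-based averaging and outlier flagging

Compounds are sorted by ascending DM. A bin is closed when it holds at
least `min_bin_size` compounds (default 50) **and** — unless it is the
first bin — its RMSE exceeds the previous bin's. The first bin therefore
closes at exactly `min_bin_size` (extended only to avoid splitting tied DM
values, which are never divided across a boundary). The trailing remainder
smaller than `min_bin_size` merges into the last bin. A terminal bin closed
only by running out of data can undercut its predecessor's RMSE; it is then
merged backward until the sequence is non-decreasing, so the fitted bin
table always shows the monotone error-versus-uncertainty profile the method
presumes. "Accuracy" within a bin is RMSE throughout, the package's sole
error statistic.

The flagging threshold is `z` times the bin RMSE, with `z = 3` by default —
the conventional large-residual multiple; the threshold multiplier is not
prescribed by the procedure itself and is exposed as a parameter. Flagging
uses a strict inequality, so an error exactly at threshold is kept. Bins
are intended to be fitted on training/cross-validated predictions and may
then be applied to test compounds; DM values outside the fitted range are
assigned to the nearest terminal bin and logged.

`ad_threshold` returns the empirical order statistic (the
`ceil(coverage*n)`-th smallest training DM, no interpolation), the vertical
cutoff drawn on Williams plots at 90% training coverage.
`cross_model_outliers` intersects per-model flag sets, keeping ids flagged
by at least `min_models` (default 3) models — consistent cross-model flags
are more plausibly data errors than model noise.

## Substructure significance

For each bit with support >= `min_support` (default 32) in the evaluation
set, the null hypothesis is that carrying the substructure does not affect
prediction quality. The subset's squared errors are rescaled by
`(RMSE_overall / RMSE_sub)^2` so the rescaled subset RMSE equals the
overall RMSE; `n_boot` (default 100,000) bootstrap resamples of subset size
from that rescaled pool form the null RMSE distribution. `p_improvement`
and `p_degradation` are the fractions of null RMSEs strictly below and
strictly above the observed `RMSE_sub`; ties count toward neither tail.
The resampling pool is the rescaled **subset** (the adjustment is applied
to subset errors); pooling from the full set instead is available via
`null_source="full"` since the choice is not forced by the procedure's
description. The smaller one-sided p, with its direction, enters a single
Benjamini–Hochberg pass across bits (backed by `statsmodels`; an
independent brute-force step-up implementation exists only in the tests);
`significant` means BH-adjusted p below the FDR level (default 0.05).
Per-bit random streams are derived from the master seed and the *bit
label*, so a scan is invariant to the column order of the bit matrix.

Calibration caveats, measured by the test suite: with the subset equal to
the full set the tails are not exactly 0.5/0.5 — the skew of the bootstrap
RMSE distribution shifts `p_improvement` to about 0.506 at n = 1000 — and
under strongly heavy-tailed squared-error distributions the bootstrap null
is mildly anticonservative toward "improvement" for subsets that miss the
extreme errors. Averaged over datasets at the generator's default
heteroscedasticity the pre-BH fraction of bits with `p_min < .05` stays
near the nominal 0.10 and BH reduces null discoveries to near zero, but
single heavy-tailed datasets can run a few points high; the BH pass and the
support filter are what keep the procedure's discovery list conservative.

## Enrichment and similarity

Actives are compounds with activity strictly above 20%. The enrichment
factor is the ratio of a group's prevalence among actives to its prevalence
among inactives; significance is the one-sided hypergeometric upper tail
(the exact over-representation test; the tool originally used for such
screens does not document its internal test, so this is an interpretation,
validated in the tests against exact tail summation). A group passes at
EF > 2.5 and p < .01, both strict. Display rounding is one decimal,
round-half-up; internal values are never rounded. Tanimoto similarity is
intersection-over-union of bit vectors (0 for two empty vectors); the
similarity summary reports per-query max and mean against the full training
set (no self-exclusion — query and training splits are disjoint) plus eCDF
coordinates.

## Synthetic-ensemble generator

The generator produces the structure the analyses assume, with all
randomness flowing from one seed through a single generator (fixed seed ⇒
byte-identical output).

* **Activities**: two-component truncated normal mixture, weights 0.8/0.2,
  means 15/60%, SDs 10/25%, truncated to [−41.6, 110.9] — most compounds in
  the 0–30% region with a long active tail, matching the screen's
  distribution shape.
* **Errors**: per compound, a log-normal difficulty scale
  `s_i = exp(N(0, difficulty_spread))` shared by all models
  (`difficulty_spread = 0.4`, about a three-fold error-scale range across
  the central 95% of compounds, consistent with the DM ranges seen on
  Williams plots); model m's error is
  `error_sd_base * s_i * (sqrt(rho) u_i + sqrt(1-rho) v_im)`.
  `error_sd_base = 20%` puts individual-model RMSEs near the ~21% typical
  of the evaluated models. `rho = error_correlation` defaults to 0.3:
  architecturally diverse model ensembles show low-to-moderate pairwise
  error correlation, and shared *data* error is modelled separately through
  planted outliers rather than folded into `rho`.
* **Sub-ensembles**: each model's `n_submodels_per_model = 10` sub-model
  predictions scatter around the model centre with SD `error_sd_base * s_i`
  and are mean-centred, so the stored prediction equals the sub-model mean
  exactly and the pairwise error correlation equals `rho` exactly. The
  ensemble STD column is their sample SD (ddof = 1) and tracks `s_i` — the
  DM is informative about error scale by construction.
* **Planted outliers**: each compound independently with probability
  `outlier_fraction = 0.04` (screens of this kind flag roughly 4–5% of
  compounds) has its *recorded* activity shifted by
  `outlier_error_shift = 60%` (about 3x the base error SD, the scale of the
  CV errors of flagged compounds in such analyses), sign chosen to stay in
  range. Predictions are built from the uncorrupted value, so every model
  mispredicts these compounds while their ensemble STD stays at baseline —
  the low-DM/high-error signature the BBA method targets.
* **Substructure bits**: random Bernoulli columns with per-bit prevalence
  uniform in 2–30%; planted effect bits occupy exactly
  `planted_bit_support` random compounds and multiply their carriers' error
  SD (errors only, not the sub-model spread, isolating a pure
  prediction-quality effect).
* **AD masks**: per model, the `ad_coverage` fraction of compounds with the
  lowest noisy ensemble STD (log-normal noise, sigma 0.3) — heterogeneous
  across models yet correlated with difficulty, so AD stringency buys
  accuracy.
* **Fingerprints**: eight random scaffold prototypes with per-compound bit
  flips, giving a realistic mix of close analogues and distant structures.
* **Experimental noise** is exposed as `experimental_noise_sd` (default 0)
  because the assay's inherent uncertainty is not known; any shared noise
  floor is otherwise absorbed into the correlated error term.
* **Splits**: largest-remainder allocation to train/leaderboard/test with
  default fractions 1012/200/300 of 1512, then a seeded permutation; split
  sizes are exact up to the rounding unit.

What the generator does **not** emulate: real chemistry (no molecular
structures; fingerprints and bits are statistical stand-ins), model bias
that varies systematically with activity, correlations between substructure
occurrence and difficulty other than the planted ones, and assay-specific
artifact mechanisms. Passing tests therefore demonstrate the correctness
and calibration of the *procedures* under their stated assumptions, not
that any particular real ensemble satisfies those assumptions.

## Problem sizes and numerical choices

The test suite exercises challenge-sized problems (1500–1512 compounds,
9 models) and scales Monte-Carlo loops to what the statistics require:
100 random ensembles for bin-structure checks, 10 seeds pooled for planted
outlier recovery, 5 datasets for scan calibration with `n_boot = 10,000`
(the default for production scans remains 100,000), 50 replicates for
planted-bit power, and brute-force oracle comparisons on exhaustive small
grids (hypergeometric tables with totals <= 30, 50x50 similarity
matrices, 1000 random BH vectors). Degenerate inputs are defined rather
than fatal wherever a sensible value exists: zero-variance Grubbs input and
sub-3 samples return "no outlier"; a zero-RMSE subset yields
`p_improvement = 0` with a degenerate-null warning; empty bit unions give
Tanimoto 0; empty result sets write no files. Bootstrap index generation is
chunked to bound memory at ~16 MB per operation regardless of `n_boot`.

## Known limitations

* The BBA bin count is data-driven and can be small (2–10 bins at
  n = 1500); thresholds are piecewise-constant in DM and coarse where the
  error-DM relation is steep.
* Outlier recall depends on the ratio of the activity-shift magnitude to
  the local bin threshold; planted data errors on high-difficulty compounds
  (large DM) are intrinsically harder to flag, and pooled recall near the
  0.6–0.7 range at the default settings reflects that, not an
  implementation deficiency.
* The bootstrap substructure test inherits the usual plug-in bootstrap
  biases for small supports and heavy tails (see calibration caveats
  above).
* Mode II requires AD flags for *every* model; partially AD-annotated
  ensembles must either drop unannotated models or use mode I.
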