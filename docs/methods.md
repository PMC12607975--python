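# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter for reproducing its
output.

## Problem setting

During black-tea rolling, leaf cells rupture and catechins oxidise into the
three pigment classes (TFs, TRs, TBs) whose contents are the targets. The
predictors are seven LCR parameters (Ls, Cs, Rs, Z, X, D, Q) swept over 30
frequencies from 0.02 to 100 kHz, flattened parameter-major into a
210-column row per sample. Columns are named `<code>_<freq>kHz` and the
layout bijection `index = parameter_rank · 30 + frequency_rank` is fixed;
frequencies are kept in kHz everywhere. Missing cells are rejected rather
than imputed: upstream acquisition averages triplicate reads and a missing
average indicates a failed measurement, not a recoverable gap.

## Pigment assay

The colorimetric systematic analysis computes, from the 380 nm absorbances
of fractions A–D:

    TF% = 2.25·E_C
    TR% = 7.06·(2E_A + 2E_D − 2E_B − E_C)
    TB% = 2·7.06·E_B

The formulas are linear, so the implementation operates on single
(replicate-averaged) quads. A noisy quad can push the TR expression
negative; the value is preserved and a warning emitted rather than clamping,
because silent clamping would bias the synthetic inversion round-trip
(`simulate_absorbances` inverts the system exactly at zero noise:
`E_C = TF/2.25`, `E_B = TB/14.12`, `E_A + E_D` from the TR equation with a
configurable A/D split).

## Synthetic rolling runs

The generator emulates the sampling design of the emulated study — 10 time
points at 0, 10, …, 90 min (the schedule includes the pre-rolling state,
which is the natural reading of "every 10 min" over a 90-min process) × 15
replicates = 150 samples.

* **Latent rolling state.** `s = g(t) + N(0, state_noise_sd)` with `g`
  piecewise linear in time, normalised to [0, 1], and slope multiplied by
  `inflection_gain` (default 2) after `inflection_min` (default 70 min),
  reproducing the reported late-rolling inflection.
* **Pigments.** Saturating-exponential curves
  `lo + (hi−lo)·(1−e^{−k s})/(1−e^{−k})` with (lo, hi, k) = (0.40, 1.25,
  2.2) for TF, (5.0, 11.0, 1.8) for TR, (3.2, 7.2, 2.0) for TB, plus
  Gaussian noise of 0.008 × range. Ranges sit in the literature ballpark
  for black tea; the curvature k was set once so that (a) an ordinary
  least-squares fit of pigment on the planted columns still exceeds
  R² = 0.99 (the planted cells must identify the pigments), while (b) the
  link remains visibly nonlinear, since a quadratic — the best a linear
  model can reach given the features below — leaves a residual ~2–3× the
  assay noise floor. That is the qualitative structure the study reports
  (the nonlinear SVR outperforming PLSR), built in as a design property of
  the fixture, not fitted to any numbers.
* **Features.** Every column has a frequency-dispersion baseline with the
  reported shapes (Ls rising with frequency; Cs, Rs, D falling; Q, Z
  unimodal; X anti-unimodal; all on a log-frequency axis, magnitudes O(1–10)
  arbitrary units). Only the planted informative cells — by default
  low-frequency Cs and Rs plus Ls and X cells spread over the sweep, 12 in
  all, echoing the parameters the selectors flagged in the emulated study —
  add `coupling·w_j·s + nonlinearity·v_j·s²` (signs following each
  parameter's rolling-time trend), plus iid Gaussian noise (sd 0.02) on all
  columns. With `noise_sd = 0, nonlinearity = 0` each informative column is
  exactly affine in `s`.
* **Determinism.** All draws come from one `numpy` generator seeded by
  `SimConfig.seed`; equal seeds give bit-identical datasets.

What the generator does **not** emulate: instrument drift and temperature
sensitivity, electrode-contact variability, correlated (rather than planted
iid) noise across neighbouring frequencies, replicate-specific chemistry,
and any physically calibrated dielectric model of leaf tissue. Passing
tests therefore demonstrate the correctness and internal consistency of the
pipeline on data with the assumed structure — not field performance on real
rolling runs.

A second, simpler benchmark (`planted_design`) provides iid Gaussian columns
with a linear planted signal (default 100 × 50, 5 informative columns,
noise 5% of signal sd). It exists because the rolling fixture's informative
cells are deliberately collinear (all driven by one latent state), so "full
recall" is not the right expectation there; on independent columns it is.

## Preprocessing and splitting

* **MSC** regresses each row on the calibration-mean row (`x = a + b·m`)
  and returns `(x − a)/b`; the whole 210-cell row is treated as one
  spectrum by default (per-parameter-block MSC is available behind
  `msc_per_block=True`, since the concatenated row is physically
  heterogeneous and the convention is genuinely open). A non-positive
  fitted slope is an error naming the row.
* **Min-Max** uses per-column calibration bounds; prediction rows may leave
  [0, 1]. A constant calibration column is an error naming the column.
* **Smooth** is a centered moving average (default window 5) applied within
  each 30-frequency parameter block, never across block boundaries; edges
  use shrinking windows, so constants are preserved exactly. No kernel was
  specified for the emulated workflow; an unweighted moving average is the
  minimal reading of "smoothing".
* **Order.** The split is computed first and every preprocessor is fitted
  on calibration rows only. The emulated study does not state its order;
  the leakage-free order is the defensible one.
* **Kennard–Stone** seeds with the two mutually farthest samples and
  greedily adds the max–min-distance sample; ties break toward the lower
  index, making the split deterministic. Mahalanobis distance uses the
  covariance of all samples with a ridge of 1e-6 × mean diagonal when
  Cholesky fails (with p = 210 > n = 150 it always does). The prediction
  count is `floor(n·(1 − fraction))`, giving exactly 100/50 at n = 150,
  fraction 2/3.

## Variable selection

All selectors share a fast NIPALS PLS1 engine (numba-compiled; one pass
returns coefficients for every component count, so per-fold component
choice by cross-validated RMSE up to 10 latent variables is cheap). The
inner component ceiling of 10 matches the PLSR ceiling.

* **CARS** (60 Monte-Carlo runs, 5-fold CV): each run samples 80% of
  calibration rows, fits PLS on the surviving variables, ranks
  |coefficients|, keeps the top `r_i·p` with `r_i = a·e^{−k i}` pinned at
  `r_1 = 1`, `r_N = 2/p`, then applies adaptive reweighted sampling
  (weighted draw with replacement, unique survivors). The visited subset
  with the lowest 5-fold RMSECV wins; per-variable selection frequencies
  are reported.
* **UVE**: p artificial noise columns (uniform, scaled to 1e-10 of the mean
  |X|) are appended; leave-one-out refits with 10 latent variables yield a
  coefficient matrix; stability = mean/sd over refits. The published
  threshold parameter 0.995 is ambiguous; it is read as the 0.995 quantile
  of the noise-column |stability| (the alternative, 0.995 × max noise
  |stability|, is available behind `uve_cutoff_rule="max_scaled"`). Under a
  null response this calibrates the false-retention rate of real variables
  to ≈ 0.5%.
* **VCPA-IRIV**: VCPA draws 1000 Bernoulli(0.5) sub-models per round
  (rows with < 2 variables are redrawn), scores each variable by its
  frequency among the best 10% of sub-models (5-fold RMSECV with inner
  component choice), and shrinks the space along a continuous exponential
  schedule from p to 100 over 50 rounds. IRIV then repeatedly draws a
  binary matrix (rows with < 3 variables redrawn so the flipped row stays
  valid) and, for each variable, compares sub-model RMSECV with the
  variable's bit on versus off — the same rows, one bit flipped, a paired
  design. A variable survives only when inclusion lowers RMSECV with a
  two-sided Mann–Whitney p < 0.05; rounds repeat until the set is stable,
  and backward elimination finishes (drop any variable whose removal lowers
  the full-subset RMSECV). The best-sub-model fraction (10%) and the 0.05
  level follow the originating literature's defaults; if every candidate is
  classified non-informative the single best-DMEAN variable is returned
  with a warning.

## Calibration and evaluation

* **PLSR**: NIPALS on column-centered data, no variance scaling; component
  count = argmin of 10-fold pooled out-of-fold RMSE, ceiling 10 (the
  ceiling visible in the emulated study's tables; whether they fixed or
  CV-selected the count is unstated, so CV selection with that ceiling is
  used). With all components on a full-rank tall design the fit equals
  ordinary least squares, which the tests exploit as an oracle; an
  independent NIPALS implementation (scikit-learn's) is the cross-check,
  never the pipeline path.
* **SVR**: features are z-scored with calibration statistics; ε = 0.01
  (unstated in the emulated workflow; small relative to every pigment's
  range); (c, g) from a base-2 grid 2⁻⁸…2⁸ by 10-fold RMSECV, then a
  refinement pass of quarter-exponent steps within ±1 octave of the coarse
  winner — the published winning pairs are off any pure power-of-two grid,
  so a refinement stage evidently existed.
* **Metrics**: R_cv and R_p are Pearson correlations between reference and
  predicted values (pooled out-of-fold for R_cv); RMSECV/RMSEP are the
  corresponding root mean squared errors; RPD = sd(prediction-set
  reference, n−1)/RMSEP, the most common chemometric convention (no formula
  was published). A constant prediction vector has undefined correlation
  and is reported as 0 with a warning; RMSEP = 0 yields an infinite RPD
  sentinel. Cross-validation runs on the calibration set only — the
  prediction set stays untouched end to end.
* **Pipeline**: one master seed drives the fold assignment (shared across
  all model combinations, so comparisons are paired) and per-(pigment,
  selector) seeds. Selections are cached per (pigment, preprocessor,
  selector) so PLSR and SVR reuse the same subset. A failing combination
  is logged and skipped without aborting the run. Reports serialise to CSV
  with fixed 6-decimal formatting, which is what makes repeated runs
  byte-identical.

## Numerical choices

* NIPALS stops extracting components when the residual covariance norm
  falls below 1e-12; requesting more components than the rank supports is
  safe and truncates with the last attainable model.
* `argmin` over RMSECV curves takes the first minimum — the smallest
  sufficient component count.
* K-S and VCPA frequency ranking break ties toward the lower column index
  (stable sorts throughout).
* The Mahalanobis ridge is 1e-6 × mean covariance diagonal.
* Fold assignment is a seeded permutation dealt round-robin, so fold sizes
  differ by at most one.

## Problem sizes in the test suite

The suite exercises the full protocol at the study scale once (150 × 210,
all 24 model combinations, full-scale selector settings: 1000 BMS draws ×
50 rounds; about six minutes on one core). Selector-recovery statistics run
on the 100 × 50 planted design over 20 seeds, with the BMS draw count
scaled to 400 for that 50-variable problem; the determinism check runs a
reduced grid (50 samples, scaled loop counts) twice, since the seeding
pathway is identical at every scale. Unit tests use further-scaled loop
counts; the algorithms themselves are never altered, only their iteration
budgets.

## Known limitations

* Because the generator's noise is iid across cells, smoothing buys little
  on the fixture and raw/MSC full-variable PLSR can edge out Smooth there;
  on real instruments with correlated high-frequency noise the ordering can
  differ. The fixture is not calibrated to reproduce any particular
  preprocessing ranking.
* The generator's planted informative cells are collinear by construction;
  selector recall on that fixture is intentionally not asserted (any subset
  spanning the latent state is a correct answer there).
* MSC on the heterogeneous 210-cell row is a convention choice; per-block
  MSC can behave differently on real data.
* The SVR refinement grid is local; a pathological CV surface could hide a
  better (c, g) between coarse nodes.
* IRIV's retention rule here requires statistical significance, which on
  very noisy data can be conservative relative to IRIV variants that retain
  non-significant positive-DMEAN ("weakly informative") variables.
* All performance figures produced by the tests and analysis scripts
  describe synthetic data with the assumed structure; they say nothing
  quantitative about measured rolling runs.
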