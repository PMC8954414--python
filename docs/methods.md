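# Methods

This note documents the models, the numerical choices, and the design
decisions behind `catbank`, and what the synthetic-data experiments do and
do not show.

## Response model and calibration

The generalized partial credit model (GPCM) gives
P_ik(θ) ∝ exp(Σ_{v≤k} a_i(θ − b_iv)) with the empty sum for k = 0.  We use
the slope–step parameterization throughout; fitted steps are allowed to be
disordered (disorder is informative: it signals never-modal categories, see
*Category collapsing*).  No scaling constant (D = 1.7) is applied anywhere;
all quantities, including the single-item EAP values asserted in tests, are
on the pure logistic metric.

Calibration is maximum marginal likelihood via EM:

- **Quadrature**: 61 equally spaced points on [−4, 4], standard-normal
  weights renormalized on the grid.  The grid is configurable; 61 points
  make the marginal likelihood accurate to well below the EM tolerance for
  banks in the discrimination range we target.
- **Identification**: the latent density is fixed at N(0,1); item
  parameters absorb all scale, matching the N(0,1) prior used for EAP
  scoring.
- **M-step**: per-item L-BFGS-B on (a_i, b_i) with analytic gradients of
  the expected complete-data log-likelihood; slope bounds [0.02, 20], step
  bounds [−8, 8].  The PCM (equal slopes) alternates per-item step updates
  with a bounded scalar search for the common slope — a generalized EM
  whose ascent property is asserted in tests.
- **Convergence**: max absolute parameter change < 1e-4, cap 500 cycles; a
  non-converged fit returns the last iterate with a warning flag.
- **Missingness**: missing and "not applicable" cells are both dropped from
  the affected item's likelihood term (ignorable missingness).  "Not
  applicable" is a distinct code on disk but is treated as missing in every
  analysis; nothing in the pipeline conditions on the distinction.
- **Unobserved categories** are collapsed away (with a warning and a
  recorded collapse map) before fitting, since their step parameters would
  be unidentified.

Model choice (PCM vs GPCM) uses the likelihood-ratio test with
df = n_items − 1 plus AIC/BIC deltas.  Item fit uses the
information-weighted infit mean square at EAP trait estimates.  Because EAP
estimates are shrunken and partly determined by the item under scrutiny,
infit at EAP runs slightly below 1 for the most discriminating items of
short banks; with ~21 items of moderate discrimination the statistic sits
comfortably in the conventional [0.7, 1.3] band, which is what the tests
assert.  Items with fitted a < 0.50 are reported as removal candidates.

## Scoring

EAP point estimate and posterior SD (SEM) on the same grid and prior as
calibration.  An all-missing pattern returns the prior (θ = 0, SEM ≈ 1).
The 0–100 reporting score is a fixed affine map: θ clipped to [−4, 4], then
(θ+4)/8·100.  The map is recorded in the bank's serialized metadata so
scores are comparable across runs; it is invertible inside the clip range.

## Category collapsing

A category is *never modal* if its fitted probability curve is nowhere the
maximum over a dense θ grid in [−4, 4] (401 points) — the grid-scan
equivalent of inspecting item characteristic curves for monotonicity.  Such
a category is merged into the adjacent category with the higher marginal
observed frequency, walking outward until a modal category absorbs the
merge.  After recoding, the model is refitted and AIC/BIC deltas
(final − initial) are reported.  Note these deltas compare likelihoods on
recoded data, as is conventional in this recoding procedure; merging
categories mechanically raises per-response probabilities, so the deltas
measure parsimony-adjusted improvement, not a nested test.

## Screening

Exclusion filters and defaults: missing share > 70%; extreme skew (> 95% of
responses in one category, or |bias-adjusted Fisher–Pearson g1| > 4);
inter-item Pearson correlation > 0.70 (pairwise-complete, on integer
codes — the polychoric matrix is reserved for the dimensionality stage).
For each flagged pair (processed in descending r), the member with the
higher mean absolute correlation to all other items is dropped; ties break
to higher missing rate, then higher item index.  This drop rule is a
determinism choice, not an empirical claim.  Cronbach's α uses
listwise-complete rows (the textbook definition; an α > 0.70 is the
conventional acceptance level).  Skewness is defined for items with at
least two distinct values and three observations; constant items are
flagged undefined.

## Dimensionality

Ordinal factor analysis is minimum-residual (minres) least squares on the
two-step polychoric correlation matrix (thresholds from the univariate
margins; ρ by bivariate-normal ML on each pairwise table, bounded scalar
search).  This is a deliberate, documented approximation to the
categorical-CFA estimators (e.g. WLSMV) of commercial SEM software: the
loading structure and eigen-structure are comparable, but the test
statistic is not mean-and-variance corrected, so fit indices are
discrepancy-based:

RMSEA = sqrt(max(χ²−df, 0)/(df·(n−1))) with a CI by non-central χ²
inversion; CFI and TLI from the independence baseline, both capped at 1.
χ² values use the ML discrepancy of the minres solution — adequate for the
structural comparisons made here, not a replication of any specific SEM
package.  Non-positive-semi-definite polychoric matrices are
eigenvalue-smoothed with a warning.

Parallel analysis permutes each item's column independently (breaking
inter-item structure, keeping margins) and compares observed eigenvalues to
the 95th percentile over 100 replicates by default; Pearson correlations
are used inside the permutation loop for speed (polychoric available by
option).  Local independence: residual = observed − ΛΛᵀ off-diagonals,
threshold 0.20 by default (0.25 supported); the deletion suggestion is the
item with the largest summed absolute residual among flagged pairs.
Bifactor ECV and omega-hierarchical (ω_h, ω_hs) use the standard
closed forms on an orthogonal general + group loading matrix supplied by
configuration — which items form group factors is a modelling input, not
something the package infers.  A seeded random half-split helper supports
EFA/CFA cross-validation designs.

## DIF

The engine is a proportional-odds (cumulative-logit) model fitted by BFGS
with analytic gradients and a log-increment parameterization that enforces
intercept ordering; it matches statsmodels' `OrderedModel` log-likelihoods
to ~1e-6 (asserted in tests) while being fast enough for the
simulation-based calibration checks.  Nested models per item:
M0 (item ~ θ), M1 (+ group), M2 (+ θ×group).  The *overall* DIF test is the
joint M2-vs-M0 LRT with df = 2(levels−1) at p < 0.01; uniform (M1 vs M0)
and non-uniform (M2 vs M1) components are reported as extras.  Effect size
is the pseudo-R² change M2 − M0; McFadden's variant drives the Zumbo
classification by default (negligible < 0.13, moderate 0.13–0.26,
large > 0.26), with Cox–Snell and Nagelkerke also reported.  The matching
variable is the EAP θ from the calibrated bank; optional purification
re-estimates θ without flagged items per grouping until the flag set is
stable (hard cap 10 iterations).  Multi-level groupings are dummy-coded
with a joint LRT.  A median-split helper dichotomizes continuous
covariates (e.g. age) at the sample median.

## CAT

Start item: maximum Fisher information at θ0 = 0 (the prior mean); ties
break to the lowest item index.  After each response the EAP estimate is
refreshed over administered items; the next item maximizes information at
the current estimate.  Stopping: SEM below the rule (0.33/0.44/0.55 —
reliability 0.89/0.81/0.70), bank exhaustion, or an optional item cap.  No
exposure control or content balancing.  Missing responses are imputed
before simulation from the IRT model at each person's EAP θ — modal
category by default (deterministic), seeded sampling optional; persons with
no observed responses are filled from the prior mean and flagged.
Evaluation compares CAT final estimates with full-bank EAP estimates:
Pearson r and RMSE *on the latent θ scale* (the RMSE ≤ 0.30 acceptance
convention is only meaningful there; 0–100-scale summaries are reported
separately), plus mean items administered.

## Synthetic-data generator

The generator defines the study conditions the pipeline is exercised
under: 458 respondents × 24 five-category items (configurable), one latent
trait (standard normal within group, plus configured group offsets — the
trait distribution is an assumption, stated here, not an empirical fact),
GPCM responses, and:

- **Discriminations**: log-normal clamped to a configured range.  The
  generic default targets 0.7–3.4.  The study-like preset uses
  lognormal(0, 0.25) clamped to [0.7, 1.8]: with a single dominant factor,
  population inter-item correlations then sit around 0.3–0.6, so *only*
  the deliberately redundant pairs cross the 0.70 screening cutoff even
  with n ≈ 458 sampling noise.  (Pairs of items with a ≳ 2.2 already
  correlate > 0.70 in population, which would make the redundancy screen
  ambiguous by construction.)
- **Thresholds**: ordered steps spread around a random item center inside
  [−2.2, 0.7] (spread 0.9), i.e. item difficulty concentrated below the
  trait mean, which is what produces the characteristic "information is
  highest on [−2, 1]" test-information profile.
- **Redundant pairs** copy one item's parameters onto its partner and then
  copy the partner's realized response with probability 0.85, producing
  observed correlations ≈ 0.9.
- **DIF injection**: a uniform shift adds to all step thresholds and a
  slope factor multiplies the discrimination for the targeted group level.
- **Missingness**: completely at random per item; the study-like preset
  draws per-item rates in [0, 6%] with two chronically skipped items at
  28%/24%.  "Not applicable" responses are injected the same way at 1%.
- **Reverse-coded items** (5 in the preset) are emitted in collected
  orientation; screening reverses them before analysis.
- **Groupings** in the preset: sex 61/39, age median split 50/50, care
  setting 84/16, diagnosis 65/20/15 — four confounders, giving the
  21 × 4 = 84-test DIF suite shape.

What passing tests on this generator *do not* show: robustness to
non-normal traits, informative missingness, multidimensionality beyond the
injected nuisance structures, local dependence from item wording, or any
property of real patient populations.  The generator reproduces the
qualitative structure of a real calibration study, not any dataset's
marginal statistics.

## Problem sizes used in the checks

The simulation-based checks run at sizes chosen to give stable Monte-Carlo
behaviour at desk scale: CAT accuracy/precision on 1000 simulees × 21
items; GPCM parameter recovery at n = 1000; LRT size under PCM truth with
500 replicates of a 5-item, 3-category, n = 300 design; DIF false-flag
rate over 24 DIF-free 458-person cohorts (2016 tests).  The EAP oracle is
direct posterior integration on a 10,001-point grid.

## Known limitations

- No graded response model, multidimensional IRT, or MCMC estimation.
- Ordinal factor analysis is an approximation (see above); no WLSMV
  test statistic, no oblique rotations.
- DIF methods are limited to the ordinal-logistic family (no
  Mantel–Haenszel, no IRT-LR DIF), and scoring is never DIF-adjusted.
- The CAT is simulated from complete (possibly imputed) response patterns;
  there is no live administration server.
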