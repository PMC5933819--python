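# Methods

This note documents the models, numerical choices, and known limitations of
the package in one place. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Task engines

**Sudoku difficulty.** "Logic-step difficulty" needs a concrete rule set to
be computable. The grader uses the two single-cell rules — *naked single*
(a cell has exactly one candidate) and *hidden single* (a digit has exactly
one admissible cell in a row, column, or 2×2 corner box) — and counts one
step per cell filled. The difficulty of a puzzle is the minimum number of
steps before the target cell's digit is determined, minimised over all
inference orderings by breadth-first search over partially filled grids.
This is the smallest standard rule set that solves every uniquely
completable 4×4 puzzle (the solver never met a uniquely solvable grid the
singles could not finish). Step counts map to 10 levels through configurable
bins, by default {1, 2, …, 9, ≥10}.

An empirical consequence worth knowing: on 4×4 grids the minimised step
count rarely exceeds 4. Four-cell units make hidden singles so powerful
that some ordering almost always reaches the target quickly; randomised
hill-climbing over uniquely solvable puzzles never exceeded 4 steps. The
generator therefore serves levels 1–4 readily and raises a
generation-exhausted error for levels it cannot reach within its retry
budget, rather than mislabelling a puzzle. A larger grid or a weaker rule
set would be needed to populate the full 10-level ladder.

**Coherence ladder.** The ten RDM levels are log-spaced between the printed
endpoints 51.2% (level 1) and 1.6% (level 10), i.e. each level multiplies
coherence by (1.6/51.2)^{1/9} = 2^{−5/9}; the spacing rule is a
psychophysical convention, not a printed fact. The printed dot "density:
2.0%" is dimensionally ambiguous for 300 dots of radius 0.08° in a 3°
aperture and is recorded as metadata only; the dot count is fixed at 300.

**Staircase.** Two-consecutive up/down with clamping to [1, 10] and streak
reset after every move. At equilibrium P(two corrects) = P(two errors)
requires p² = (1−p)², i.e. p = ½, for any continuous monotone psychometric
crossing ½ — verified by long simulation (5,000 trials converge to
50.0 ± 2%).

## Synthetic observer

The generative model is deliberately minimal: a first-order
signal-detection stage that produces choices, and a second-order stage that
reads the decision evidence with additive noise and produces confidence.

- Accuracy: a(L) = 0.25 + 0.75/(1 + e^{(L−m)/s}); defaults m = 5 (trained
  proficiency reaches mid-ladder), s = 1.2 levels (near-ceiling at level 1,
  near-chance at level 10). Four-alternative choice is collapsed to
  correct/incorrect with the 0.25 guessing floor inside a(L); option
  identities are sampled uniformly.
- Evidence: e₁ ~ N(d(L), 1) with d(L) = Φ⁻¹(a(L)); correct iff e₁ > 0.
- Metacognitive readout: x₁ = e₁ + N(0, σ_meta), binned at criteria
  (−0.4, 0.4, 1.2) into confidence 1–4. Reading the *signed* evidence (the
  evidence magnitude signed by correctness — identical quantities here)
  rather than the magnitude alone is essential: at the staircase operating
  point d ≈ 0 and |e₁| carries no information about accuracy, which would
  pin the type-2 AUC at 0.5 for every σ_meta. With the signed readout,
  σ_meta = 0 gives A_ROC ≈ 0.95 and large σ_meta degrades it monotonically
  to 0.5 — the calibration the parameter-recovery tests check.
- Redecision: a fresh sample e₂ ~ N(d₂, 1) with d₂ = g·d for d ≥ 0 and d/g
  for d < 0, so the gain g ≥ 1 improves evidence quality at every level and
  g = 1 reproduces phase-1 accuracy. Confidence 2 reads
  (e₁+e₂)/√2 + N(0, σ_meta). This yields the target couplings: uncertainty
  reduction increases with initial uncertainty, and accuracy change grows
  with g.
- RT: clip(rt_base + rt_slope·u + N(0, rt_sd), 0.2 s, 2.0 s), defaults
  0.6 s base, 0.22 s per uncertainty unit, 0.25 s noise — giving the
  positive RT–uncertainty correlation the analyses expect. Non-responses
  are not simulated; table ingestion rejects invalid rows instead.

**Cohorts.** σ_meta ~ U(0.45, 1.5) and a criterion shift ~ N(0, 0.25) are
per-participant traits shared across tasks and sessions (stable
uncertainty sensitivity and uncertainty bias), while the redecision gain
g ~ U(1.0, 2.8) is drawn independently per task (task-specific control
ability). This plants the dissociation the reliability analyses recover:
cross-session and cross-task Cronbach α of A_ROC above 0.8, cross-task α of
accuracy change near zero.

What the generator does *not* emulate: lapses/attention drifts (available
as a parameter, default 0), response biases among the four options,
post-decisional evidence accumulation dynamics, learning across sessions,
and any coupling of RT to evidence beyond the uncertainty channel. Passing
tests therefore demonstrate that the pipeline recovers planted structure of
this model class, not that real data satisfy the model.

## Behavioural statistics

- The type-2 ROC sweeps uncertainty thresholds k = 4..1; hit rate
  P(u ≥ k | error), false-alarm rate P(u ≥ k | correct), anchored at (0,0)
  and (1,1); trapezoidal area. The error-detection framing is primary; the
  complementary confidence framing is exposed and gives the same area. No
  parametric ROC model and no meta-d′ are fitted, keeping the statistic
  nonparametric. All-correct or all-error input raises rather than silently
  returning 0.5.
- Uncertainty bias regresses mean uncertainty on A_ROC *across participants
  within a session × task* (the regression scope is genuinely ambiguous;
  per-session estimates are then averaged per participant). A constant
  A_ROC falls back to the raw mean with a warning flag.
- γ uses the contingency-table pair counts (ties excluded), α the standard
  k/(k−1)(1 − Σvarᵢ/var_total) form with participant-wise variances
  (ddof = 1), and the Fisher transforms use √(n−3) scaling. Tail-edness is
  an argument everywhere it applies; no multiple-testing correction is
  applied inside this module.
- Control trials are excluded from every metacognition metric.

## First-level design machinery

- Trial timing (defaults): 1-s cue, 2-s stimulus, 2-s choice, 2-s
  confidence, 4-s re-presentation, 2-s choice, 2-s confidence — a 15-s
  trial; a configurable ITI (default fixed 2 s — the ITI distribution is
  not printed anywhere, so a concrete default is required) separates
  trials. Regressor 1 starts at stimulus onset with duration 2 s plus the
  trial's choice-RT differential from the control-trial mean; regressor 2
  starts at the first confidence judgment with duration confidence-report
  time (recorded value if supplied, else the 2-s window) + re-presentation
  + RT differential; regressor 3 spans the ITI. The short-redecision
  variant (2-s re-presentation) shortens regressor 2 accordingly.
- Boxcars live on a 0.1-s microtime grid (matching the 10× oversampling of
  the 2-s TR), are multiplied by demeaned modulators *before* convolution
  with the canonical double-gamma HRF (peak gamma delay 6 s, undershoot
  16 s, unit dispersions, 6:1 amplitude ratio, 32-s support, unit peak),
  and are sampled at volume onsets.
- Serial orthogonalization residualizes each modulated column against the
  base columns, the intercept, and all earlier modulated columns in the
  declared order (default u₁ → RT → Δu, reversible). The implemented and
  tested identity is the stepwise-regression equivalence: the β of the j-th
  orthogonalized column equals the OLS coefficient of covariate j entered
  at step j (for the last column, the full-model β), to 1e−10. Note that
  *earlier* columns' βs are not invariant — Gram–Schmidt deliberately
  reassigns shared variance to whichever column enters first.
- VIF_j = 1/(1−R²_j) with R² from OLS of column j on the other selected
  columns plus an intercept; exact collinearity is flagged as ∞ rather
  than raised.
- GLM fitting is OLS. Under AR(1) noise the nominal OLS 95% intervals
  undercover (≈87% at ρ = 0.3 on this design), so `fit_glm` offers a
  single Cochrane–Orcutt prewhitening step (ρ estimated from the OLS
  residuals) that restores ≈94% coverage; the whole-stack recovery test
  uses the prewhitened fit at the simulation default ρ = 0.3. Plain OLS
  remains the default because the first-level model being reconstructed
  does not whiten.
- The reconstructed one-run design (40 trials, zero RT differential, 2-s
  ITIs) yields a pairwise VIF between the decision and post-decision
  regressors of ≈1.49 (cross-checked against nilearn's design machinery).
  Reported values near 2.4 for comparable designs are not reproducible
  from the printed timing alone: across ITI choices of 0–4 s the pairwise
  VIF spans 1.2–2.3, while the full three-regressor VIF of the
  post-decision regressor spans 4.2–5.5; the difference presumably lies in
  unprinted details (actual ITI distribution, RT variability, or the VIF
  convention used).
- PPI: the physiological factor is the seed series with the mean and the
  HRF-convolved (demeaned) uncertainty component removed; the psychological
  factor is that uncertainty regressor over the redecision phase; the
  interaction is their elementwise product; all three enter the GLM, and
  the interaction β is the coupling. Injection–recovery over 100 seeds is
  unbiased within 2 SEM.
- Beta-series connectivity: per ROI, the mean, the three event regressors,
  the three modulated regressors, and their pairwise modulator interactions
  are regressed out; residuals are segmented per trial (segment extends
  10 s past the trial to capture the HRF tail); each trial's redecision
  regressor is fit within its segment for one value per trial; values are
  correlated across trials per condition. Planted shared trial-wise gains
  are recovered with r > 0.8 at 90 task trials.
- Epoching oversamples by linear interpolation (default 10×), averages
  across trials then participants, and reports the between-participant SEM;
  windows running past the series end are truncated and flagged.

## Problem sizes used in the checks

Simulation-based checks run at desk scale, chosen to keep sampling error
well inside the asserted tolerances: 5,000 staircase trials (convergence),
10,000 trials (chance floor, couplings), 5 meta-noise values × 5,000 trials
(A_ROC monotonicity), 200 AR(1) seeds (interval coverage), 100 seeds (PPI
recovery), 50 puzzles per attainable level (generator/grader fixed point),
and a 21-participant × 6-session × 2-task cohort (reliability structure).

## Known limitations

- The 10-level Sudoku ladder cannot be fully populated on 4×4 grids under
  the single-cell rule set (see above).
- The observer's accuracy floor enters through the psychometric function
  rather than an explicit guessing stage, so evidence and guessing are not
  separable in the simulated trials.
- The coupling between uncertainty reduction and accuracy change is one
  plausible instantiation with a free magnitude (the gain g); no claim is
  made that it is the mechanism behind real redecision benefits.
- OLS residual autocorrelation is handled only by the optional AR(1)
  prewhitening step; higher-order noise structure is out of scope.
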