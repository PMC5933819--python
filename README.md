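# redecision

A toolkit for studying metacognition in a **decision–redecision** paradigm:
a participant makes a fast initial decision on a stimulus, rates their
confidence (1–4), immediately sees the *same* stimulus again, decides again,
and rates confidence again — all without feedback. Decision *uncertainty* is
the inverse of the confidence rating (u = 5 − confidence), and the interest
is in how well people monitor that uncertainty and how much the second look
lets them repair their own errors.

The package is aimed at cognitive/computational neuroscientists who want to
(1) generate the two task types used in such studies, (2) simulate realistic
behavioural cohorts to validate an analysis pipeline end-to-end, and
(3) run the behavioural and first-level fMRI design statistics on either
simulated or real trial tables.

## What is inside

**Task engines** (`redecision.sudoku`, `redecision.rdm`,
`redecision.staircase`)

- 4×4 Sudoku generation with an exhaustive backtracking solver (uniqueness
  oracle) and difficulty grading by the *minimum number of single-cell logic
  inferences* (naked/hidden singles, minimised over orderings by BFS) needed
  before the target cell is determined.
- Random-dot-motion stimuli: ~300 dots in a 3° aperture, 8°/s, 3-frame
  lifetime, with a 10-level coherence ladder log-spaced from 51.2% down to
  1.6% (100% for the control stimulus).
- An adaptive staircase: one level harder after two consecutive correct
  trials, one level easier after two consecutive errors, else unchanged.
  For any monotone per-level accuracy p(L) crossing ½ this holds mean
  accuracy near 50% (chance is 25% with four alternatives).

**Synthetic observer** (`redecision.agent`) — a signal-detection observer
with a separate noisy metacognitive readout. Phase 1: evidence
e₁ ~ N(d(L), 1) with d(L) calibrated to the psychometric function
a(L) = 0.25 + 0.75/(1 + e^{(L−m)/s}); choice correct iff e₁ > 0; confidence
bins the noisy readout x₁ = e₁ + N(0, σ_meta). Phase 2: a fresh
quality-improved evidence sample (gain g ≥ 1) drives the redecision, and
confidence reads the combined evidence. σ_meta is the single knob for
metacognitive sensitivity; g is the knob for how much redecision helps.

**Behavioural statistics** (`redecision.metrics`)

- `type2_roc` — the nonparametric type-2 ROC: uncertainty levels are swept
  as thresholds for flagging an erroneous decision; the trapezoidal area
  (A_ROC) is the *uncertainty sensitivity* (0.5 = uninformative, 1 =
  perfect error detection). Equals the rank statistic
  P(u_error > u_correct) + ½ P(tie).
- `rt_uncertainty_correlation` (Pearson r with one-tailed t),
  `uncertainty_bias` (mean uncertainty with the A_ROC component regressed
  out), `accuracy_change` (final − initial accuracy),
  `goodman_kruskal_gamma` ((C−D)/(C+D), ties dropped), `cronbach_alpha`,
  `fisher_z_compare`, and `summarize_cohort` for tidy per-session /
  per-participant summaries plus reliability reports.

**First-level fMRI machinery** (`redecision.glm`,
`redecision.connectivity`) — event schedules for the 15-s trial (decision,
post-decision, and ITI regressors; durations offset by each trial's RT
differential from the control-trial mean), canonical double-gamma HRF
convolution on a 0.1-s microtime grid, demeaned parametric modulators
(u₁, RT, Δu) with serial orthogonalization (equivalent to stepwise
regression), VIF diagnostics, OLS fitting with optional AR(1) prewhitening,
PPI regressor construction, beta-series trial-wise connectivity, and
10×-oversampled ROI epoching.

## Worked example

```python
from redecision.agent import AgentParams, SessionConfig, simulate_session
from redecision.metrics import summarize_cohort

session = simulate_session(AgentParams(), SessionConfig(), 7)  # 4 runs x (30+10)
out = summarize_cohort(session)
print(out.per_session.iloc[0])
```

prints (seed 7):

```
n_trials: 120          # control trials are excluded from the metrics
a_roc1: 0.868          # uncertainty sensitivity, initial decision
a_roc2: 0.792          # ... final decision
r_rt_uncertainty: 0.701
mean_uncertainty: 2.833
accuracy1: 0.533       # staircase holds the initial decision near 50%
accuracy2: 0.567
accuracy_change: 0.033 # redecision helps, in proportion to the gain g
gamma_u1_reduction: 0.565
```

The error-rate table shows the monotone link between reported uncertainty
and actual error probability (initial decision: 6%, 13%, 44%, 87% for
u = 1..4 in this session), and the uncertainty-reduction table shows that
trials that start uncertain gain the most from redecision (mean Δu = 0.84
at u₁ = 4 versus −0.77 at u₁ = 1).

The same pipeline runs from the shell:

```bash
redecision simulate --config config.json --out trials.csv
redecision analyze --in trials.csv --out metrics/
redecision glm-demo --config config.json --out run1/
redecision sudoku generate --level 3 --n 20 --seed 1 --out bank.csv
```

where `config.json` needs only `{"seed": 7}` to use the defaults.

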