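# Methods

This note documents the models implemented in `birdwatch`, the generative
model behind its synthetic participants, the numerical choices made where
the design was genuinely open, and what the simulation-based tests do and do
not establish.

## The adaptive engine

The task engine reproduces the adaptive *n-match* controller exactly as a
discrete between-block state machine with state
(n, threshold epoch, MaxRT, failure streak, elapsed time).

**Scoring.** Block d' is Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate). The 1/2N
correction is applied only to rates of exactly 0 or 1 (the standard
signal-detection convention), with N the trial count of the relevant class
(match trials for the hit rate, non-match for the false-alarm rate). d' is
positive for above-chance discrimination. The game score is
`100(Hit+CR) − 50(Miss+FA) + 1000·d'(7 − MaxRT)`: the middle term is a
penalty, so an all-error block at MaxRT 7 would score −4000.

**Trial generation.** Each context is seeded with an unscored preview
stimulus before the block starts, so all 80 trials have a well-defined
match/non-match status and unscaled accuracy spans the full 0–80 range. The
match rate defaults to 0.5, consistent with a chance-level accuracy of
40/80 under symmetric guessing; it is configurable. The context sequence is
uniform random; a trial is a *switch* trial when its context differs from
the previous trial's.

**Timeouts.** A response not delivered within MaxRT marks the trial a miss
regardless of the trial's match status. This is the engine's single rule
for missing input; it preserves count conservation
(hit + cr + miss + fa = 80) at the cost of slightly deflating the
false-alarm denominator on non-match timeouts.

**Difficulty progression.** Thresholds run 0.6, 0.8, …, 2.8 (epochs 0–11)
with six context levels each: 72 upward states. The pass at (epoch 11,
n = 6) sets the threshold to its advertised 3.0 cap and freezes the
progression (terminal state, n stays 6); Difficulty Level is clamped at 72
there. This reconciles the 72-state count with the naive 13 × 6 = 78
enumeration: the 3.0 threshold is a terminal cap, not a playable band of
six further states. MaxRT milestone decrements are applied before
failure-streak increments when both fire between the same two blocks, and
the failure counter resets on any pass and after each relief. All parameter
changes happen between blocks only.

## Synthetic participants

No public trial data exist for this task, so cohorts are simulated from an
explicit generative model. Its purpose is to reproduce the study conditions
that the analysis stages assume — not to model human cognition beyond them.

**Response model.** Per trial,

    P(correct) = lapse/2 + (1 − lapse) · [0.5 + 0.5·logistic(η)]
    η = ability_base + ability_gain·ln(t) − load_cost·(n − 1)
        − epoch_cost·epoch + Σ coefᵥ·xᵥ(day) + ε_day

with t the global block index. The 0.5 floor makes a collapsed agent a pure
guesser (chance accuracy 40/80); the ln(t) gain produces the logarithmic
Simple-Score growth the learning-rate stage fits; daily context enters
linearly on the logit scale so the ARIMAX recovery problem is well-posed.
Response times are log-normal (median 0.9 s, log-SD 0.35); draws beyond
MaxRT become timeouts, so the milestone-tightened response window erodes
effective accuracy late in training and performance saturates. Defaults
(ability_base −0.5, gain 0.55, load_cost 0.25, epoch_cost 0.18, lapse 0.02)
were chosen so a default cohort reaches a mean top difficulty level near 51
with roughly 2-minute blocks and a minority of participants reaching level
72 — the attainment profile the analysis stages are designed around.

**Daily states and surveys.** The five latents (wellbeing, stress,
busyness, mood, sleep) are stationary AR(1) processes (φ = 0.5, standard
normal marginals; sleep is mapped to hours as 7 + 1.2·z, truncated to
[0, 14]). Surveys discretize the latents through fixed cut-points
(−1.5, −0.5, 0.5, 1.5) into 1–5 Likert responses — deterministically, so an
agent whose latent sits below the lowest cut-point every day produces the
invariant-regressor case the forecasting stage must handle. One survey is
emitted per session, before its first block.

**Adherence and schedule.** Total trained hours are a two-part mixture
calibrated to the target moments (mean 17.35 h, SD 5.93 h): with
probability 5/37 the agent discontinues early with an exponential stopping
time (mean 3.48 h); otherwise hours are drawn from a truncated normal whose
mean (~19.5 h) and SD (~2.0 h) are solved from the mixture identities.
Sessions run 2–3 per week on random weekdays (length ~N(0.67 h, 0.25 h)),
giving roughly 1.5 surveys per trained hour. Engine state persists across
sessions. Within-day session counts and inter-session intervals are
unconstrained by the study description; one session per training day is the
package's choice.

**What the generator does not emulate.** Practice effects on response
speed, strategy shifts, fatigue within a session, survey measurement error
beyond discretization, missing surveys, and any dependence of adherence on
performance. Tests passing on these agents demonstrate that the pipeline
recovers what the generative model puts in — they do not validate the
psychological assumptions on real data.

## Learning rates

Simple Score = Difficulty Level × unscaled accuracy. Training periods are
half-open intervals of the block's cumulative hours at block end: early
[0, 5), middle [5, 10), late [10, ∞) — a block ending exactly at 5.0 h is
middle. The log model Y = b0 + b1·ln(t) is fitted by OLS over all blocks
(overall rate) and the early period; linear slopes over middle and late.
t is the global block index in every fit, so period fits are nested views
of one series. A period is fitted only with ≥ 10 blocks (`min_blocks`);
shorter periods are flagged unfittable rather than extrapolated, which is
how discontinued participants surface downstream.

## Daily ARIMAX stage

Each participant's series is indexed by ordinal training day (calendar gaps
ignored); y[day] is the mean Simple Score over the day's blocks (mean, not
sum, so the aggregate is invariant to blocks-per-day); x[day] is the day's
first survey, used on its raw scale (Likert integers, sleep hours).
Zero-variance columns are removed and recorded before fitting. Days with
blocks but no survey are excluded with a warning.

Models are regression-with-ARMA-errors fitted by maximum likelihood in a
state-space form (statsmodels SARIMAX), with an intercept for d = 0 and
none after differencing. The order search is an exhaustive grid over
p ≤ 5, d ≤ 1, q ≤ 5 (72 candidates) scored by AIC = 2k − 2·logL, k counting
regression coefficients, ARMA terms, the intercept when present, and the
innovation variance. Ties (within 1e-9) break toward smaller p + q, then
smaller p. Exogenous p-values are asymptotic z-tests; no multiplicity
correction is applied across regressors or participants (per-participant
α = 0.05 reporting).

Numerical choices: the optimizer is L-BFGS with a bounded iteration count
and a loosened convergence tolerance — the AIC ranking is insensitive to
the final optimization digits, and an exhaustive 72-model grid at exact
tolerances costs several times more for identical selections. A candidate
is skipped only if its fit raises or returns a non-finite likelihood;
the optimizer's convergence flag is recorded on the winner but does not
exclude candidates, since near-converged high-order models would otherwise
drop out nondeterministically. Series shorter than 10 observations return
an explicit fit-failure result (the observed cause of unfittable
participants: early discontinuation plus sparse surveys), never an
exception.

## Group-level stage

Stepwise regression alternates forward entry (lowest p < 0.05 enters; ties
to the lower column index) and backward removal (largest p > 0.05 leaves)
to convergence, on complete cases per analysis (listwise deletion). Entry
stops if the current fit is numerically perfect (R² within 1e-12 of 1),
since any further term would fit floating-point residue. An empty final
model is a valid report. The entry/removal α of 0.05 operationalises
"until only significant predictors remained". Hierarchical regression fits
two nested OLS models and reports ΔR² with the standard F-change test; a
design condition number above 1e8 raises a collinearity warning. Partial
correlation residualises both variables on the controls plus intercept and
correlates the residuals, df = n − 2 − #controls, two-sided p from the t
transform.

The covariate fixture draws age, cognitive scores, and regional volumes
from a latent-factor Gaussian (a general-cognition factor, a head-size
factor loading on eTIV and volumes, and age loading negatively on both) at
the cohort's means and SDs, so the regression stage sees realistic
collinearity without real data. RAVLT aggregation: learning total
= ΣA1..A5, interference cost = A5 − A6, delay cost = A6 − A7, recognition
errors = sum of the five error categories; aggregates touching a missing
trial are NaN and flagged.

## Reproducibility

All randomness descends from one root seed through a SeedSequence;
per-participant seeds and output digests are recorded in the run manifest.
Identical config + seed yields byte-identical logs and identical downstream
reports. Monte-Carlo checks in the test suite and the acceptance script use
deliberately modest replicate counts and cohort sizes (stated in each
test/entry) — large enough to separate signal from noise at the asserted
tolerances, small enough to keep a full run at desk scale.

## Known limitations

* The agent model's late-training behaviour (saturation plus
  timeout-driven erosion) only loosely mimics observed plateau dynamics;
  middle/late slopes should be read as qualitative.
* The AIC grid at n ≈ 30–60 days overfits occasionally (spurious ARMA(2,2)
  winners on white noise); this mirrors the behaviour of AIC-based
  auto-ARIMA at these lengths and is why order-selection checks are modal,
  not per-replicate.
* Exogenous z-tests after order selection inherit post-selection optimism;
  the false-positive-rate test bounds, but does not calibrate, this effect.
* The stepwise procedure has the usual selection-inference caveats; it is
  provided because it is the procedure under study, not as a recommended
  inferential tool.
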