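# Methods

## Scope and data model

`weightcast` models one person at a time. The statistical unit is the
daily response of that person's weight to energy balance (EB) and
macronutrient composition; nothing is pooled across users. A user's
diary is a gapless daily table (missing calendar days are inserted as
missing rows on ingestion) with weight [kg], carbohydrate/protein/lipid
masses [g], energy intake, resting metabolic rate and activity
expenditure [kcal].

## Energy ledger

EB = EI − TEE with TEE = RMR + TEA + TEF and
TEF = 0.095·(m_C·3.75) + 0.015·(m_L·9) + 0.25·(m_P·4) kcal. The TEF
coefficients are fixed constants of the method (≈10% of expenditure for
a mixed diet); the energy densities 3.75/4/9 kcal/g are used everywhere
a conversion between grams and kcal is needed, including diet-plan
construction, so gram/kcal round trips are exact by construction.

**Missing values** are pad-imputed (carry the previous day forward).
Train and test segments are imputed independently so the test segment
never informs the training segment. A missing value at the very start
of the *test* segment has no within-segment predecessor; the strict
operation refuses it, while the pipeline fills it from the last
observation before the boundary — the value that is causally available
at deployment. Only a missing series start is irrecoverable.

**Reporting bias.** Self-logged intake is typically chronically
misreported, shifting EB by a roughly constant amount while weight
responds only to the true balance. For non-overlapping weekly points we
regress the trailing 7-day mean of daily EB on the 7-day weight change,
`EB_week = a·Δw_week + b`; the intercept `b` estimates the mean daily
bias [kcal/day] and is subtracted from every day's EB. Conventions
chosen where the method description is open: EB_week is a *mean* (not a
sum), so `b` lives on the daily scale and is subtracted unscaled;
weekly points are taken at stride 7 to avoid window-overlap
autocorrelation (overlapping mode available). Correction is guarded
against double application. With the default synthetic conditions the
recovery error of an injected 300 kcal/day bias is within ±30 kcal.

**Seasonality.** Weekly harmonics cos(2πt/7), sin(2πt/7) encode
day-of-week habits. By default the phase is anchored to the calendar
weekday of the first record so the features mean the same thing across
users; with no dates, day 0 is phase 0.

## Supervised reframing and scaling

One sample predicts weight on day *t* from the feature rows of days
*t−k..t−1*, features ordered (EB, m_C, m_P, m_L, w[, week_cos,
week_sin]). Windows are contiguous and ordered. Features and target are
min–max scaled to [0, 1] with parameters fitted on training days only;
test values may leave [0, 1] (no clipping), constant features map to 0.
Min–max is the default because it keeps all inputs in a range where
every candidate activation is well behaved; z-score standardization is
available via the scaler's ``method`` option. The target is the weight
*level* in scaled space; predicting day-to-day weight deltas instead
was considered and rejected as the default because the level target is
what the one-step output layer defines.

## GRU forecaster

Architecture: input (k × p) → GRU(n_units, activation) → dropout →
dense(1). The GRU cell uses the standard update/reset-gate equations
with sigmoid gates and the tuned activation on the candidate state
(reset gate applied before the candidate's recurrent product; the
update gate carries the previous state). Training: Adam (lr 1e-3,
β₁ 0.9, β₂ 0.999, ε 1e-7) on mean absolute error for exactly the tuned
number of epochs — no early stopping, since the epoch count is itself a
tuned hyperparameter; the held-out window is only logged as a
validation curve. Dropout applies to the final hidden state during
training only, so inference is deterministic. Batches are shuffled each
epoch by default: once reframed, samples are exchangeable rows, and
shuffling measurably improves optimization quality on ~300-sample
diaries; strict time-ordered batches are a flag away. Weights are
float32; forward and backward passes are Numba kernels (the
implementation is self-contained; a vectorized NumPy forward pass
serves as an independent cross-check in the tests). Initialization:
Glorot-uniform kernels, orthogonal recurrent kernels, zero biases. A
non-finite loss raises a training-diverged error naming the offending
hyperparameter point (the exponential activation can overflow — that is
expected behaviour for that grid arm, and the search records the point
as failed rather than crashing).

Seeding: one master seed fans out to per-point seeds; runs are
reproducible on a fixed machine/BLAS configuration.

## Hyperparameter tuning with physiological constraints

Grid: neurons {50,100,150,200} × activations {tanh, relu, sigmoid,
softplus, softsign, selu, elu, exponential} × batch {8..128} × epochs
{50..200} × dropout {0.2,0.4,0.6} × lookback {3..7} × seasonal {on,off}
= 19,200 points. Exhaustive search is out of proportion for a ~300-day
diary, so the default budget draws 60 uniform points (seeded) plus an
always-included anchor (ReLU, dropout 0.2, 100 neurons, 50 epochs,
batch 32, lookback 5) that guarantees one sane candidate.

Each candidate is trained on all but the last 7 days, then must pass
four physiological conditions evaluated by a frozen-model 7-day diet
simulation at EB = −1000…+1000 kcal/day (50/20/30 split): weight gain
at +1000, loss at −1000, day-7 spread of the extremes < 10 kg, and
monotone response in EB (tolerance 1e-6 kg, on raw simulated endpoints,
non-strict). Failing any condition discards the point regardless of its
RMSE — a planted perfect forecaster with wild EB response is never
selected. Survivors are ranked by 7-day held-out RMSE (recursive
forecast: own weight predictions, actual covariates); ties prefer fewer
neurons, then smaller lookback, then smaller batch. The constraint
simulations run frozen (no per-step retraining) for speed and because
they probe the trained model's response surface, not the retraining
loop.

## Walk-forward validation and simulation

* **Train/test forecast**: train once, predict the test window
  recursively with actual covariates.
* **WFV**: each test day is predicted from the last *k* actual days;
  with the default every-step policy the revealed day is appended and
  the model refit from scratch (fresh scaler, same hyperparameters and
  seed) before the next day. Retraining never sees rows beyond the
  current day (no lookahead).
* **WFS**: windows carry planned covariates and previously predicted
  weights; known rows come from actual history. The plan's covariates
  take effect from the last observed day onward — starting a plan
  redefines "today's" intake — so a constant-EB plan drives every
  simulated step and a linear reference model reproduces its closed
  form exactly. Every-step retraining (appending the predicted/planned
  row) mirrors the validation loop and is the default for plain WFS;
  the frozen variant supports starting from arbitrary historical days
  and is what tuning and the diet sweep use. Simulated weights are
  clamped to [30, 250] kg; clamping is logged and treated as failure
  during tuning.

## Diet plans and metabolic plasticity

Because TEF depends on intake, the gross intake realizing a target EB
is obtained in closed form: EI = (EB + B)/(1 − 0.095p_c − 0.015p_l −
0.25p_p), with B the user's mean RMR+TEA over the training window (the
minimal assumption: habitual non-food expenditure is held at its
personal mean). Grams follow from the energy split and densities, and
the plan round-trips through the ledger to the target EB exactly.

The plasticity readout simulates the five-level EB sweep (7 days,
frozen model, common starting state), anchors each trajectory at the
last actual weight, fits a second-order polynomial over days 0–7 (to
cancel day-scale artifacts such as water retention), takes
Δw = p(7) − p(0), and regresses Δw on EB:

    Δw = m·EB + q.

**Units.** m is the *weekly* weight change per kcal/day of sustained
imbalance — the scale on which per-user plasticity is conventionally
reported. The equivalent per-day slope is m/7; m = 1.5e-3 kg/kcal
corresponds to ≈ 7000 kcal per kg of tissue, squarely at the accepted
tissue-energy scale. The package logs a warning when a fitted m implies
an implausible tissue energy density (weekly Δw per weekly kcal beyond
~5× the 3500 kcal/lb scale).

## Synthetic cohort: what it emulates and what it does not

The generator produces the study conditions every test runs under: 330
daily records; latent weight following
w(t+1) = w(t) + (m_true/7)·EB_true(t) + ε (ε sd 0.05 kg/day); EB_true
normal around a weekly cosine cycle (amplitude 150 kcal, sd 300
kcal/day, mean 0 — a weight-stable user); intake inverted through the
ledger so all columns are mutually consistent; observed intake shifted
by a constant reporting bias; observed weight = latent + N(0, 0.15 kg)
(impedance-scale repeatability); ≤3% missing cells (default 1%), never
on day 0. m_true is the weekly plasticity (defaults bracket 0.3–2.0
×10⁻³ kg/kcal); an optional saturating response tests nonlinearity.
Process vs measurement noise are separate knobs: the former is real
weight change, the latter is not, and only the former should be
forecastable.

Not emulated: multi-day water retention/bloating dynamics (only i.i.d.
noise), macronutrient-composition variation day to day (the energy
split is constant), drifting reporting bias, or behavioural feedback
from weight to intake. Passing tests therefore demonstrate correct
mechanics and parameter recovery under a linear, stationary ground
truth — not forecasting skill on real physiology.

## Problem sizes and numerical choices

Default test/acceptance problem sizes are chosen as desk-scale
experiments: tuning budgets of 60 (full protocol) or 7 (smoke
protocols) points, 10-seed replications for stochastic claims, 7-day
horizons. Scalar tolerances: 1e-9 kcal/kg for algebraic identities,
1e-6 kg for the monotonicity filter, 1e-12 for exact linear-algebra
recoveries. Weekly-regression minimum span: 15 days (2 weekly points).
Scaler inversion is exact to 1e-9; float32 network arithmetic is
cross-checked against a float64 reference to 1e-5.

## Known limitations

* The constraint filter caps how strong a weekly plasticity can be
  certified: a model whose day-7 ±1000-kcal spread exceeds 10 kg is
  rejected by construction, so weekly plasticities above ≈ 5×10⁻³
  kg/kcal are not representable by a selected model.
* Plasticity extraction reads the *model's* response surface; for EB
  levels far outside the training distribution (±1000 kcal/day vs a
  ±900 kcal observed range) it extrapolates, and saturating activations
  can attenuate the response.
* Walk-forward retraining refits from scratch each step (full epoch
  budget, fresh scaler); warm-starting from the previous weights was
  considered but rejected to keep every step's model a pure function of
  its training window. Retraining cost grows linearly with the horizon.
* The per-user model needs roughly two months of data before the
  supervised reframing and scaler have anything stable to work with;
  the pipeline enforces ≥ 30 training samples.
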