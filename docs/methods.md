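# Methods

## The model

Both classifiers share one dynamical core: an echo state network (ESN)
reservoir of `M` neurons with fixed random weights.  Given an input
sequence `u_1, ..., u_n` (each `u_t ∈ R^k`), the internal state
`x_t ∈ R^M` evolves by the leaky tanh recurrence

    x_{t+1} = (1 − a) x_t + a tanh(W_in u_{t+1} + W_res x_t),   x_0 = 0,

where `a ∈ [0, 1]` is the leakage rate, `W_in` (M×k) and `W_res` (M×M) are
drawn i.i.d. standard normal from a seeded generator, and `W_res` is rescaled
so its spectral radius equals a target `ρ`.  No weight is ever trained inside
the reservoir, and there is no output-feedback term: for classification the
label exists only at the end of a series, so feeding an output back into the
dynamics is meaningless.  With `ρ < 1` the network has the echo state
(fading-memory) property: the influence of the initial state vanishes under
any bounded input, which the test suite verifies numerically (two initial
conditions driven by the same 200-step input converge to < 1e−6).

The state is reset to zero between samples/participants so that nothing
leaks across them.

### Method 1 — differential ESN (regular series)

Equal-length labelled series are encoded by their adjacent pairwise
differences, `û_j = u_{j+1} − u_j` — static suppression: most transformed
observations sit near zero and only abrupt change survives, which is where
class information typically lives in the regimes this method targets.  The
differenced series drives the reservoir; the per-neuron **variance over
time** of the state trajectory is the fixed-length "hallmark" feature
vector; hallmarks are stacked into a design matrix and a linear SVM is
trained on them.  Consequences that double as checks:

* the whole pipeline is invariant to adding a constant to any series
  (differencing cancels shifts);
* a constant series produces an all-zero feature row;
* the error rate is deterministic given (dataset, reservoir seed).

### Method 2 — interpolation ESN (irregular longitudinal series)

Screening-style data have 2–6 visits per participant at uneven times.  Each
participant's visits are linearly interpolated and resampled at integer
months 0, 1, ..., floor(span) since their first record; when the last visit
falls between grid points, its exact value is appended as the final row so
the most recent screen — the clinically decisive observation — is always
represented.  Cubic splines are deliberately not offered: with fewer than
six support points a nonlinear trajectory is not identifiable.

The monthly sequence drives the reservoir (reset per participant) and the
states are stacked into a design matrix with **skip sampling**: retain rows
`{n, n−τ, n−2τ, ...}` counted backwards from the last timestamp, so the last
state is always kept and each participant contributes `ceil(n/τ)` rows,
every row labelled with the participant's outcome.  The readout is a linear
SVM with Platt-calibrated probabilities (sigmoid fitted on 5-fold
cross-validated decision values).  A participant's prediction is the
probability at their final retained row — earlier history enters through
the recurrent state folded into it.

**Forecasting.**  To predict `γ` months ahead, the trained model is applied
to test sequences truncated to their first `m − γ` monthly rows;
participants with `m − γ < 1` are excluded and reported.  Training is
untouched.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `M` | 50 | reservoir size; small enough to be cheap, rich enough to separate burst timings |
| `a` | 0.9 | leakage; close to 1 ⇒ fast, short-memory dynamics (headline setting) |
| `ρ` | 0.95 | target spectral radius; < 1 preserves the echo state property |
| `input_scale` | 1.0 | multiplier on the standard-normal `W_in` |
| `τ` | 4 | skip step, recommended 3–6 (months; comparable to tumour doubling times) |
| `C` | 1.0 | SVM regularisation weight, untuned |
| `γ` | 6 | forecast horizon in months for the screening use case |

The leakage rate is the memory dial: the per-step contraction of a state
perturbation is roughly `(1 − a) + a·ρ·E[sech²]`, so at `a = 0.9` the
reservoir forgets in a few steps, while `a = 0.3` integrates over tens of
steps.  The package's **slope-sensitivity protocol** therefore uses
`a = 0.3` (with τ = 4, M = 50) when the question is whether trajectory
*shape* — not level — separates cases from controls; at `a = 0.9` a
slope-only signal measurably vanishes from the final state.

Marker panels are standardized per marker with training-split mean/SD,
applied unchanged to the test split (no leakage).  Visit times given in
years are converted to months (×12) before gridding.

## Synthetic study conditions

`synthetic.gen_regular` draws 2-class univariate series (50 + 50 per split,
T = 100): Gaussian noise (SD 1), with class 2 carrying a ×3 noise burst in
months 40–60.  Classes differ only in local variance — exactly the structure
the differential encoding amplifies.  `add_test_noise` perturbs a test set
with SD = scale × max|train| (scales 0.02 and 0.05 in the robustness
protocol).

`synthetic.gen_cohort` draws a 222-participant cohort, 6 markers, 2–6
visits at 4–10-month gaps, balanced outcomes.  Controls are stationary
noise; cases rise linearly at 0.12 SD/month on half the panel from 18
months before their last visit.  The `slope_only` variant instead raises
cases *to* the control baseline at the last visit (same slope, equalized
last-visit marginals), removing all cross-sectional signal by construction.

What the generators do **not** emulate: marker-specific distributions and
detection-limit censoring, correlated marker noise, informative visit
timing (sicker participants screening more often), competing diagnoses, and
class imbalance typical of population screening.  Passing tests show the
pipelines recover the intended longitudinal structure under clean Gaussian
conditions; they do not certify performance on real screening data.

## Evaluation protocols

* **Seed robustness** (regular data): rebuild the reservoir from 50 seeds,
  refit, report per-seed test error with mean and normal-approximation 95%
  CI of the mean (SD/√n; standard at n = 50 and matching the symmetric
  intervals such summaries usually print).
* **Split robustness** (cohorts): 50 unstratified random 50-50 participant
  splits; standardize on train, fit, score test participants by ROC AUC.
  Splits leaving one class on either side are redrawn and counted.
* **Last-visit baseline**: logistic regression on each participant's final
  raw visit values only — the cross-sectional comparator.

Error rate is the misclassified fraction; AUC is the rank-based
probability that a random positive outscores a random negative (ties half),
computed via scikit-learn and cross-checked in tests against an O(n²)
pairwise oracle.  No multiple-testing correction is applied; the reports
are descriptive.

## Numerical choices and degenerate inputs

* Spectral radius by dense eigensolver; rescaling is exact up to float
  round-off (checked at 1e−8 relative).  A raw radius below 1e−12 (possible
  only for pathological tiny draws) is an error, not silently patched.
* Variance hallmark uses the population denominator (n); it is a per-sample
  summary, not an estimator, and with equal lengths the choice is a global
  column scaling absorbed by the SVM.  Configurable via `ddof`.
* Shift invariance of the differencing is exact in exact arithmetic; in
  float64 it holds to round-off (bit-exact for integer-representable data),
  and hard predictions are unaffected.
* Constant samples yield all-zero feature rows and are passed through;
  single-class training sets, empty sequences, ragged or non-numeric input
  rows, duplicate visit times and conflicting outcomes are hard errors.
* Participants with a single visit are dropped at ingest (no trajectory to
  interpolate); the exclusion count is logged and kept on the cohort.

## Problem sizes

The shipped protocols use the defaults above: 50 reservoir seeds on the
100 + 100 burst dataset, and 50 splits of the 222-participant cohort for
each of the standard, forecast and slope-only analyses.  The full
acceptance run completes in about a minute on one CPU.

## Known limitations

* Both methods assume the discriminative signal survives their summary:
  Diff-ESN is blind to classes separated by level rather than change;
  Interp-ESN's linear interpolation invents no structure between sparse
  visits and degrades when visits are very far apart.
* The probability calibration inherits the usual small-sample noise of
  5-fold Platt scaling.
* Multiclass support (one-vs-rest) exists for Diff-ESN only; the cohort
  pipeline is binary.
* CI method is a normal approximation across runs; runs share the dataset,
  so the intervals describe protocol variability, not sampling variability
  of new data.
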