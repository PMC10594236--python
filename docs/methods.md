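# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the tests do and do not establish.

## Task and units

Two virtual finger groups (index; middle-ring-small, MRS) move along arcs
normalized to positions in [0, 1]; flexion increases position. Time is
binned at 50 ms. Each trial presents one target center per group (drawn
uniformly so the full extent, half-width 0.1, fits in the arc; consecutive
trials differ in at least one group). A trial succeeds when every group
stays inside its target for the hold time (500 ms online, 750 ms for
manual-control training) and fails at a 10 s timeout. Positions are in arc
units, velocities in arc units/s, times in ms. The signed distance to the
target center is `D = T − P`; a movement is *away* in a bin when `V·D < 0`,
i.e. when it increases |D|.

## The simulated subject

Intent is a proportional feedback controller on the *rendered* finger
positions:

    V_intent(k) = g · D(k) + η(k),    η(k) = ρ η(k−1) + √(1−ρ²) σ ε(k)

with gain `g = 3 /s`, motor-noise sd `σ = 0.4 arc/s` and AR(1) coefficient
`ρ = 0.85` (≈ 300 ms error time constant). The AR structure matters: with
white noise, command errors reverse themselves within one bin, so a stopping
correction can only block the controller's own mean reversion and *hurts*
performance. Persistent command errors are both more physiological and the
regime in which stopping a detected erroneous movement prevents real
displacement loss. `ρ = 0` recovers white noise.

These values were calibrated once, before the test suite was frozen, to
give near-ceiling manual-control success, majority-success brain control,
and a workable balance of away-labeled segments (~25% of labeled ones);
they are the package's study conditions and are not varied by tests.

## Neural generator

Each of 16 channels is a lagged linear function of the kinematics:

    SBP_c(k) = ω₀c + Σ_g [ ω_P P_g(k−6) + ω_V V_g(k) + ω_D D_g(k−4) ]
               + Σ_g γ_cg · 1[group g moving away](k−1) + ν_c(k)

Weights are drawn per channel (`ω_P, ω_V, ω_D` Gaussian with sd 0.2, 0.5,
1.5; `γ` half-normal with scale 0.1 in the error-gain scenario; iid Gaussian
noise sd 0.4). Lag placement encodes that activity tracks velocity with no
lag, lags the distance by 4 bins and the position by 6; the error drive uses
the previous bin's rendered movement (one-bin visual-feedback latency). At
session edges the kinematics are replicate-padded for generation; the
*analysis* models instead drop bins whose lagged index leaves the session.

The distance weight scale intentionally dominates the velocity scale.
Because the intent law ties velocity to distance (`V ≈ gD + η`), any
velocity coding leaks distance information into a single-lag distance
regression at lag 0; only when direct distance coding is strong enough does
the distance variance curve peak at the injected −4 bins, which is the
regime the generator is meant to emulate.

Scenarios: `distance-coding` (γ = 0), `error-gain` (the main detection
fixture), `null-coding` (all kinematic weights and γ zero — channels are
bias + noise), `single-finger` (one group). A velocity-coding-only session
is *not* a valid chance-level control, for the leak reason above; the null
scenario therefore zeroes everything.

## Kalman filter

Standard BMI velocity filter: state `x = [P₁..P_G, V₁..V_G, 1]`, observation
`y = SBP`. Position rows of the transition matrix are fixed to exact
integration (`P(k+1) = P(k) + Δt V(k)`), the velocity rows and the
observation matrix are least-squares fits on the manual session, and the
residual covariances provide process/observation noise. Channels with mean
activity above a configurable floor are included (default: all). A singular
observation-noise covariance (e.g. duplicated channels) raises an error
naming the offending channels. Decoded position is re-derived by
integrating decoded velocity with clipping at the arc boundaries, and the
rendered position/velocity are written back into the filter state each bin,
both offline and online — so the filter always tracks what is displayed.
Fitted matrices are stored C-contiguous so a serialization round trip
reproduces decode output bit-exactly.

## Encoding analysis

Single-lag models regress each channel's SBP in bin `k` on the chosen
kinematics at bin `k + l` (negative `l`: kinematics precede the activity);
multi-lag models use all lags in [−L, L]. Percent variance explained is
in-sample R² per channel, averaged across channels with SEM bars; no
held-out protocol is used here because the quantity of interest is
explanatory, not predictive. Channels with zero variance are excluded with
a warning. The distance contribution is the one-sided Wilcoxon signed-rank
comparison of per-channel R² between VPD and VP at matching lag windows;
nested-model monotonicity (R² never decreases with added regressors) holds
exactly on every fitting set. The default lag grid is −12..12 bins
(±600 ms).

## Error detection

A sliding window of N = 4 bins (200 ms; N = 5 supported) over each group's
decoded movement yields one candidate segment per bin. A segment is
*toward*/*away* when every bin's `V·D` is positive/negative, typed
flexion/extension when every velocity shares a nonzero sign, and unlabeled
otherwise; exact zero velocity makes it inconsistent; segments spanning a
target change are unlabeled (their direction is ill-defined, and training
labels must be clean even though an online system would still score them).
Location (inside/outside target) is judged at the segment's end bin.
Features are the flattened N × C SBP block (bin-major) of the channels used
by the filter, z-scored with training-set statistics.

Detectors are trained per (group × movement type) on balanced sets
(majority class subsampled, seeded). SWLDA uses forward/backward stepwise
regression of the ±1 label (entry p < 0.10, removal p > 0.15, max 60
features — conventional settings in the BCI literature) followed by a
pooled-covariance linear discriminant on the retained features; with
unrestricted entry this is exactly ordinary LDA. QDA and linear SVM are the
scikit-learn implementations behind the same interface.

Thresholds come from the validation ROC: among operating points with
FPR < 5% choose the one maximizing TPR (ties: lower FPR, then larger
threshold); if no such point detects anything, fall back to the minimum
strictly positive FPR. Two consequences worth knowing: (a) because the rule
maximizes TPR on the selection set, the selection-set TPR carries a small
optimistic bias (~2% at typical validation sizes) — FPR control is exact,
TPR estimates on the selection set are not; (b) a degenerate classifier
with constant scores admits only FPR ∈ {0, 1}, and the fallback then flags
everything — the rule prefers a useless detector that fires to one that
never does.

Overlapping windows create a second subtlety: segments sharing bins leak
between a random train/validation split. For noise-only channels this leak
is slightly *negative* (shared noise straddling a label change is fitted
toward one label and validated with the other), depressing within-session
validation AUC by ~0.01–0.015. Chance-level claims are therefore evaluated
on an independent session; the operational 70/30 random split is kept for
training because the paper-style protocol does so and the effect is
negligible at real signal strengths.

## Closed loop and correction

Each bin: intent → SBP (from lagged rendered history) → filter update →
correction → render → detection. The two-step stopping policy zeroes the
flagged group's velocity for `stop_bins = N = 4` bins and suspends that
group's corrections for `pause_bins = 2N = 8` bins (detectors still score
during the pause; flags are suppressed per group). The corrected velocity
is written into the filter state, so the stop feeds the next update; the
other group is corrected independently. Detection is only possible once a
trial has N committed bins, so the earliest flag comes 200 ms after an
error starts. The refractory contract (inter-correction gap ≥ stop + pause
bins per group) holds by construction and is asserted in tests.

Per trial: TFA is the time before the first in-target bin of a group; OT is
the time between first acquisition and the final (re)entry after which the
group stays in target (zero if it never leaves); TTT is trial duration
minus hold time. Timeout trials are excluded from TTT/OT comparisons. The
ABA analysis pools both monitoring phases and tests "B smaller" with a
one-sided Wilcoxon rank-sum (exact for small untied samples, tie-corrected
normal approximation otherwise). TP/FP tags of online flags come from the
offline labeler applied to the logged trajectory, which by construction
agrees with the online ground truth.

## Numerical and design choices

- Distance is measured to the target *center*, not its nearest edge; an
  away movement inside the target is still an error (and stopping there is
  precisely what shortens orbiting time).
- Ties in ROC scores are grouped at a single threshold (step ROC); AUC is
  trapezoidal and equals the Mann–Whitney pair-concordance probability.
- Rank-sum p-values use the exact distribution when samples are small and
  untied.
- The stepwise partial-F uses orthogonalized candidate screening
  (numerically equivalent to the textbook partial F test, vectorized over
  candidates); features with zero variance can never enter.
- Session CSVs are written with `%.17g` and parsed with round-trip float
  precision, so write→read is bit-exact.
- Decoded positions are clipped to the arc; whether the original online
  system clipped is unknowable from the outside, but unclipped integration
  can drift out of the rendered range.

## Problem sizes

Default tests use 120-trial training sessions, 200–300-trial brain-control
sessions, 400-trial ABA phases, and 10–20 seeds for repeated-measure
claims; the full suite runs in about a minute on one CPU. These sizes give
the acceptance properties comfortable margins while staying desk-scale.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analyses assume: lagged linear
tuning, distance coding, an optional direct error drive, persistent
erroneous movements, and a closed loop in which correction feeds back into
decoding. It does not emulate spike-train statistics, nonstationarity,
learning or motivation effects, channel dropout, or real monkeys'
error-movement statistics (unreported in any case). Passing tests therefore
establish that the pipeline's logic, statistics and threshold rules are
correct and that the correction mechanism helps *when its assumptions
hold* — not that any particular animal's recordings would yield the same
detector quality. Quantities tied to real recordings (per-day TPR tables,
specific OT percentages) are deliberately out of scope; the package's
claims are the reproducible ones: the FPR design bound, the 200 ms
latency, the 8-bin pause, lag recovery, chance-level null controls, and a
significant OT reduction under correction.
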