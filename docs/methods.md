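# Methods

## Problem and overall design

The package estimates three gait-phase timepoints — foot-off (FO),
mid-swing (MidS) and foot-contact (FC) — from two inertial sensors worn
above the ankles and sampled at 100 Hz.  The pipeline has two routes to
events:

1. a **deterministic peak labeler** that finds the FO–MidS–FC triple-peak
   of each step on the smoothed angular-velocity magnitude and is used to
   produce training labels, and
2. a **learned detector**: one recurrent sequence model per phase that
   maps a 251-frame window of three magnitude features to the
   probability that the phase occurs at the window's center frame, plus a
   two-stage event caller (supra-threshold region → argmax → local
   refinement on the raw signal).

A synthetic gait simulator with exact ground truth makes every stage
testable without recorded data.

## Signals and preprocessing

Per leg the pipeline consumes the 3-D angular velocity (deg/s), the 3-D
free acceleration (m/s², gravity removed by the device) and the [1][1]
element of the orientation direction-cosine matrix.  Cleaning: missing
values are pad-imputed (forward fill; a leading gap takes the first valid
value), and samples outside the sensors' physical validity ranges
(±160 m/s² accelerometer, ±2000 deg/s gyroscope) are treated as missing
and imputed the same way, which makes the operation idempotent.

Smoothing is a normalized Gaussian kernel specified by its full width at
half maximum in frames, σ = FWHM / (2√(2 ln 2)); the default FWHM = 9
frames (90 ms at 100 Hz, σ ≈ 3.822) matches the scale of gait transients.
The kernel is truncated at 4σ per side and boundaries are reflected,
which avoids edge droop on short trials.  Smoothing is applied to the
*magnitude* signals, not the raw axes: the labeler's defining quantity is
the smoothed angular-velocity magnitude, and smoothing the axes first
then taking norms yields a different (biased) signal because the norm is
nonlinear.  A `smooth_raw_channels` switch exists for comparison runs.

## Features

Orientation-invariant magnitudes: AngVelMag = ‖gyro‖₂ and
FreeAccMag = ‖free acc‖₂ are invariant under any fixed rotation of the
sensor frame (property-tested against random rotations); the bilateral
RotMatMag = √(r11_left² + r11_right²) is constant during straight walking
and deviates whenever heading changes, flagging turns.  Model inputs are
the three smoothed magnitudes per leg, min–max scaled per recording; the
scaling choice is ours (the field offers no standard here) and is stored
with every trained model.

## Peak-based labeling

MidS candidates are local maxima of smoothed AngVelMag with prominence
≥ 0.1 of the signal range and ≥ 0.4 s apart; because MidS is the largest
peak of a step, the separation rule also removes the FO/FC flank peaks.
For each MidS, FO is the most prominent local maximum in a window
extending at most 0.8 s to the left, and FC symmetrically to the right —
but the window is additionally clipped at the midpoint to the adjacent
MidS.  Without that clip, the *next step's* FO (taller than the current
step's FC) can fall inside the 0.8 s window at ordinary cadence and be
picked as the FC; attributing flanks to the nearest step by the midpoint
rule fixes this while keeping the prominence criterion.  Equal flank
candidates tie-break toward the frame nearest MidS.

Turning detection operates on smoothed RotMatMag with a two-pass
baseline: candidate frames deviate from the global median by more than
0.25; the straight-walking baseline is the median of the remaining
frames; final intervals must exceed the threshold for ≥ 0.5 s and are
then extended outward while the deviation exceeds 0.2 × threshold.  The
hysteresis matters because |cos| returns to its baseline value in the
second half of a 180° turn; entry/exit at a single threshold would clip a
gradual sweep to its central ~70%.  A limitation is intrinsic to the
feature: the final part of a turn in which the heading approaches a
multiple of 180° minus the starting heading is invisible to a
magnitude-of-cosine signal.

Steps are typed by rest gaps (2.0 s, echoing the protocol's rests):
*initial* if no step ends within the gap before FO, *terminal* if none
begins within the gap after FC, otherwise *steady*; a lone step is
terminal.  A step is invalid iff any of its three events falls inside a
detected turning interval; invalid steps keep their events but are
excluded from the binary label channels.

All detection constants are configuration, logged into run metadata; none
is claimed to be canonical.

## Windows and class balance

Each training example is a 251-frame slice (~2.5 s) whose binary target
is the phase's label at the middle frame (0-based offset 125); a
recording of n frames yields n − 250 windows, and events within 125
frames of an edge are unreachable by construction.  Labeled frames are a
sub-percent minority, so desk-scale training balances the stream:
targets are dilated ±2 frames around each event (matching the ±5-frame
scoring tolerance), all positives are kept, and negatives are
undersampled at 2:1 with 60% of the budget drawn from *hard* centers —
frames within 125 of any truth event, including events invalidated by
turning, which the model must learn to suppress.  Strategy `none`
preserves the raw imbalanced stream for fidelity runs.

## Models

Each per-phase model is a stacked LSTM — units [30, 60, 60, 60, 30], all
but the last layer returning sequences — with batch normalization
(momentum 0.99, ε = 0.001) and dropout (0.2) after every recurrent
layer, a 1-unit sigmoid head, Adam (lr 1e-4) on binary cross-entropy,
up to 100 epochs.  The implementation is a NumPy recurrent network with
explicit backpropagation through time; a finite-difference gradient
check in the test suite guards every backward pass.  Glorot-uniform
input kernels, orthogonal recurrent kernels, unit forget-gate bias.

The `desk_scale` profile makes the study runnable on one CPU in minutes:
units [8, 16, 16, 16, 8], 10 epochs, Adam 3e-3, batch 64, dropout 0.
Three desk-scale-specific findings are baked into the code:

- **Batch-norm calibration.**  After a few hundred updates the
  exponential moving statistics (momentum 0.99) lag far behind the
  trained weights, opening a large train/inference gap.  `train()`
  therefore ends with a calibration pass that replaces the moving
  statistics with exact training-set statistics (computed with batch-stat
  normalization, as in training).
- **No dropout at desk scale.**  These models underfit; dropout on 8–16
  unit layers is pure gradient noise and specifically prevents the rare
  boundary cases (terminal steps, gait initiation) from being fit.
- **Per-phase reading direction.**  A unidirectional final-state readout
  weights the most recent ~100 frames most heavily.  FO is flanked by
  discriminative peaks *after* the event (MidS, FC), so a forward reader
  works; FC's flanks *precede* it and its terminal-step pulse is faint,
  so FC uses a consensus of a forward and a time-reversed reader
  combined by geometric mean (both must agree, which cancels each
  reader's blind-side phantoms); MidS is flanked on both sides and reads
  forward.

Inference is deterministic: dropout off, batch-norm on stored statistics.
Sliding the model over a recording yields a probability trace with one
value per possible center frame (frames 125 … n−126).

## Event calling and scoring

Maximal runs of trace probability ≥ 0.5 become candidate events at the
run's argmax; events closer than 0.4 s merge keeping the higher
probability.  Each event is then refined to the nearest raw
angular-velocity-magnitude peak (prominence ≥ 5% of range) within
±0.3 s, recovering timing precision that smoothing and the model blur;
refinement never moves an event farther than the window.

Scoring is event-level precision/recall/F1 with one-to-one matching at a
±5-frame (50 ms) tolerance.  Matching processes events in time order and
pairs each prediction with the earliest unmatched truth event within
tolerance; for interval-structured candidates this greedy attains the
maximum possible number of matches (a nearest-first greedy does not —
two mutually shifted event trains can trap it), and a property test
checks it against an exhaustive optimal matcher on small instances.
Frame-level accuracy and BCE are also reported, always next to the
all-negative baseline: at realistic event densities (~0.2% positive
frames) an always-negative predictor already scores ≈ 0.998 frame
accuracy, so frame accuracy alone cannot distinguish a working detector
from a silent one.

## Synthetic gait simulator

The simulator emulates the movement repertoire the pipeline must handle:
straight bouts at slow/convenient/fast cadence (0.8 / 1.0 / 1.3 steps/s
per leg), 180°/360° turns taken with small steps, optional in-place
stepping, and 2 s rests.  Each step writes two negative Gaussian pulses
(toe-off and heel-strike surrogates, σ = 40 ms) flanking one positive
swing pulse onto the mediolateral gyroscope axis, so the magnitude shows
the FO–MidS–FC triple-peak; event times sit at 0% / 20% / 45% of the
stride (swing ≈ 45%, near the physiological share, and wide enough that
the faint terminal FC survives smoothing at the fastest cadence).
Amplitudes: steady 300/420/260 deg/s; an initial step's FO is 70% of
steady and a terminal step's FC 30%, the two shapes that break naive
peak pickers.  Free-acceleration bursts coincide with FO and FC; the
direction cosine is cos(heading), 0.9 at rest and sweeping during turns;
white sensor noise (8 deg/s, 0.5 m/s², 0.01) is added per channel.

Step timing carries 3% Gaussian jitter (human step-time variability is
roughly 2–4%).  This is not cosmetic: with metronomic steps the sequence
models learn to extrapolate periodicity — confidently predicting an
event one period before a bout starts — instead of reading step
morphology.

What the simulator does *not* model: real pulse shapes (only the
triple-peak morphology is faithful), inter-subject variability,
double-support dynamics, soft-tissue artifacts, drift or pathological
gait.  Passing tests therefore demonstrate that the pipeline's logic is
correct on signals with the documented morphology, not clinical
performance on recorded data.  Truth events inside turning or in-place
segments are marked invalid; turn steps are confined to the central 70%
of a turn where the heading deviation is detectable.

## Problem sizes and reproducibility

The standard desk study trains on 11 simulated trials (two bouts each,
bout lengths cycling 8/3/5/3 steps, the three cadences interleaved —
228 steps over both legs), ≈ 3400 balanced windows per phase, and
evaluates on a held-out trial with an unseen seed.  Measured on that
holdout, event-level F1 at ±5 frames is ≈ 0.94 (FO), ≈ 0.99 (MidS),
≈ 0.93 (FC); the labeler recovers 100% of truth events within ±1 frame
across 20 trials.  Every stage draws its randomness from an explicit
seed: the simulator from `SynthConfig.seed` (timing jitter on an
independent stream so it does not shift the noise draws), window
balancing from a derived per-recording seed, model initialization and
shuffling from `TrainConfig.seed`.  Identical configuration plus seed
reproduces every artifact bit for bit, and each CLI run writes its fully
resolved configuration to `run_metadata.yaml` before computing.

## Known limitations

- The two sensors are assumed frame-aligned; a length mismatch is
  resolved by truncating the longer series (wireless dropouts), but
  clock drift is not modeled or corrected.
- "Excessive jerky movement" is not an invalidation criterion (no
  jerk-based rule is implemented); in-place stepping without heading
  change is invisible to the turning detector and must be handled by the
  learned models, as covered by the hard-negative sampling.
- The full-scale `paper_fidelity` profile (full units, 100 epochs,
  unbalanced window stream) is provided but impractical on one CPU; its
  behavior at full scale is untested here.
- Event-time refinement searches raw AngVelMag only; refinement against
  the raw mediolateral gyroscope is a possible extension.
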