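# Methods

This note documents the models and procedures implemented in `bmifes`, the
defaults and why they were chosen, and what the synthetic benchmark does and
does not demonstrate.

## Signal model and preprocessing

EEG is represented as a channels × samples matrix in microvolts at 256 Hz
with the 16-electrode 10/10 montage.  Electrode positions use the standard
spherical 10/10 arc construction (one 10 % step = 18°, Cz at the vertex,
left/right homologues exactly mirrored); inter-electrode distances are chord
lengths on the unit sphere.  The montage is a fixed table — no per-subject
head digitisation — so the Laplacian weights are identical across sessions.

All temporal filters are **causal** (single-pass IIR): a second-order notch
at 50 Hz (quality factor 35) and a 4th-order Butterworth band-pass 5–40 Hz.
Causality matters because the online loop cannot look ahead; the offline
training path runs through the identical filters so the feature
distributions of the two phases match.  Trials starting in the first 0.5 s
of a recording are discarded to keep filter start-up transients out of the
data (with the cued paradigms this never removes a labelled window, since
the first task period starts at 5 s).

The surface Laplacian subtracts from each channel the inverse-distance
weighted average of all the others.  Its weight rows sum to one, so any
spatially common component (reference drift, line residue) is removed
exactly; the operation is linear and is verified in the tests against a
naive double-loop evaluation of the definition.

Normalisation is per-channel z-scoring **within each 1-s analysis window**,
applied after the Laplacian and before feature extraction.  The source
protocol states variance normalisation per processing window and channel but
not its position relative to the spatial filter; the order here
(notch → band-pass → Laplacian → windowing → normalisation) follows the
narrative order of the processing description and is fixed throughout.

## Paradigms and trial bookkeeping

*Motor imagery*: per run, rest and imagery cycles alternate starting with
rest (the interleaving is not specified in the source; strict alternation
matches the online phase's description).  Each cycle is 3 s cross + 2 s cue
+ task (10 s imagery / 30 s rest).  Four runs × four cycles per class give
160 s imagery and 480 s rest.

*Movement intention*: per run, ten relax and ten movement tasks alternate;
each task is 3 s cue + 7 s performance, and only the 4-s window between
seconds 4.5 and 8.5 of the task (`used_data`) is segmented, avoiding
cue-evoked potentials and the movement-bracketing transients.  The
protocol's "around 360 s per class" figure is not reproduced by the 4-s
selection (it would require 6-s windows) and is not treated as a target.

Windows are 1 s with 500 ms overlap, half-open `[t, t+1)`, aligned to period
onset.  **Long periods are segmented in consecutive 10-s blocks** — the
protocol's repetition unit — and windows never straddle a block boundary.
This choice reproduces the printed trial arithmetic exactly: 19 windows per
10-s repetition, 57 (= 3 × 19) per 30-s rest repetition, hence 304 imagery
and up to 912 rest trials per offline session.  (Plain sliding-window
segmentation of an undivided 30-s period would give 59.)  The pure
closed-form count `floor((L − w)/(w − o)) + 1` is exposed as
`window_count()` and property-tested against exhaustive enumeration.

## Features

*Motor imagery*: one-sided periodogram PSD (rectangular window, no
detrending, no log transform — the simplest estimator consistent with "the
periodogram method") sampled at the integer frequencies 8…36 Hz.  A 1-s
window at 256 Hz puts the DFT bins exactly on those frequencies, so no
interpolation occurs; 29 features per electrode, 464 per trial,
channel-major layout (persisted with the model, enforced at prediction
time).

*Movement intention*: per electrode, sums of the one-sided PSD bins over
mu 8–12 Hz, low beta 13–24 Hz and high beta 25–30 Hz, edges inclusive
(5/12/6 bins).  Whether the original band sums used density or raw-power
normalisation is unstated; sums of one-sided density bins are used as the
package convention (any fixed scaling is absorbed by the classifier's
feature standardisation).  The seven non-empty band subsets are enumerated
singles-first (1 = mu, 2 = low beta, 3 = high beta, 4 = mu+low, 5 = mu+high,
6 = low+high, 7 = all three), consistent with the reported per-subject
selections (a mu-only subject on combination 1, a low-beta-only subject on
combination 2, all-bands on 7).

## Classification

The classifier is an SVM with RBF kernel behind a feature standardiser.
C and gamma are not stated in the source; they are chosen by a seeded inner
3-fold grid search over C ∈ {1, 10, 100} × gamma ∈ {'scale', 0.01}
(configurable).  Class weighting is disabled: imbalance is handled only by
subsampling the rest class to 1:1, 2:1 or 3:1 rest:task, drawn uniformly
without replacement from a seeded generator.

Model assessment is run-as-fold cross-validation.  Reported accuracies are
per-class percentages plus a **total defined as the unweighted mean of the
two class accuracies** (balanced accuracy).  This matches the printed CV
tables of the source protocol — e.g. a 3:1 model with 0.3 % task and 99.5 %
rest accuracy totals 49.9 %, not the trial-weighted 74.7 % — and keeps the
chance level at 50 % under deliberate rest oversampling.

The rest:task ratio is selected by an explicit operationalisation of the
informal two-criteria rule ("total accuracy, but also maximise rest
accuracy"): among ratios whose total is within a margin (default 5 points)
of the best total, pick the highest rest accuracy; ties go to the larger
ratio.  The margin rule is a package choice, not a fidelity claim — the
source does not formalise its trade-off (and its own tables contain a
selection the rule would not make).  The selection report always lists all
candidates.  Band-combination selection simply maximises total accuracy
(ties → more bands, then lower id).

## Online decision rule

Per 1-s window (500 ms hop) the model predicts task/rest; a command is
emitted only at the n-th consecutive task prediction (default n = 3,
≈ 1.5 s of consistent evidence).  The counter resets on any non-task
output, at period boundaries, and after a command.  Commands alternate
extension/flexion with the arm state, starting from a flexed arm.  In the
simulated online phase, rest periods are fixed at 10 s; an imagery period
ends at its first command, followed by a 5-s movement window that is never
classified; commands during rest periods are logged but never actuate
stimulation (they count only toward FPR).  The false-command probability of
the rule is verified against an exhaustive run-length dynamic-programming
oracle and is non-increasing in n.

For the intention pathway the decision is taken once per `used_data` window,
when the cue dot disappears: the implementation takes a majority vote over
the period's seven window predictions (ties → rest).  Whether the original
system also applied a consecutive rule there is unclear; the single
end-of-period decision follows its stated timing.

Scoring is period-level: TPR = % of task periods with a correct command,
FPR = % of rest periods containing at least one suppressed command,
ACC = % of all periods resolved correctly.

## Closed-loop FES simulation

The reference is the minimum-jerk quintic; its velocity is bell-shaped,
symmetric about T/2, and peaks at 1.875 (qf − q0)/T.  Default movement
duration T = 2 s (typical completion time), with a 5-s hard window per
movement.

The plant is a **nominal linear elbow**: normalised inertia 1, viscous
damping 3 s⁻¹, stimulation gain 15 (deg/s²)/mA, first-order activation lag
80 ms, angles in degrees, safety limits (−45°, 225°).  It is a desk-scale
stand-in for a human arm in a gravity-compensated exoskeleton: no recruitment
nonlinearity, no fatigue, no joint hard-stops.  For this plant the ultimate
gain and period under proportional control have the closed form
ω₁₈₀ = √(b/(Jτ)), Ku = 1/|G(jω₁₈₀)| (Ku ≈ 3.10, Tu ≈ 1.03 s); the closed
form is used instead of an empirical oscillation probe because it is exact
and deterministic, and a test confirms it by simulation (sustained
oscillation at Ku with period Tu, decay below it).  PID gains follow the
classic Ziegler–Nichols closed-loop table Kp = 0.6 Ku, Ki = 1.2 Ku/Tu,
Kd = 0.075 Ku Tu.

The discrete PID (default dt = 5 ms, required ≤ 10 ms) uses
conditional-integration anti-windup: the integrator freezes while the output
is saturated and the error would push it further in.  The signed output maps
to a muscle (positive → triceps/extension, negative → biceps/flexion) and
its magnitude to the stimulation amplitude, clamped to the per-subject
maximum (default 25 mA; pulses 40 Hz / 350 µs).  With the defaults the
10° step settles to < 0.05° error within 5 s and the 70° minimum-jerk reach
tracks with ≈ 3° RMSE; the amplitude cap is asserted at every step of every
simulation.  The sampling rate and anti-windup scheme are configuration
choices, not fidelity claims.

## Synthetic EEG generator

Each channel is an independent unit-RMS 1/f background (default 5 µV)
plus three band-limited oscillators (4th-order Butterworth-filtered white
noise; defaults 4/2/1 µV RMS for mu/low-beta/high-beta) weighted by a fixed
two-lobe Gaussian topography centred on C3 and C4 (σ = 0.6 chord units), so
C3/Cz/C4 carry the strongest rhythms.  From 0.5 s before each task period
(ERD begins before movement) to the period's end the rhythm envelope is
multiplied by 1 − erd_depth; for 1.5 s afterwards by ers_gain (default 1.5).
Motor-imagery sessions use the same mechanism, reflecting that imagined and
executed movement share the cortical pattern.  Because the carriers are
stochastic, single-trial ERD is not visually evident — only averages show
it, as with real recordings.

The source reports no quantitative ERD depth for its subjects, so the
defaults are chosen for test discriminability, not subject fidelity:
depth 0.6 is the "strong responder" condition, depth 0 the null, and the
cohort generator draws depths from a configurable spread (default 0.3–0.7)
to emulate harder cases.  What the generator deliberately omits — volume
conduction, EMG/EOG artifacts, cue-evoked potentials, non-stationary
background — bounds what passing tests show: they validate the *pipeline*
(arithmetic, estimators, decision logic, recovery of injected effects), not
clinical-grade performance on real patient EEG, whose printed accuracies are
not reproducible from synthetic data and are not targets.

## Problem sizes and determinism

Simulation-heavy checks use reduced study sizes as the package's own
benchmark conditions: recovery and monotonicity tests run four-run sessions
with two repetitions per class (≈ 420 s of EEG each) and a fixed SVM setting
(C = 10, gamma = 'scale'); the acceptance script runs the full four-run ×
four-repetition offline protocol for both pathways and a four-run online
phase.  The depth-monotonicity trend uses 20 seeds × 4 depths with a
per-pair sign test (≥ 17/20 non-decreasing) plus strictly increasing means.
Every stochastic component (generator, subsampling, inner CV shuffling)
is seeded explicitly; two runs with the same configuration and seed are
byte-identical, and each CLI report prints its configuration hash and seed.

## Known limitations

- The nominal plant and its tuned gains are internally consistent but not
  subject-specific; tracking numbers characterise the simulation, not a
  patient's arm.
- The EDF writer covers the subset of EDF needed here (16-bit, 1-s records,
  µV); it is verified by round-trip through an independent reader.
- The delimited recording format does not encode the sampling rate and
  assumes the 256 Hz acquisition default on load.
- Run-fold CV with windows overlapping 50 % within a period slightly
  correlates train/test samples *within* a fold but never across folds
  (folds are whole runs).
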