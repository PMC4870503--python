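# Methods

This note documents the models, conventions and open design choices behind
`biocyberloop`. It covers what each stage assumes, the defaults and their
units, what the synthetic data generator does and does not emulate, and the
numerical conventions tests rely on.

## Synthetic EEG generator (`synth`)

The generator emulates only what the downstream chain consumes: two channels
(Fz, P4) whose theta-band and upper-alpha-band RMS follow a scripted
timeline of player states.

**Oscillator model.** Each rhythm is a narrowband filtered-noise process:
white Gaussian noise brick-wall bandpassed (FFT-domain) to the oscillator
band, normalised to unit RMS, then multiplied by a per-sample RMS envelope
`rms_amplitude × multiplier(t)`. Filtered noise rather than a pure sinusoid
is deliberate: spectral estimates of the output have realistic chi-squared
estimator variance, so averaging behaviour in the DSP chain is actually
exercised. Defaults: theta centred at 6 Hz (the grand-average theta peak)
with 2 Hz bandwidth; upper alpha centred at 11.75 Hz with 2.5 Hz bandwidth,
exactly filling the 10.5–13 Hz analysis band.

**Background.** 1/f noise (`power ∝ 1/f^1`, rms 10 µV) on both channels, so
band powers must be estimated against a floor rather than read off.

**Amplitude convention.** Absolute baseline band amplitudes are not a
quantity the loop's design fixes, so they are a synthetic convention here:
theta rms 7 µV (49 µV² against a ~11 µV² 1/f floor inside 4–8 Hz) and upper
alpha rms 5 µV (25 µV² against ~3.4 µV² inside 10.5–13 Hz). The values were
chosen so that (i) each rhythm clearly dominates the background within its
band, and (ii) scripted deviations across the full trigger range (up to 5×
RMS for the conservative profile) remain below the 100 µV muscle-artifact
criterion on the channel being read. Larger conventions would make strong
theta *increases* (engagement/zone scripts) indistinguishable from muscle
artifact — which the chain then correctly refuses to act upon.

**State scripts.** `script_from_states` maps a named state and a deviation
strength `s ≥ 1` onto RMS multipliers per the two-axis state model: boredom
(θ×1/s, α×s), overload (1/s, 1/s), engagement (s, s), zone (s, 1/s),
baseline (1, 1). Segment boundaries use a 100-ms linear crossfade of the
envelope; a step would leak broadband power into both bands.

**Not emulated:** multichannel topography, ocular artifacts, reference
electrodes, any coupling from game demand back to the EEG. Streams are
open-loop: passing tests therefore demonstrate that the chain implements its
rules on signals with known ground truth, not that those rules regulate a
human player.

## Signal chain (`spectral`)

* **Filtering.** Kaiser-window linear-phase FIR bandpass, default 2–30 Hz.
  The design parameters not fixed by the loop description default to 60 dB
  stopband attenuation and a 1 Hz transition width; the contract (±0.5 dB
  passband, ≥60 dB stopband, exact coefficient symmetry) is tested against
  `scipy.signal.freqz`. Applied zero-phase via centred convolution.
* **Spectra.** FFT power over tapered windows, default 2-s Hanning at 50 %
  overlap. Window length in samples is always `duration × rate` — 512 points
  at the 256 Hz offline rate, 1024 at the 512 Hz loop rate — never a
  hard-coded sample count. Per-bin power is divided by the taper's
  mean-square gain so the full-spectrum bin sum is an unbiased estimate of
  signal variance with or without the taper (Parseval-checked in tests).
* **Band power.** Sum of bin powers whose centres lie in the closed interval
  `[f_lo, f_hi]` (bin-sum convention, documented rather than density ×
  bandwidth). Two theta conventions coexist deliberately: 4–7 Hz for
  offline analysis, 4–8 Hz for the real-time loop; both are configuration.
* **Artifact exclusion.** A frame is flagged when any sample of its source
  window on any channel exceeds 100 µV in magnitude; flagged frames are
  excluded from every aggregate. Flags are computed on the unfiltered
  signal, since the bandpass would attenuate exactly the low-frequency bulk
  of movement artifact.
* **Theta individualisation.** The per-participant 1-Hz theta window is
  automated as the bin in 4–7 Hz maximising the across-condition range of
  log power (original procedure: visual inspection). Ties resolve to the
  lowest frequency; the window is clipped to stay inside 4–7 Hz.
* **Epoch aggregation.** Epochs average *linear* frame powers; logs are
  taken on demand only. A frame belongs to an epoch only when its window
  lies entirely inside the epoch — four 2-s frames per 5-s epoch at 50 %
  overlap. This keeps each real-time decision causal and prevents a window
  straddling a state change from contaminating the preceding epoch. The
  alternative assignment by frame start alone is available
  (`containment="start"`). An epoch with zero clean frames is invalid.

## State model (`states`)

Baselines are mean linear band powers over ≥30 s of clean resting frames
(the 60-s default rest duration is a convention; the loop's design gives
none).

**Trigger arithmetic.** A literal "decrease by 200 %" is impossible for
non-negative linear power. Triggers are therefore read ratio-symmetrically:
an `X %` trigger fires upward at `ratio ≥ 1 + X/100` and downward at
`ratio ≤ 1/(1 + X/100)`, preserving the printed magnitudes (100/150/200)
while making increase and decrease exact mirror images on the log scale.
This is an interpretation, documented as such, not a formula stated by the
original design.

**Partition.** Boredom and overload require *both* axes to trigger
(theta-down with alpha-up, and theta-down with alpha-down respectively).
All remaining pairs — including theta-down with alpha in the neutral band —
are non-adaptive; they split into engagement (alpha-up, i.e. low cortical
activation) and zone (otherwise) purely for reporting, since the controller
holds for both. Deviations are ratios of linear power, not log power:
"percent change" is defined on power, and the log transform in offline
analysis served distributional normalisation, not the trigger rule.
Artifact-invalid epochs are `indeterminate` and always hold: a covert
adaptive system should never act on invalid data.

## Game engine (`tetris`)

Board 10 × 20 booleans, row 0 at top, columns 0-based; seven tetrominoes
with hard-coded rotation tables, drawn independently and uniformly (the
original "random order", not the modern bag randomiser). Demand levels 1–10
map to drop speed geometrically, `2.5 × 8^((level−1)/9)` squares/s, anchored
at the measured slow (2.5) and excessive (20) presets; a geometric ladder
makes each level a constant multiplicative difficulty step. Fractional drop
progress accumulates across ticks.

* **Fixed-demand mode** caps the stack at board centre by discarding bottom
  rows (discards never count as cleared), so a fixed-duration game cannot
  die.
* **Adaptive mode** declares death when blocks reach the top two rows or a
  spawn is blocked; the board empties, the level returns to 1 and the reset
  counter increments. A `death_enabled=False` option substitutes the centre
  cap, for experiments where resets must not interfere.
* **Coins.** The cumulative coin target is `floor(70 × cleared_rows /
  max_possible_rows)` with `max_possible_rows = squares delivered / board
  width`; each 10-s accrual awards the shortfall clamped to [0, 7]. This
  cumulative reading is the only one consistent with both printed
  constraints (70-coin cap, 0–7 per accrual — naively 18 × 7 = 126 ≠ 70).
* **Bot.** Greedy one-piece placement (lines cleared, holes, aggregate
  height, bumpiness) with a simple human motor model: decision latency
  `0.15 + 0.6(1 − skill)` s per piece and action rate `1 + 5·skill` per
  second, skill ∈ [0, 1] (skill 0 = no input at all). The motor limits are
  the package's own model of plausible human tapping, and are what makes
  row-clearance percentage fall as drop speed rises.

## Session loop (`loop`)

Epoch length 5 s, session 300 s by default. Each epoch is played at the
current level; at its end the epoch's band powers are classified and the
level moves by ±1 (the smallest covert step on the 1–10 scale), clamped to
[1, 10]. Adjustments never occur mid-epoch; death resets can. The manual
benchmark replaces the classifier with a schedule of spoken
"higher"/"lower" commands applied at their timestamps. Non-overlapping
epochs with at most one adjustment each is a documented choice; the loop
description does not state whether assessments overlapped.

## Metrics (`metrics`)

Session behaviour is summarised as upward/downward adjustment counts, reset
count, and *time-weighted* mean difficulty (an unweighted per-epoch mean
would misrepresent sessions with mid-epoch resets). The conservation
identity — effective increases − effective decreases − reset level losses =
final − initial level — uses *effective* adjustments, i.e. excluding those
swallowed by the 1–10 clamp: the original evaluation itself noted triggers
that could not slow an already-slowest game. Recovery sweeps score the
classifier per epoch against the generating script, counting a scripted
baseline epoch as correct when it lands in either non-adaptive state.
Human-subject session means from the original evaluation are qualitative
context only and are never used as numeric oracles.

## Problem sizes and numerical conventions

Simulation defaults used throughout the tests and experiments: 512 Hz
sampling (256 Hz for offline-convention fixtures), 300-s sessions, 30-s
scripted state blocks aligned to epoch boundaries, 20 sessions per
condition in recovery sweeps, 30 Hz game tick. Band-edge comparisons use a
1e-9 Hz tolerance so exact-binary bin centres (0.5 Hz grid) compare
predictably. All randomness flows through `numpy.random.default_rng`
seeded per run; identical configuration and seed reproduce recordings, game
trajectories and logs bit-identically.

## Known limitations

* Open-loop EEG: no model of how demand changes a player's EEG, hence no
  emergent negative-feedback equilibrium — only the controller's rules are
  testable, not closed-loop convergence on a human.
* The artifact rule is a single amplitude threshold; real muscle artifact
  has spectral structure the generator does not imitate.
* The bot's greedy policy has no lookahead and its motor model is
  deliberately simple; its clearance percentages are qualitative analogues
  of human performance trends, not calibrated to them.
* EDF/BDF ingestion is not implemented; the plain-text signal format is the
  interchange format.
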