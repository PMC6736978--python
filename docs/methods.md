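# Methods

## Stimulation model

The pattern generator produces, per muscle group, a periodic envelope
with period `P = on_time + off_time + 2*transition_time`: an ON plateau
at level 1, a linear ramp down over `transition_time`, an OFF plateau at
`off_pct` (the OFF-stimulation percentage, default 0), and a linear ramp
back up. The RIGHT group is the LEFT envelope delayed by `P/2`; time zero
is the start of the LEFT ON plateau, which makes fixtures deterministic.
With the protocol timing (5/3/1 s) the parameters satisfy
`on = off + 2*transition`, so the two ON plateaus tile: one side begins
its ON transition while the other is still fully stimulating, and at
every instant at least one group is at full level. The validator reports
"overlap" or "gap" for other parameter choices but generation proceeds.

The envelope modulates pulse *width* (0–500 μs per channel); pulse rate
(30 Hz) and amplitude (138 mA into a nominal 1 kΩ ∥ 100 nF load) are
fixed device properties. Pulses are discrete (time, width, amplitude)
events on a `t0 + k/30 s` lattice; zero-width pulses are omitted. Ramp
shape is linear and monophasic/biphasic pulse shape is not modelled —
only timing, width and amplitude matter downstream. A continuous
(constant-level) mode models the operator-controlled stand-up assist;
hand-over to the cyclic pattern is pinned to a LEFT-ON plateau start,
where both group envelopes equal 1, so a full-level hold switches without
a level discontinuity.

## Sensing model

Rail forces: each DoF is the mean of two co-planar load cells (static
torque offsets cancel in the average) with a linear raw→newton
calibration fitted by least squares to a 0–58.5 kg sweep in 4.5 kg steps
(14 points). The fit includes an offset term; on noiseless synthetic
lines it recovers gain and offset to machine precision, and with additive
Gaussian noise the gain bias shrinks as points are added (property
tests). Plates: a 6×6 invertible matrix maps six raw channels to the
wrench (Fx, Fy, Fz, Mx, My, Mz); application is a matrix–vector product
and therefore linear. Raw units are abstract counts/volts; only
calibrated outputs carry physical units. `g = 9.81 m/s²` everywhere.

## Session container

All timestamps are seconds from session start; transport-layer clocks
are out of scope. A recording is a directory: `session.json` (metadata,
masses, grid rate, events, stream manifest) plus one CSV per stream.
Values are written with six decimal places, so a write/read round trip
is lossless to 1e-6. Resampling onto the uniform grid uses linear
interpolation (isolated in `resample_to_grid` so it can be swapped);
synchronization intersects spans and never extrapolates. Coordinates:
X lateral (positive toward the participant's right), Y anterior,
Z vertical; plate Fz positive is upward support; rail pull reads
negative.

## Virtual participant

The simulator is behavioural: the exercise literature gives forces and
angles, not dynamics, so no musculoskeletal model is attempted. A
normalized lean drive `w(t) ∈ [−1, 1]` tracks the difference of the two
stimulation envelopes through a first-order lag (time constant 0.4 s,
the human response to the pattern and the game cue). Two drives are
derived from it:

- the **posture drive** (trunk sway) holds the lagged plateau — the lean
  is maintained through the ON period;
- the **force drive** adds a raised-cosine "commitment surge" at each ON
  plateau midpoint (the hoop time; depth 0.15 of the drive, half-width
  0.4 s): participants push hardest as the hoop arrives, so each cycle's
  force peak is a brief, well-defined apex rather than a flat plateau.

Body weight partitions exactly before noise. The arms carry
`arm_support_frac` (default 0.0759 of BW, sign negated for a "pull"
strategy), a knee-pad/harness residual carries `residual_frac` (0.0241,
under the 3% BW cap), and the legs share the remaining ~90% BW with the
left-leg share `center + (s − center)·w`, where `center` splits the leg
total evenly and `s` is the session's supporting-leg level. At the apex
of a mature cycle the stimulated leg therefore carries
`mature_support_frac` (default 0.7532) of body weight.

Session structure: 10 s of centered standing under continuous
stimulation (events `stand_start`/`exercise_start`), then the cyclic
pattern for the rest of the 3600 s session, ending with `sit_start`.
Habituation scales the drive amplitude by `(t/300 s)³` (clipped at 1):
the cubic shape keeps early leans below the 50% BW detection threshold
for the first ~2–3 minutes, reproducing the excluded "artificial peaks"
phase and a countable-cycle total in the 650–700 per hour range.
Longitudinal improvement interpolates the session-level support from
0.6369 (session 1) to 0.7861 (saturated from session 8), with a small
documented drift (0.26 pp/session) inside the early block; the two
printed summaries of the improvement (grouped-mean difference 14.92 pp
versus per-participant mean increase 13.88 pp) are mutually inconsistent
for identical participants, and this profile lands the per-participant
first-five/last-five difference between them. Sway half-angle follows
the same profile from 6.065° to 7.61°, chosen so that a left/right pair
of mature early-session leans spans the reported range-of-motion scale.
Cycle-to-cycle amplitude jitter (6.5% relative SD, ≈2% BW at the apex)
and session-level jitter (0.5 pp SD) model human variability.

Noise is added last: Gaussian with 5 N SD on force channels (20% of that
on moments) and 2 mm on marker coordinates, band-limited by a 30 ms
Gaussian kernel — adjacent 100 Hz samples are correlated, as after an
acquisition anti-alias chain. Band-limiting matters beyond realism: peak
detection takes a maximum over samples, and the expected maximum of wide-
band noise over a flat plateau would bias every detected peak upward by
1–2% BW. The surge apex plus correlated noise keep that bias at ~0.3–0.6%
BW, which is what makes the simulator's defining contract hold: the
support fraction configured is the support fraction the analysis pipeline
recovers (verified by a Monte-Carlo recovery test).

The sensing chain sits in the loop: physical wrenches are converted to
raw sensor units through the inverse plate matrix and inverse rail
calibrations (including the two-cell averaging with static offsets) and
calibrated back before recording.

What the simulator does **not** emulate: fatigue (the study observed
none), balance-loss events, sit-to-stand dynamics beyond the threshold
envelope, marker sets beyond the clavicle, inter-participant behavioural
differences beyond mass and arm strategy, and any drift between sensor
clocks. Passing tests therefore show that the *pipeline* recovers the
generating parameters under these idealized conditions — not that the
pipeline is robust to artifacts real sessions may contain.

## Analysis pipeline

Peak detection enumerates strict local maxima (the first sample of a
flat maximum is its time) at or above `min_frac` (0.5) of body weight,
drops candidates inside labelled transfer/rest intervals or within
`min_sep` (5 s) of either recording edge, then prunes greedily by
descending amplitude so that no two survivors are closer than `min_sep`.
The filter order (threshold → exclusion/edges → separation) is fixed and
mirrored by the brute-force oracle used in tests. The 5 s separation is
applied per plate; opposite-side peaks alternate ~5 s apart by design
and would otherwise suppress each other. Forces at each peak are grid
samples (linear interpolation off-grid). The lean angle is
`atan2(x − x_ref, z)` in degrees with the reference taken as the mean
clavicle position from `stand_start` to the first detected peak (the
initial centered phase); a common lateral offset cancels in ROM. ROM
pairs consecutive cycles disjointly and sums absolute angles; a trailing
unpaired cycle is dropped. Summaries flag all statistics undefined at
zero cycles.

## Statistics

`rm_anova` computes the one-way repeated-measures decomposition from
sums of squares (conditions, subjects, residual) without sphericity
correction, matching the printed degrees-of-freedom structure
(3 participants × 10 sessions → F(9, 18)). Cross-checks: a cell-by-cell
textbook oracle (1e-10), statsmodels `AnovaRM`, and a type-I calibration
under the null. `tukey_hsd` uses `q = |Δmean|/√(MSE/n)` with p from
`scipy.stats.studentized_range`, itself cross-checked against the k=2
t-distribution identity and direct quadrature of the distribution's
definition. `compare_periods` builds the first-five/last-five session
table, runs the omnibus ANOVA, applies the Tukey contrast to the grouped
means using the ANOVA error term (all-pairs contrasts are exposed
separately because the original post-hoc family is ambiguous), and
reports group means, SD, SE and the per-participant difference. Reported
p-values are truncated to four decimals at the formatting layer only.

## Problem sizes and numerical choices

The reproduction script uses 12-session longitudinal series per
participant (the improvement profile saturates at session 8, so the
last-five block sits entirely on the late level, as in the study's
first-five/last-five design), two early sessions per participant for
ROM, and single full 3600 s sessions for counts and stability; all
randomness derives from one seed through `numpy` `SeedSequence` spawning.
Peak plateau ties take the first sample; coincident bilateral peaks
resolve to the larger; container round-trips are exact to the written
six decimals; envelope boundary values are continuous by construction
(plateau end equals ramp start). Degenerate inputs raise typed errors
(`ConfigurationError`, `DataError`, `SpanError`, …) rather than
propagating NaNs.

## Known limitations

- The simulator's behavioural waveform is calibrated to the pipeline's
  peak statistic; other statistics of the same recordings (e.g. plateau
  means) are not constrained to published values.
- Only the clavicle marker is simulated; the analysis uses no other
  marker.
- The stats module reproduces the *methods* (ANOVA/Tukey machinery,
  validated against oracles), but the study's printed F and post-hoc
  p-values depend on unobserved raw human data and are not reproduction
  targets.
- C3D export of the marker stream is not implemented; the plain-text
  container is the interchange format.
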