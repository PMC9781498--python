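# fcskill

Individualized estimation of longitudinal change in motor skill from
resting-state EEG functional connectivity.

Frequent, objective assessment of motor function usually requires a trained
examiner. This package implements an alternative: a participant traces a
curved track with a computer mouse (spatial tracing error = objective skill
measure), rests for five minutes of EEG before and after each training
session, and a per-participant statistical model estimates the session's
tracing error from resting-state phase-synchronization indices alone. It is
aimed at researchers in motor-learning and rehabilitation neurophysiology who
want to prototype or validate this class of individualized brain-behavior
models without access to clinical recordings — a synthetic-data module
generates complete studies with planted, known ground truth.

## Method

**Behavior.** Each tracing trial is scored by the unsigned area between the
pointer trajectory and the track section (pixels², converted at 0.25 mm² per
pixel), optionally multiplied by the trial duration and augmented by an
endpoint-overshoot penalty. A session of 90 trials is summarized by the
median over all trials (single-median) or by the medians of the first and
last 30 trials (dual-median: pre- vs post-training skill).

**Connectivity.** The 32-channel recording (250 Hz, 10–20 montage) is
band-passed 1–45 Hz (zero-phase FIR), convolved with 15 complex Morlet
wavelets (three sub-band centers per canonical band: δ, θ, α, β, γ), and each
of the 496 electrode pairs is scored per 1-s epoch by one of five estimators.
With `S = z_x z_y*` the per-sample cross-spectrum:

- phase clustering (PLV): `|⟨S/|S|⟩|`
- phase lag index: `PLI = |⟨sign Im S⟩|`
- weighted PLI: `|⟨Im S⟩| / ⟨|Im S|⟩`
- spectral coherence: `|⟨S⟩|² / (⟨|z_x|²⟩⟨|z_y|²⟩)`
- imaginary coherence: `|Im ⟨S⟩ / √(⟨|z_x|²⟩⟨|z_y|²⟩)|`

PLI, wPLI and imaginary coherence ignore zero-lag (volume-conducted) mixing.
The scalar *connectivity index* per pair and center frequency is the maximum
epoch value inside a 120-epoch window starting 30 s into the recording.

**Brain–behavior model.** For a candidate combination (estimator × center
frequency × pre/post EEG × behavior option), PLS correlation decomposes the
z-scored brain-behavior cross-correlation; with one behavioral variable the
salience is the correlation vector `r` normalized and the singular value
`‖r‖₂`, tested by permuting session labels. Channels are kept only if their
bootstrap ratio (correlation / bootstrap SE over session resamples) clears a
threshold (default |BSR| ≥ 2) in more than 80% of 50 repetitions. PLS1
regression with rank-one deflation maps the retained channels to a
feature-space coefficient vector; channels are then pruned backward (smallest
|standardized coefficient| first) until the post-hoc power of the regression,
`f² = R²/(1−R²)`, noncentral-F with `λ = f²·n`, reaches 0.8 at α = 0.05.
Accuracy is the leave-one-session-out RMSE as a percentage of mean behavior,
with a zero-intercept fit of estimated vs actual as a calibration check. The
best candidate minimizes RMSE% (ties: fewer channels, lower permutation p).

## Worked example

`python examples/pls_model_selection.py` simulates a participant's
connectivity-index matrix (8 sessions × 496 pairs, 3 columns linearly tied to
behavior) and runs the full selection chain:

```
planted columns: [49, 66, 107]
permutation p-value of the brain-behavior correlation: 0.5737
(the omnibus test pools all 496 correlations, so 3 informative columns
 barely move it -- channel selection rests on the bootstrap consensus)
consensus channels (70): [8, 17, 23, 33, 39, 49, 58, 60, 66, 67, 97, 100] ...
after power-constrained pruning: ['f023', 'f058', 'f066', 'f107', 'f267', 'f418']
in-sample R^2 0.9997, power 1.000
LOO RMSE 0.0740 = 0.75% of mean behavior
estimated-vs-actual slope through origin: 1.0001
```

Two of the three planted columns (f066, f107) survive pruning, the held-out
estimation error is under 1% of the mean tracing error, and the
estimated-vs-actual slope is indistinguishable from 1 — the model tracks the
planted skill trajectory. The other examples cover trial scoring
(`score_tracing_session.py`), the connectivity stage
(`connectivity_indices.py`) and the end-to-end on-disk pipeline with the YAML
config and CLI (`full_participant_cli.py`, which selects the planted 21 Hz
beta center with a 1.95% LOO RMSE at reduced scale).

A thin CLI mirrors the stages: `fcskill simulate | score-trials |
connectivity | search | evaluate | report`.

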