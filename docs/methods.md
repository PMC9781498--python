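# Methods

This note documents the models, estimators and design choices behind
`fcskill`, what the synthetic-data generator does and does not emulate, the
numerical conventions, and known limitations.

## 1. Tracing-performance scoring

**Track geometry.** The track is a four-lobed closed figure built from eight
quarter-ellipse sections meeting at five vertices (the center and four lobe
tips on the axes). Each arc from center to tip is a genuine quarter-ellipse
constructed on the Thales circle over the chord: placing the ellipse center
on that circle (at 60° by default) guarantees the two endpoints lie on
conjugate perpendicular semi-axes, so the parameter range 0–π/2 sweeps
exactly one quarter of an ellipse with unequal axes. One side of each lobe is
the mirror image of the other, making the full pattern symmetric about both
screen axes. Extents default to the pattern's tip-to-tip distances; with the
study-scale physical mapping they correspond to roughly 35 cm × 25 cm of
mouse travel. Units are screen pixels; 1 px² = 0.25 mm² (0.0025 cm²), hence
a linear scale of 0.05 cm/px for distance-valued penalties.

**Position error.** The score of one trial is the unsigned area enclosed
between the pointer trace and the track section. The two polylines are joined
end-to-end into a closed ring; self-intersections are noded and the absolute
areas of the resulting sub-loops are summed (shapely `polygonize`), so
excursions on alternating sides of the track cannot cancel. This is exact for
polylines — no resampling or rasterization is involved; a 0.1-px
rasterization serves as the independent test oracle (agreement within 1% on
random perturbed traces).

**Timing conventions** (the protocol states a 1-s terminal dwell but not the
mechanics; these are configurable choices):

- *movement onset*: first sample displaced > 1 px from the start position;
- *came to rest*: first sample opening a period of ≥ 1 s entirely within a
  5-px radius of the destination vertex (dwell start);
- *trace time*: onset → dwell start;
- *endpoint penalty*: Σ of per-sample distances to the destination (in cm)
  for samples strictly between the first entry into the rest radius and the
  dwell start — zero when the pointer arrives and stays;
- the scored trace segment runs onset → dwell start, and the track is
  truncated at its vertices nearest the segment endpoints, so a perfect trace
  scores exactly zero.

The combined position-time score multiplies (position error + endpoint
penalty) by trace time; a switch (`penalty_mode="post"`) instead adds the
penalty after the multiplication, since the verbal definition admits both
readings. The penalty adds a length-valued quantity to an area-valued one;
this is dimensionally odd but follows the scoring rule as specified.

**Session summaries.** Median of all trials (single-median) or of the first
and last 30 (dual-median); even counts use the midpoint of the two central
order statistics. The SD-ratio diagnostic (SD of the first *n* trials over
their median) quantifies how many trials are needed for a stable estimate.
Incomplete trials (no terminal dwell) are flagged and excluded with a
warning.

## 2. Connectivity stage

**Front end.** Zero-phase FIR band-pass 1–45 Hz (Hamming window,
forward–backward, default ~875 taps at 250 Hz: stopband > 50 dB per pass,
doubled by the two passes; transition width just under the 1-Hz edge).

**Filter bank.** Fifteen complex Morlet wavelets, three per canonical band.
Only four centers are pinned by the study configuration (alpha-high 13 Hz,
beta 16/21/27 Hz); the remaining eleven sit at rounded sub-band midpoints
(δ 1.5/2.5/3.5, θ 4.5/6/7.5, α 9/11, γ 32/37/42), all overridable. Cycles
default to 7 (envelope SD `n_cycles/2πf`); below 3 cycles the spectral
bandwidth is too wide for stable narrowband phase and construction is
refused. Wavelets are unit-energy; convolution uses reflect padding, and the
30-s analysis offset discards edge transients anyway.

**Epoch estimators.** All five synchronization measures are computed per 1-s
non-overlapping epoch (250 samples) from the per-sample cross-spectrum
`S = z_x z_y*`; formulas are in the README. Conventions: `sign(0) = 0` in the
PLI (numerically, `|Im S| ≤ 1e-12 |S|` counts as zero so that identical
channels score exactly 0); wPLI's 0/0 is 0; the epoch grid is anchored at the
recording start. Coherence estimators are computed per epoch (a per-epoch
normalization); for PLV/PLI this coincides with averaging instantaneous
quantities, for coherence it is one of two defensible readings and is the one
implemented.

**Peak-detected index.** The scalar per (pair, center) is the *maximum* epoch
value over epochs [30, 150) — a 2-min window starting 30 s in, out of a 5-min
recording. Two consequences worth stating plainly: the maximum of 120 noisy
epoch values is biased toward the ceiling (uncoupled narrowband pairs reach
peak PLI ≈ 0.8, and saturate at 1.0 under strong coupling), and it carries
irreducible extreme-value noise. The brain-behavior models therefore work off
the *session-to-session variation* of the index, not its absolute level, and
per-column correlations with behavior of ~0.7–0.9 are the realistic ceiling
for the EEG path.

## 3. PLS brain–behavior modeling

Features are z-scored and behavior mean-centered throughout; this makes
coefficient magnitudes comparable across channels, which the pruning rule
requires.

**PLSC.** With a single behavioral variable, the SVD of the z-scored
cross-correlation reduces to salience ∝ correlation vector and singular value
= its norm; both are computed in that closed form. Significance: permutation
of session labels, p = (1 + #{permuted ≥ observed}) / (n_perm + 1), default
2000 permutations. Robustness: session bootstrap (default 1000 resamples),
BSR = observed correlation / bootstrap SE; resamples in which a column or the
behavior becomes constant are excluded for that column. Zero-variance columns
are dropped with a warning.

**Consensus.** PLSC is repeated (default 50×) with independent bootstrap
streams; features with |BSR| ≥ 2.0 (≈ 95% normal interval; the "same level of
robustness" is interpreted as this fixed threshold, configurable) in *more*
than 80% of repetitions are retained.

*Small-sample caveats, measured on synthetic nulls:* (i) with 6–8 sessions
the strongest of ≥100 spurious correlations (|r| ≈ 0.9) is *stable under
bootstrap*, so a pure-noise consensus is sparse (≈ 2–15% of features) but
essentially never empty — the bootstrap measures sampling stability, not
significance, and the permutation screen is what controls false positives at
the candidate level; (ii) the omnibus permutation test pools the full
496-feature correlation norm, so a signal carried by only ~3 features barely
moves it — sparse effects pass the screen only rarely, whereas broad network
effects (tens of coupled pairs, the physiologically expected case) screen
reliably. Channel *identity* at n = 8 is statistically, not exactly,
identifiable: planted channels are strongly enriched in the consensus but
accompanied by stable spurious ones, mirroring the participant-to-participant
channel variability such studies report.

**PLSR.** PLS1 with rank-one deflation: per component the weight vector is
the normalized covariance `X_d'y_d` (the covariance-matrix SVD collapses to
this for one dependent variable), followed by scores, loadings, and deflation
of both matrices; coefficients return to feature space via
`W(P'W)⁻¹q`. Components default to `min(k, n−2)`; requesting more than
`min(n−1, k)` truncates with a warning; full-rank fits reproduce OLS, and
predictions match scikit-learn's NIPALS implementation to 1e-6 (test oracle).
A constant behavior series yields a mean-only model.

**Evaluation.** Leave-one-session-out refits everything *downstream of
channel selection*; selection itself is performed once on all sessions, as in
the original protocol — LOO RMSE therefore inherits some selection optimism,
which is visible in the synthetic leaderboards (spurious candidates can post
small RMSE). RMSE is reported as a percentage of mean behavior; since
session-to-session skill change is modest relative to absolute tracing error
(coefficient of variation ≈ 0.1 in the emulated regime), a mean-only
predictor already reaches ≈ 8–9% and the planted models reach ≈ 0.5–2%.
The zero-intercept least-squares slope of estimated vs actual is the
calibration summary.

**Power and pruning.** Post-hoc power of the overall regression F-test:
Cohen's `f² = R²/(1−R²)`, noncentral F with df (k, n−k−1) and `λ = f²·n`
(fixed-design convention; the Monte-Carlo oracle uses an orthonormalized
fixed design, for which this is exact). While power < 0.8 (or undefined
because n ≤ k+1) and more than one channel remains, the channel with the
smallest absolute standardized coefficient is dropped (ties by column order)
and the model refit; failure to reach the target with one channel is flagged,
not hidden.

**Model search.** Candidates are screened at permutation p < 0.05
(uncorrected, matching the original analysis — no FDR across the grid), then
consensus → prune → LOO; the winner minimizes RMSE% with deterministic
tie-breaks (fewer channels, lower p, grid order). The full leaderboard is
always emitted.

## 4. Synthetic data: what it emulates, and what it does not

**EEG.** Per-channel background is unit-RMS 1/f-power noise (spectral
shaping). A planted entry names two electrodes (a coupled pair) or more (a
synchronized network clique — all pairs coupled) plus a center frequency. The
oscillator is a narrowband stochastic process: a band-limited complex
Gaussian envelope (default bandwidth 0.5 × center; 0.35 × in the end-to-end
fixtures to keep the rhythm inside its sub-band) times a carrier. Electrode
*i* carries `κ·(lag-delayed shared envelope) + √(1−κ²)·(independent
envelope)`, so total oscillator power is constant while the *coupled
fraction* is the session's coupling strength κ ∈ [0, 1]; pairs use lags
(0, π/4) with the first electrode unmixed (pair coupling then scales as κ,
not κ²), cliques stagger lags by 0.4 rad so every pair difference stays well
inside (0, π). At κ = 0 a planted pair is statistically indistinguishable
from an unplanted one; the peak-detected PLI rises monotonically to 1 as
κ → 1. An earlier design (shared sinusoid plus bounded smooth phase jitter)
could not satisfy these two requirements simultaneously at the peak-index
level and was replaced. A zero-lag common-source confound is available
(`common_source_amplitude`) to exercise the volume-conduction blindness of
PLI/wPLI/imaginary coherence.

The non-planted EEG condition (post-training by default) receives a
seed-fixed permutation of the coupling series: comparable connectivity
magnitudes, no systematic relation to behavior.

**Behavior.** `b_s = β₀ + β₁·κ_s + ε`, defaults β = (8.0, 3.5) cm²,
σ_ε = 0.12, κ declining linearly 0.85 → 0.15 across sessions: median tracing
error ≈ 8–10 cm² varying ≈ ±10% session to session, so that relative
estimation errors of a few percent are meaningful while the brain-behavior
R² sits in the high 0.9s — the regime the method targets.

**Trials.** Each trial is a randomly chosen section/direction; the trace is
the section polyline plus smooth correlated noise (Gaussian-kernel smoothed,
correlation ≈ 8 samples), tapered to zero at both endpoints, followed by a
1.3-s dwell at the destination; timestamps come from a constant-speed model
(400 px/s) with a lognormal per-trial factor. The mapping from a target
median error to trace-noise SD uses `area ≈ σ·√(2/π)·L` and is accurate while
σ ≪ section length. The generator plants *one* skill level per session — no
within-session learning, so dual-median pre ≈ post.

**Index-level generator.** `simulate_indices` plants the same linear
structure directly at the connectivity-index scale (planted columns
`0.3 + 0.5κ + N(0, 0.015)`, a planted-column SNR ≈ 5; null columns
`0.3 + N(0, 0.05)`), which is the right scale for exercising the PLS stage in
isolation and for the 50-seed recovery experiments.

**Not emulated:** head geometry and volume conduction beyond the common-source
option, artifacts (EOG/EMG, electrode pops), non-stationarity within a
recording, within-session learning curves, and any cross-participant
structure. Passing tests therefore demonstrate correctness of the estimators
and the selection/validation machinery under the planted model — not that the
method's accuracy claims transfer to real recordings.

## 5. Problem sizes used in tests and the acceptance script

Chosen as the package's own balance of statistical resolution against
desk-scale runtime: metric oracles at 1e-12 on hand-worked values plus 1000
random epochs; geometry vs a 0.1-px rasterization on 100 perturbed sections;
PLS vs scikit-learn on 20 random instances at 1e-6; permutation calibration
with 500 null simulations × 199 permutations (99% binomial envelope at
α = 0.05); power vs a 10,000-rep Monte-Carlo F-test within 0.02; recovery
with 50 generator seeds at full feature width (496) with 50×500
consensus resampling; the end-to-end EEG participant uses 8 sessions of
150-s recordings (the 30-s offset plus the complete 120-epoch window — the
full analysis window at reduced total recording length), a 10-electrode
planted clique at 21 Hz, and a 3-center × 2-condition PLI search with 500
permutations/bootstraps. The acceptance script repeats the recovery
experiment over 25 seeds and the end-to-end run once per invocation seed.

## 6. Known limitations

- Selection (consensus) precedes cross-validation, as in the protocol it
  implements; reported LOO RMSE% is optimistic for weak signals.
- The omnibus PLSC screen is insensitive to very sparse signals and the
  bootstrap consensus cannot fully empty a null channel set at n ≤ 8; both
  are documented properties of the method at this sample size, not bugs.
- The peak-detected index saturates under strong coupling; coupling ranges
  producing index variation are required for recovery.
- RMSE% depends on the behavior's coefficient of variation; comparisons
  across behavior scales should use the slope and R² alongside it.
- EDF reading requires the optional `mne` dependency and is untested against
  vendor-specific label variants beyond upper-casing.
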