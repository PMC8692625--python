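# Methods

This note records the models, parameter choices and numerical decisions
behind `bedvitals`, and what the synthetic-bed simulator does and does not
emulate.

## Signal model

A bed on four load cells reports, per channel *j*,

```
r_j(t) = s_j · [ tare_j + Σ_p π_pj (W_p + resp_p(t) + bcg_p(t)) + drift_j(t) ] + ε_j(t)
```

where `s_j` is the channel's digitizer sensitivity (AU per lb), `π_pj` the
fraction of person *p*'s load carried by leg *j* (nonnegative, summing
to 1), `W_p` the body weight, `resp_p` the chest-wall load swing,
`bcg_p` the cardiac recoil train, and `ε_j` white sensor noise. Between
episodic movements `π_pj` is constant — each person behaves as a point
source — which is the premise behind both position-invariant weighing and
linear source separation.

## Calibration

Joint gains `g_j` are fitted so the gain-weighted channel sum of one load
placed at several positions has minimal variance across placements. With
`g_0 ≡ 1` (the overall scale is a gauge freedom) this is an ordinary
least-squares problem on the placement-centered channel means, solved by
`lstsq`; a channel that is constant across placements makes the design
degenerate and raises. The affine AU→lbs map is anchored by two-point
calibration (empty reading → 0 lbs, reference load reading → the load),
exact by construction.

## Filtering and moving statistics

All bandpasses are Butterworth of order 4, applied forward–backward
(`sosfiltfilt`) so they are zero-phase: breath- and beat-peak *timing* is
what the rate estimators consume, and a causal filter would shift it.
A 50 Hz upper cutoff exceeds the 40 Hz Nyquist at the 80 Hz sampling rate
and is clipped to 0.99 × Nyquist with a logged warning. Irregular
timestamps are linearly interpolated onto a uniform grid before filtering.
Moving statistics use centered windows of odd sample length (edges shrink),
so a moving mean of a ramp reproduces the ramp.

Steady (movement-free) regions are runs where a moving variance stays below
a threshold; the default threshold is adaptive, 4 × the 10th percentile of
the overnight variance series. The variance window must span at least one
breath cycle (5 s for respiration, 2 s for the BCG scale), otherwise quiet
breathing itself oscillates in and out of "steadiness". Regions shorter
than 10 s (respiration) or 5 s (BCG) are rejected.

## Respiration

The four respiratory-band channels (0.167–1.5 Hz) are composited by
projecting each non-overlapping 12.5 s window onto the leading eigenvector
of its channel covariance; windows are stitched with a 0.5 s crossfade and
the eigenvector sign is fixed so the loading of the highest-variance
channel is positive. A zero-variance window carries the previous loading
forward. On a rank-1 mixture this reproduces the source up to scale; on
noise it cannot exceed the strongest channel by more than the eigenvalue
spread.

Breath peaks are sought only inside steady regions, on a 0.5 s-smoothed
composite, in two passes: a strict pass (height ≥ half the 98th-percentile
level) estimates the dominant period; the final pass enforces a minimum
spacing of 60% of that period, floored at 1.5 s (40 bpm), with prominence
≥ 25% of the region's amplitude scale. The scale is half the 2nd–98th
percentile range: slow breathing has a low duty cycle, and narrower
percentiles track the baseline instead of the peaks. The two-pass design is
what keeps 8 bpm recoverable: at that rate the band's 0.167 Hz edge sits
above the fundamental and only harmonics survive, with between-breath
ripple that a fixed 1.5 s spacing would happily mis-detect.

A rate epoch is 30 s; its value is 60 / median inter-peak interval within
the 5-min window centered on the epoch (median, so isolated gaps leave the
rate untouched until more than half the window's intervals are apneic).
Epochs with fewer than two peaks, or more than 45 s of unsteady time in the
window, are invalid with a recorded reason.

### Apneas

Candidate events are runs where a moving-RMS envelope (4 s window) stays
below 50% of the flanking-breathing baseline (rolling 75th percentile over
±60 s, excluding sub-threshold samples). Because breaths are discrete
events, envelope crossings blur the edges by up to one breath period, so
boundaries are refined from the flanking full-size breath peaks: the apnea
runs from one breath period after the last pre-gap upstroke to the first
post-gap upstroke, making the measured duration (peak gap minus one period)
exact to peak-timing accuracy. Events longer than 10 s are apneas.

The residual effort fraction is the ratio of Fourier amplitude at the
flanking breath frequency inside the event vs in the flanks, both detrended
with the same 3 s moving mean (the detrend attenuation cancels in the
ratio). This measure is used instead of an envelope ratio because the
chest waveform has a positive mean — lung volume rides above the relaxed
position — and its cessation step makes the 0.167 Hz band edge ring into
the gap, which an RMS envelope misreads as ~10% effort. Events with effort
below 7.5% of baseline are central, in [7.5%, 50%) obstructive, and
unclassified when no usable flank exists. The 7.5% split sits just above
the estimator's noise floor at the 10 s duration minimum; clearly
obstructive efforts (≥ 10%) remain correctly typed.

Periodic breathing is flagged from the autocorrelation of the respiratory
envelope (RMS, then an 8 s moving mean so within-cycle ripple cannot pose
as slow periodicity): the first autocorrelation peak ≥ 0.5 at lag ≥ 10 s is
the dominant period, and the flag raises when it exceeds 30 s. Requiring
the *first* qualifying peak prevents the 2nd harmonic of a fast (< 30 s)
modulation from triggering the flag.

## Ballistocardiography

The single-peak BCG converts each channel's 5–50 Hz transient into energy:
bandpass → moving mean (50 ms) → moving variance (150 ms) → channel sum →
bandpass (1–50 Hz). Window lengths span one BCG complex without merging
beats at 180 bpm. Because the variance step is quadratic, the energy peak
scales with the squared beat amplitude; beat *magnitude* — the scale on
which respirophasic and post-ectopy ratios are physiologically meaningful —
is the square root of the baseline-corrected energy at the detected peak
(baseline = rolling 1 s minimum of the summed energy). Beat detection
mirrors the breath detector (two passes, spacing ≥ 60% of the estimated
beat period, floored at 60/180 s) plus a height gate at 35% of the local
beat-height scale: the 1 Hz high-pass rebound between beats has large
prominence but sits far below beat height.

Amplitude analytics use the 1 Hz lower cutoff variant (amplitude mode).
Beats are labeled inspiratory if they fall on the rising limb of the
respiratory composite (after a trough, before a peak), expiratory on the
falling limb, and *unknown* within 0.25 s of either extremum — the filtered
composite's turning points are slightly displaced from the true chest-wall
turning points, and transition beats straddle phases. Inspiratory vs
expiratory magnitudes are compared by two-sided Mann–Whitney. Post-ectopy
ratio = magnitude of the first post-ectopy beat over the mean of the three
preceding beats; when no annotation is available a heuristic flags
candidate ectopic runs (interval < 70% of the local median followed by one
> 120%, or a lone interval near twice the median when the weak ectopic beat
escaped detection) — a fallback, not a diagnostic.

## Two-person demixing

The respiratory-band observations are modeled as a linear-Gaussian
state-space model with one latent block per sleeper; each block is a 2-D
stochastic damped oscillator (rotation with spectral radius ≤ 1 plus
process noise), giving quasi-oscillatory, stochastically continuous
sources. The mixing operator is unconstrained, observation noise is
diagonal. EM alternates an exact E-step (Kalman filter + RTS smoother with
lag-one covariances and the exact innovations log-likelihood; missing rows
skip the correction step) with closed-form M-steps constrained to
block-diagonal transition/process covariance and diagonal observation
noise — each a valid constrained maximizer, so the log-likelihood is
monotone (an internal guard raises on any decrease beyond numerical slack).
Observations are decimated to 8 Hz first (the 1.5 Hz band edge is far below
the 4 Hz Nyquist), which cuts cost by an order of magnitude.

Initialization matters: mixing columns seeded with the two leading global
PCA eigenvectors converge to a sum/difference local optimum in which both
"sources" are mixtures. Instead, each source's mixing column is initialized
from the leading eigenvector of the observation covariance in a narrow band
around that source's own spectral peak, with the peaks required to be
mutually non-harmonic (a harmonic of a chosen fundamental belongs to the
same non-sinusoidal source, not to a second person). Oscillator frequencies
start at those peaks; restarts jitter the initialization, keeping the best
likelihood. Convergence: relative log-likelihood change < 1e-6, up to 200
iterations (100 in the demixing driver).

Each source is reduced to a scalar by projecting its smoothed-state
contribution at the sensors onto its leading principal direction, scaled to
unit variance (the amplitude gauge is unidentifiable) and oriented to
nonnegative skewness (inspiratory upstrokes are sharp positive
deflections — without a sign convention, peak-timing comparisons can land
on troughs). Label order is arbitrary. Unidentifiable configurations —
near-collinear mixing directions, near-identical sources, or one block
carrying < 2% of the contribution variance — raise a warning. Whether the
transition dynamics are estimated or held fixed is a flag
(`estimate_transition`, default estimated).

The inner filter/smoother loops are numba-compiled when numba is
importable, with the identical pure-NumPy code as fallback.

## Synthetic bed generator

The generator emulates: static tare and per-person weight projected onto
the legs; a respiratory contour with a brisk linear upstroke over 30% of
the cycle and exponential decay (τ = 1.2 s) thereafter, smoothed with a
0.2 s symmetric kernel because real chest-wall motion is band-limited (the
raw piecewise contour's corners would radiate artificial energy into the
BCG band); a BCG train of ~8 Hz damped-sinusoid kernels (0.3 s) with the
kernel's 0th and 1st moments removed — momentum and displacement return to
baseline over a beat — so the train does not radiate spurious energy at its
~1 Hz repetition rate into the respiratory band; respirophasic amplitude
coupling (inspiratory beats × `coupling_gain`); ectopic beats (preceding
interval halved, amplitude halved, successor × 1.4 by default); apneas
(central: amplitude 0; obstructive: × effort fraction), with onsets snapped
to the next breath-cycle boundary and a fresh recovery-breath upstroke at
the end, so truth intervals are well defined to sub-second precision;
periodic-breathing amplitude modulation; bed entry/exit steps; 1–5 s
movement bursts with permanent re-draws of the projection vector; linear
drift; white noise; and per-channel sensitivities whose correcting gains
(channel 0 as reference) are recorded in the truth.

Defaults are chosen as typical adult sleep physiology: 150 lbs, 15
breaths/min with 0.5 lbs chest-wall load swing, 65 beats/min with a
0.3 lbs-scale beat kernel, 0.01 AU sensor noise at ~80 Hz. The
rate-recovery experiments run at a signal-to-noise ratio of 3, defined as
the strongest channel's component amplitude over the per-sample noise SD.
Identical seeds give bit-identical output; all truth (breath peaks, beat
times and amplitudes with respiratory phase, events, snapped apnea
intervals, movement intervals, mixing matrix, calibration) is returned
alongside the frame.

What the generator does *not* emulate — and hence what green tests do not
establish about real beds: postural drift of the projection vector during
quiet sleep, respiratory rate and amplitude variability (rates are constant
per session), heart-rate variability and true arrhythmia statistics,
mattress mechanical filtering and inter-leg crosstalk, temperature drift of
the load cells beyond a linear ramp, and co-sleeping partners touching or
synchronizing their breathing. Validation against polysomnography-grade
references requires real recordings.

## Epoch aggregation

Plausibility bounds are applied strictly as printed (6 < RR < 40,
60 < HR < 120; a 60.0 bpm epoch is excluded). Days run noon-to-noon; a day
without valid epochs reports missing values, never zero. Heatmaps are
2880 × n_days (30 s slots), with cells below the display floor emitted as
missing; the display floor and the plausibility filter are configured
independently. Wall-clock placement requires a session-start datetime; with
none given, day 0 starts at session time zero.

## Problem sizes

The test suite and the acceptance script use 5–12 minute sessions at 80 Hz,
5 placement positions, 4 simultaneity intervals, 5-point rate grids,
20-seed EM/demixing batteries at 8 Hz (T ≈ 4800), and T = 50 instances for
the dense smoother oracle — sizes at which every stage's behavior is
already asymptotic while a full run stays in the minutes range on one CPU.
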