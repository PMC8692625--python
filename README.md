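# bedvitals

Adherence-independent monitoring of body weight, respiration, heart rate and
sleep apnea from force sensors placed under the four legs of a bed.

Patients with chronic cardiopulmonary disease — heart failure above all —
deteriorate along trajectories that daily weights, respiratory rates and
heart rates would reveal, but only if the measurements actually happen.
Devices that require the patient to do something every day stop being used
by exactly the patients who need them most. A bed instrumented with a load
cell under each leg measures continuously while the patient does nothing at
all: body weight is the calibrated sum of the four leg loads; chest-wall
motion redistributes load between the legs at the breathing frequency; each
heartbeat's mechanical recoil (the ballistocardiogram, BCG) appears as a
5–50 Hz transient. `bedvitals` implements the full analysis stack for such
recordings, together with a seeded synthetic-bed simulator that provides
exact ground truth for every stage, so the whole pipeline is testable
without hardware.

## What the package computes

Given a 4-channel force time series sampled at ~80 Hz:

* **Weight** — joint gain calibration from one load at several bed positions
  (gains minimize across-placement variance of the weighted sum), two-point
  AU→lbs conversion, step-event extraction from plateau differences,
  attribution of steps to up to two persons by magnitude clustering, bed
  occupancy (%TIB) and noon-to-noon daily weights. Resolves steps of
  0.033 lbs (15 mL of water) in high-sensitivity mode.
* **Respiration** — per-channel bandpass (0.167–1.5 Hz), a single composite
  respiratory signal from the leading principal component per 12.5 s window,
  breath peaks inside movement-free regions (≥ 10 s), the rate per 30 s
  epoch as 60 / median inter-peak interval of a centered 5-min window,
  apnea detection (envelope collapse > 10 s; central vs obstructive by
  residual effort), and periodic-breathing flagging (envelope periodicity
  > 30 s).
* **Ballistocardiography** — the single-peak BCG: bandpass (5–50 Hz) →
  moving mean (50 ms) → moving variance (150 ms) → channel sum → bandpass
  (1–50 Hz), giving one dominant peak per heartbeat; beat detection, heart
  rate per 30 s epoch, respirophasic beat-amplitude coupling
  (inspiratory vs expiratory magnitudes, Mann–Whitney) and post-ectopy
  amplitude ratios.
* **Two-person demixing** — each sleeper as a latent respiratory source in a
  linear-Gaussian state-space model,
  `x_t = A x_{t-1} + w_t`, `y_t = H x_t + v_t`, with per-source stochastic
  oscillator dynamics, mixing operator `H` estimated by
  Expectation–Maximization (closed-form M-steps, exact log-likelihood) and
  sources extracted by fixed-interval (RTS) Kalman smoothing. Weights of two
  people sharing a bed are demixed from entry/exit timing down to 5 s
  simultaneity.
* **Longitudinal aggregation** — strict plausibility filters
  (6 < RR < 40 bpm, 60 < HR < 120 bpm), noon-to-noon daily summaries and
  2880-slot time-of-day × day heatmap exports.

## Worked example

`examples/04_demix_two_sleepers.py` simulates ten minutes of two sleepers
(12 and 17 breaths/min, independent leg projections), fits the state-space
model by EM on the respiratory-band signal and smooths out the two sources:

```
EM converged after 100 iterations; log-likelihood strictly non-decreasing: True
source 0: corr 0.996 with P2 (0.010 with P1); breath-peak timing error 0.036 s vs own belt, 0.874 s vs wrong belt
source 1: corr 0.996 with P1 (0.009 with P2); breath-peak timing error 0.010 s vs own belt, 0.880 s vs wrong belt
```

Each demixed source reproduces exactly one sleeper's chest waveform
(correlation 0.996 with the correct source, ~0.01 with the other), and
breath-peak timing against the correct reference is tens of times tighter
than against the wrong one — the contrast that validates assignment.
The other scripts in `examples/` walk through calibration and two-person
weighing, overnight RR/HR estimation, apnea screening, and longitudinal
summaries, each printing the numbers it computes alongside ground truth.

A thin command-line interface wires the same modules into reproducible runs:

```bash
bedvitals simulate --seed 3 --duration 600 --out run1
bedvitals resp run1/session.csv --out run1     # rate epochs + apneas
bedvitals report run1/session.csv --out run1   # weight + RR + HR summary
```

Every run writes a provenance JSON (config, seed, version, input checksums).

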