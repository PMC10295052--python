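# lognecg

Sigma-lognormal decomposition of single-lead ECG. Each PQRST complex is
modeled as the sum of six time-shifted, scaled lognormal waves
(P, Q, R, S, and a positive/negative pair for the T wave), fitted per beat
inside a physiologically constrained parameter box by a sequential-decision
environment, with a downstream parameter-versus-age statistical stage.
Everything is testable end to end on synthetic ECG with known ground truth.

## What's inside

- `lognecg.model` — forward model: lognormal components, 24-parameter beat
  sets, peak times, synthesis, and the normalized-time/seconds
  denormalization `{mu + ln(alpha), sigma, alpha*t0, alpha*D}`.
- `lognecg.bounds` — packaged prototype and bounds tables, the ±20%
  bound-derivation rule, box validation, and the ball-in-hypercube
  geometry check.
- `lognecg.envelope` — closed-form pointwise lower/upper envelopes of a
  lognormal component over a parameter box and their signed sums.
- `lognecg.preprocess` — resampling to 1024 Hz, R-peak detection,
  500-sample duration-normalized beat epoching, SNR quality control
  (segments below 5 dB mean SNR are rejected).
- `lognecg.environment` — the fitting environment: box-and-order
  constrained multiplicative parameter updates, windowed error
  observations, SNR-delta rewards, patience/max-step termination.
- `lognecg.extract` — policy training (lightweight cross-entropy-method
  backend over the standard episodic contract), greedy per-beat
  extraction, and a deterministic random-restart coordinate-search
  baseline that serves as a testing oracle.
- `lognecg.synth` — synthetic ECG generator: beats with known parameters,
  RR variability, calibrated noise, per-subject offsets, and linear
  age drifts.
- `lognecg.analysis` — two-stage aggregation (beats → segments →
  recordings), per-age sample-size filtering, and Kendall tau-b age
  correlations with Bonferroni correction for 24 tests.
- `lognecg.cli` / `lognecg.pipeline` — stage orchestration and the
  command-line surface.

## CLI

```sh
lognecg run-all --config config.yaml --out results --seed 0
# or stage by stage:
lognecg synth --out results
lognecg preprocess --out results
lognecg train --out results
lognecg extract --out results
lognecg analyze --out results
```

Configuration is YAML with strict key validation; all thresholds (5 dB
segment filter, 5 dB beat exclusion, ≥8 participants per age level,
alpha 0.01 with 24-test Bonferroni) default to the published values.
Input traces are two-column CSV (`time_s`, `ecg_uv`) at 128/512/1024 Hz
(EDF works when `mne` is installed); outputs are plain CSV/JSON.

## Notes

- The fitting SNR follows the power-ratio formula
  `10*log10(sum(ref^2)/sum((x-ref)^2))`; perfect fits report a 120 dB cap.
- Epochs span the previous-R to next-R window, so neighboring beats' T and
  P waves land outside the fitted `[-0.3, 0.7)` observation window but
  still count against the full-window fitting SNR. On synthetic corpora
  rendered with the packaged prototype (large T waves), that structural
  residual caps the attainable full-window SNR of trace-rendered beats at
  a few dB; noiseless directly synthesized beats have no such ceiling.
- The packaged bounds table is authoritative where it and the derivation
  rule disagree (its Tp amplitude ceiling is 204 rather than the plain
  rule's 180); `derive_bounds(..., apply_tp_override=False)` exposes the
  plain rule.
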