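# Methods

## The detection model

A sacrum-mounted (S1) accelerometer senses whole-body motion close to the
centre of mass. Two landmarks are extracted per step from the filtered
signal:

* the per-cycle minimum of the **vertical** channel — the Vertical
  Acceleration Step Cycle landmark, one per step cycle;
* the dominant positive peak of the **anteroposterior** channel — the
  heel-strike impact transient.

The per-step offset Δ = heel-strike time − vertical-minimum time measures
how long the ground-contact impact takes to register relative to the body's
vertical cycle. With continuous ground contact the impact arrives at, or
shortly after, the vertical minimum; a flight phase delays it further. The
classification rule is strict: Δ > threshold ⇒ illegal, Δ ≤ threshold ⇒
legal, with a default threshold of 0.03 s. The threshold is a configurable
parameter, not a constant, because it is an empirical calibration of the
force-transmission delay: a new sensor placement or population can
re-derive it from an agreement analysis against a reference system.

Only heel strike is detected on the sensor side; toe-off kinematics
coincide closely enough with heel strike in race walking that the single
event suffices for legality classification. The sensor never measures
flight *duration* — it classifies.

## The camera reference

The camera measures the signed ground-contact overlap directly:
t = (Σn)/Hz, where Σn is the signed frame count from contralateral heel
strike to toe-off. The frame difference (not an absolute count) is used
because the sign carries the legality: positive = double support,
negative = flight. Same-frame events (0.00 s) form a distinct "threshold"
category that is pooled with legal in all accuracy bookkeeping, since a
zero overlap does not demonstrate loss of contact. Quantising a continuous
event time to frames bounds the camera's own timing error by one frame
period (1/125 s = 0.008 s) per event.

## Statistics

* **Agreement (validity).** The sensor's signed timing (threshold − Δ,
  which shares the camera's sign semantics) is regressed on the camera
  overlap by ordinary least squares. The Typical Error of the Estimate is
  the standard error of the estimate, √(RSS/(n−2)); its 95% confidence
  limits are TEE·√(df/χ²₀.₉₇₅) and TEE·√(df/χ²₀.₀₂₅) with df = n−2.
  Mean bias is the mean of (sensor − camera) differences; the "±" value
  reported alongside it is the SD of those differences (the source
  literature's "±0.01" is interpreted this way; the interpretation is a
  package choice).
* **Reliability.** Repeated frame identifications (events × repeats) are
  decomposed by ANOVA. The typical error is the within-event SD,
  √(SSW/(n(k−1))), in frames, with chi-square confidence limits on its df.
  The ICC is fixed to the two-way mixed, consistency, single-measure form
  ICC(3,1) = (MSB − MSE)/(MSB + (k−1)MSE) with MSE from the two-way
  residual; the consistency form deliberately ignores a fixed offset per
  repeat session. With zero between-event variance the ICC is undefined
  and reported as NaN.
* **Confusion.** Four cells (illegal agreed / illegal missed / legal
  agreed / legal flagged), overall accuracy = 100·(agreements)/total, and
  an *illegal-only* variant defined as 100·(total − legal_flagged)/total.
  The illegal-only variant is **not** the standard sensitivity
  (illegal_agree/(illegal_agree+illegal_missed) would be ≈93% on the
  published table, not >96%); the implemented definition follows the
  source's own gloss ("or 3 legal steps identified as illegal") and is
  kept for comparability, flagged here as non-standard.

## The synthetic-data generator

No public recordings of race-walk sacral accelerometry exist, so the
simulator is a declared stand-in, not a biofidelic model. It generates:

* a vertical channel: a cosine carrier at the step frequency whose
  per-cycle minima are placed at h_k − transmission_offset + overlap_k
  (phase is piecewise-linear through the minima and clamped a
  quarter-cycle outside the stepping interval so lead-in/lead-out are
  flat), plus a small positive Gaussian impact bump (0.2 g, σ = 6 ms) at
  each heel strike;
* an anteroposterior channel: a 0.05 s positive half-sine impact pulse
  (2 g) per heel strike over a 0.1 g baseline oscillation;
* a mediolateral channel carrying only noise;
* additive white Gaussian noise (default SD 0.05 g) on all channels;
* a paired camera annotation: the true event times quantised to the
  125 Hz frame grid (floor convention by default — a frame records
  everything within its exposure window; nearest-frame is available as a
  switch).

The `transmission_offset` parameter (default 0.03 s) embeds the empirical
force-transmission delay, so the simulated sensor offset is
Δ ≈ transmission_offset − overlap and the 0.03 s threshold separates
legal from illegal exactly at zero overlap. Default cadence is 3 steps/s
(~180 steps/min, competitive race-walking); overlaps may be scalar or
per-step, and `sample_study_overlaps` draws a mixed session emulating a
validation experiment: ~71% illegal (flight 0.008–0.05 s), ~2.5% exactly
on the threshold, the rest legal (double support 0.008–0.05 s).

**What passing tests do and do not show.** The simulator guarantees a
well-defined cycle minimum and a single dominant AP transient per step;
real signals contain soft-tissue artefact, asymmetry, drift, cadence
variation and transient morphology the generator does not attempt.
End-to-end recovery on synthetic walks therefore validates the *pipeline
logic* (event pairing, sign conventions, threshold rule, quantisation
bookkeeping, statistics), not field performance on athletes.

## Numerical choices

* **Filter:** 4th-order Butterworth, 20 Hz cutoff, applied forward and
  backward (`sosfiltfilt`) so filtering cannot shift event timing; cutoff
  must be below Nyquist or the call is rejected.
* **Event timing resolution:** events are reported on the 100 Hz sample
  grid (no sub-sample interpolation); each event therefore carries up to
  half a sample (5 ms) of timing error, and offsets up to one sample.
* **Threshold comparison:** Δ > threshold + 1e−9. The epsilon guards the
  strict inequality against binary representation error in sample-grid
  time differences (0.55 − 0.52 ≠ 0.03 exactly in floating point); it is
  five orders of magnitude below the sample period.
* **Pairing:** each vertical minimum is paired with the nearest heel
  strike within half the median inter-minimum interval, greedily by
  smallest gap, one-to-one. The window is symmetric — not
  "at-or-after" — because during double support longer than the
  transmission offset the heel strike legitimately precedes the vertical
  minimum (Δ < 0). Minima with no pairable heel strike are excluded and
  counted, never fabricated; if fewer than half the candidate steps pair,
  a structured error names the orphan events.
* **Vertical impact bump:** kept small (0.2 g) and narrow (σ = 6 ms)
  because a large or oscillating transient near the cycle minimum can
  displace the detected minimum by 1–2 samples once widened by the 20 Hz
  filter; at 0.2 g the displacement stays below one sample except when
  the heel strike lands exactly on the minimum (overlap ≈ transmission
  offset), where verdicts are far from the legality boundary anyway.
* **Modal frame in reliability trials:** ties are broken toward the value
  nearest the event median, then toward the smaller frame.
* **Degenerate inputs:** empty traces, constant channels, zero-variance
  criteria, <3 agreement pairs, ragged reliability tables and single-
  repeat tables are all rejected with specific errors; an all-zero AP
  channel yields an empty detection plus a warning, not an error.

## Problem sizes

The test suite simulates walks of 5–80 steps for unit and end-to-end
checks, 500 steps for the bias parameter-recovery check and 1,000 steps
for the exhaustive camera-quantisation sweep; the acceptance script runs
an 80-step session, matching the scale of the original validation
experiment. These sizes give stable statistics while keeping the whole
suite in the order of seconds.

## Known limitations

* The simulator's waveform is schematic; its amplitudes are chosen so
  detection is easy at zero noise and degradable under noise, not fitted
  to recordings.
* The anteroposterior heel-strike criterion (largest positive peak per
  window above a prominence floor) is a declared substitute for the
  antecedent accelerometry method it abstracts, which is not publicly
  specified in detail.
* Whether the 0.03 s offset should be measured on filtered or raw
  signals is unspecified in the source; this package measures it on
  filtered signals (the zero-phase filter does not move event times, so
  the choice only affects noise robustness).
* The published validity statistics (TEE 0.02 s, r 0.67, bias 0.02 s,
  reliability TE 0.24 frames, ICC 0.99) depend on the unreleased athlete
  recordings and are not reproducible from first principles; the package
  instead proves its statistics against independent brute-force oracles
  on frozen fixtures and recovers known parameters from synthetic data.
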