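"""Synthetic race-walk sacral acceleration traces with known gait events.

No public recordings of sacrum-mounted accelerometry in race walking exist,
so every downstream stage (event detection, camera reference, agreement
statistics) is exercised against signals generated here, for which the
toe-off and heel-strike times — and hence the legality of every step — are
known exactly.

The signal model
----------------
Race walking alternates steps at a cadence near 3 steps/s.  For each step
``k`` the generator lays down a heel-strike instant ``h_k`` and a
contralateral toe-off instant ``h_k + overlap_k``: a positive overlap is a
period of double support (legal), a negative overlap a flight phase
(illegal under the continuous-contact rule).

* vertical channel: a sinusoid at the step frequency whose per-cycle
  minimum falls at ``h_k - transmission_offset + overlap_k``, plus a small
  positive impact bump at each heel strike.  The ``transmission_offset``
  (default 0.03 s) models the delay with which the ground-contact impact
  reaches a sensor at the sacrum: with zero overlap the heel-strike
  transient trails the vertical minimum by exactly that delay, flight
  stretches the lag further, double support shortens it.
* anteroposterior channel: a narrow positive half-sine impact pulse
  (~0.05 s wide) centred on each heel strike over a low-amplitude baseline
  oscillation.
* mediolateral channel: noise only.

Gaussian noise of standard deviation ``noise_sd`` is added to all three
channels.  A paired camera annotation is emitted by quantising the true
event times to the camera frame grid (125 Hz by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .camera import CameraAnnotation
from .detect import AccelTrace

__all__ = [
    "GaitParams",
    "GroundTruth",
    "simulate_walk",
    "quantise_to_frames",
    "sample_study_overlaps",
]

#: duration of the anteroposterior heel-strike impact pulse, seconds
AP_PULSE_WIDTH = 0.05
#: width (Gaussian sigma) of the vertical impact bump, seconds
VERT_BUMP_SIGMA = 0.006
#: amplitude of the anteroposterior baseline oscillation, g
AP_BASELINE_AMPLITUDE = 0.1


@dataclass(frozen=True)
class GaitParams:
    """Parameters of one simulated race walk.

    Parameters
    ----------
    step_rate:
        Cadence in steps per second.  Must be positive.  Default 3.0,
        a typical competitive race-walking cadence (~180 steps/min).
    n_steps:
        Number of steps to generate (may be 0 for an empty walk).
    overlap_time:
        Signed ground-contact overlap in seconds, either a scalar applied
        to every step or a per-step sequence of length ``n_steps``.
        Positive = double support (legal), negative = flight (illegal).
        Every value must satisfy ``|overlap| < 1/step_rate``.
    impact_amplitude:
        Peak of the anteroposterior heel-strike pulse, in g.
    base_amplitude:
        Amplitude of the vertical step-cycle sinusoid, in g.
    noise_sd:
        Standard deviation of additive Gaussian noise on all channels, g.
    sensor_rate, camera_rate:
        Sampling rates of the inertial sensor (default 100 Hz) and the
        high-speed camera (default 125 Hz).
    seed:
        Seed of the private random generator; generation is
        bit-reproducible for a fixed seed.
    transmission_offset:
        Lag from the vertical-channel cycle minimum to the heel-strike
        transient at zero overlap, seconds (default 0.03).
    vertical_impact_amplitude:
        Peak of the positive vertical impact bump, g.  Kept modest so the
        bump cannot displace the cycle minimum the detector keys on.
    step_jitter_sd:
        Per-step Gaussian jitter of the heel-strike times, seconds
        (default 0: perfectly constant cadence).
    overlap_jitter_sd:
        Per-step Gaussian jitter added to ``overlap_time`` (default 0).
    quantise:
        Camera quantisation convention, ``"floor"`` (a frame contains the
        instant; default) or ``"nearest"``.
    lead_in:
        Quiet time before the first heel strike and after the last event,
        seconds.
    """

    step_rate: float = 3.0
    n_steps: int = 50
    overlap_time: float | Sequence[float] = -0.02
    impact_amplitude: float = 2.0
    base_amplitude: float = 1.0
    noise_sd: float = 0.05
    sensor_rate: float = 100.0
    camera_rate: float = 125.0
    seed: int = 0
    transmission_offset: float = 0.03
    vertical_impact_amplitude: float = 0.2
    step_jitter_sd: float = 0.0
    overlap_jitter_sd: float = 0.0
    quantise: str = "floor"
    lead_in: float = 0.5

    def overlaps(self) -> np.ndarray:
        """Per-step overlap times as an array of length ``n_steps``."""
        o = np.asarray(self.overlap_time, dtype=float)
        if o.ndim == 0:
            o = np.full(self.n_steps, float(o))
        if o.shape != (self.n_steps,):
            raise ValueError(
                f"overlap_time must be scalar or length {self.n_steps}, got shape {o.shape}"
            )
        return o

    def validate(self) -> None:
        if self.step_rate <= 0:
            raise ValueError("step_rate must be positive")
        if self.sensor_rate <= 0 or self.camera_rate <= 0:
            raise ValueError("sensor_rate and camera_rate must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.quantise not in ("floor", "nearest"):
            raise ValueError("quantise must be 'floor' or 'nearest'")
        period = 1.0 / self.step_rate
        o = self.overlaps()
        if o.size and np.max(np.abs(o)) >= period:
            raise ValueError(
                f"|overlap_time| must be below the step period {period:.4f} s"
            )


@dataclass(frozen=True)
class GroundTruth:
    """True event times and legality of every simulated step.

    ``heel_strike_times[k]`` is the heel strike of step ``k`` and
    ``toe_off_times[k]`` the toe-off of the contralateral (trailing) foot;
    their signed difference is ``overlap_times[k]``.  A step is illegal
    exactly when its overlap is negative (loss of ground contact).
    """

    toe_off_times: np.ndarray
    heel_strike_times: np.ndarray
    overlap_times: np.ndarray
    legality: tuple[str, ...] = field(default=())

    @property
    def n_steps(self) -> int:
        return len(self.heel_strike_times)


def quantise_to_frames(time: float, camera_rate: float, mode: str = "floor") -> int:
    """Return the index of the camera frame capturing instant ``time``.

    The default ``"floor"`` convention assigns an instant to the frame
    whose exposure window contains it; ``"nearest"`` rounds to the closest
    frame boundary.  A small epsilon guards against representation error
    when ``time`` is an exact multiple of the frame period.
    """
    if camera_rate <= 0:
        raise ValueError("camera_rate must be positive")
    if time < 0:
        raise ValueError("time must be non-negative")
    x = time * camera_rate
    if mode == "floor":
        return int(math.floor(x + 1e-9))
    if mode == "nearest":
        return int(math.floor(x + 0.5))
    raise ValueError("mode must be 'floor' or 'nearest'")


def sample_study_overlaps(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-step overlap times emulating a mixed legal/illegal session.

    Emulates a validation session in which roughly 70% of steps carry a
    flight phase: steps are illegal with probability 57/80 (flight time
    uniform on 0.008–0.05 s, reported as negative overlap), exactly at the
    threshold (zero overlap) with probability 2/80, and legal otherwise
    (double support uniform on 0.008–0.05 s).
    """
    u = rng.random(n)
    flight = -rng.uniform(0.008, 0.05, size=n)
    support = rng.uniform(0.008, 0.05, size=n)
    out = np.where(u < 57 / 80, flight, support)
    out[(u >= 57 / 80) & (u < 59 / 80)] = 0.0
    return out


def _phase(t: np.ndarray, minima: np.ndarray, step_rate: float) -> np.ndarray:
    """Monotone phase (cycles) with integer values at the cycle minima.

    Clamped a quarter-cycle outside the stepping interval, so the cosine
    carrier freezes at its zero crossing during lead-in and lead-out and
    contributes no spurious cycle minima there.
    """
    if len(minima) == 0:
        return t * step_rate
    if len(minima) == 1:
        phi = (t - minima[0]) * step_rate
    else:
        k = np.arange(len(minima), dtype=float)
        phi = np.interp(t, minima, k)
        before = t < minima[0]
        after = t > minima[-1]
        phi[before] = (t[before] - minima[0]) * step_rate
        phi[after] = k[-1] + (t[after] - minima[-1]) * step_rate
    return np.clip(phi, -0.25, len(minima) - 1 + 0.25)


def simulate_walk(
    params: GaitParams,
) -> tuple[AccelTrace, CameraAnnotation, GroundTruth]:
    """Generate one walk: sensor trace, camera annotation and ground truth.

    Returns
    -------
    trace:
        Tri-axial acceleration sampled at ``params.sensor_rate``, units g.
    annotation:
        Per-step ``(toe_off_frame, heel_strike_frame)`` pairs obtained by
        quantising the true event times to the camera frame grid.
    truth:
        The exact event times, overlaps and legality labels.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    period = 1.0 / params.step_rate

    overlaps = params.overlaps()
    if params.overlap_jitter_sd > 0 and params.n_steps:
        overlaps = overlaps + rng.normal(0, params.overlap_jitter_sd, params.n_steps)
        # jitter must not push an overlap past the step period
        overlaps = np.clip(overlaps, -0.95 * period, 0.95 * period)

    heel = params.lead_in + np.arange(params.n_steps) * period
    if params.step_jitter_sd > 0 and params.n_steps:
        heel = heel + rng.normal(0, params.step_jitter_sd, params.n_steps)
        heel = np.sort(heel)
    toe = heel + overlaps
    minima = heel - params.transmission_offset + overlaps

    legality = tuple("illegal" if o < 0 else "legal" for o in overlaps)
    truth = GroundTruth(
        toe_off_times=toe,
        heel_strike_times=heel,
        overlap_times=overlaps,
        legality=legality,
    )

    if params.n_steps == 0:
        trace = AccelTrace(
            start_time=0.0,
            sample_rate=params.sensor_rate,
            ap=np.empty(0),
            vert=np.empty(0),
            ml=np.empty(0),
        )
        return trace, CameraAnnotation(camera_rate=params.camera_rate, steps=[]), truth

    duration = float(max(heel[-1], toe[-1], minima[-1])) + params.lead_in
    n_samples = int(round(duration * params.sensor_rate)) + 1
    t = np.arange(n_samples) / params.sensor_rate

    vert = -params.base_amplitude * np.cos(
        2 * np.pi * _phase(t, minima, params.step_rate)
    )
    ap = AP_BASELINE_AMPLITUDE * np.sin(
        2 * np.pi * _phase(t, heel, params.step_rate)
    )
    for h in heel:
        # vertical impact bump (positive, so the cycle minimum stays put)
        vert += params.vertical_impact_amplitude * np.exp(
            -0.5 * ((t - h) / VERT_BUMP_SIGMA) ** 2
        )
        # anteroposterior half-sine impact pulse
        in_pulse = np.abs(t - h) <= AP_PULSE_WIDTH / 2
        ap[in_pulse] += params.impact_amplitude * np.cos(
            np.pi * (t[in_pulse] - h) / AP_PULSE_WIDTH
        )
    ml = np.zeros_like(t)

    if params.noise_sd > 0:
        vert = vert + rng.normal(0, params.noise_sd, n_samples)
        ap = ap + rng.normal(0, params.noise_sd, n_samples)
        ml = ml + rng.normal(0, params.noise_sd, n_samples)

    trace = AccelTrace(
        start_time=0.0, sample_rate=params.sensor_rate, ap=ap, vert=vert, ml=ml
    )
    steps = [
        (
            quantise_to_frames(float(to), params.camera_rate, params.quantise),
            quantise_to_frames(float(h), params.camera_rate, params.quantise),
        )
        for to, h in zip(toe, heel)
    ]
    annotation = CameraAnnotation(camera_rate=params.camera_rate, steps=steps)
    return trace, annotation, truth
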