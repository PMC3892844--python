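"""High-speed-camera reference: frame arithmetic, legality labels, operator reliability.

The camera measures the signed ground-contact overlap of each step as the
frame count between toe-off of one foot and heel strike of the contralateral
foot, converted to seconds by t = (sum of frames) / Hz.  Positive time is
double support (legal), negative time is flight (illegal), and events in the
same capture frame sit exactly on the threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraAnnotation",
    "CameraStepResult",
    "camera_flight_time",
    "camera_ground_overlap",
    "label_camera_steps",
    "reliability_trial",
]


@dataclass(frozen=True)
class CameraAnnotation:
    """Per-step (toe_off_frame, heel_strike_frame) pairs at the camera rate."""

    camera_rate: float
    steps: list

    def __post_init__(self) -> None:
        if self.camera_rate <= 0:
            raise ValueError("camera_rate must be positive")
        for to, hs in self.steps:
            if to < 0 or hs < 0:
                raise ValueError("frame indices must be non-negative")

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class CameraStepResult:
    """Signed overlap and legality label of one camera-measured step.

    ``label`` is "illegal" for negative overlap (flight), "threshold" for a
    same-frame event pair (0.00 s, counted legal downstream) and "legal"
    otherwise.
    """

    step_index: int
    overlap_time: float
    label: str


def camera_flight_time(frame_count: int, camera_rate: float) -> float:
    """Duration of ``frame_count`` camera frames, seconds (t = n / Hz)."""
    if camera_rate <= 0:
        raise ValueError("camera_rate must be positive")
    if frame_count < 0:
        raise ValueError("frame_count must be non-negative")
    return frame_count / camera_rate


def camera_ground_overlap(
    toe_off_frame: int, heel_strike_frame: int, camera_rate: float
) -> float:
    """Signed ground-contact overlap (toe_off - heel_strike) / Hz, seconds.

    Positive when toe-off follows the contralateral heel strike (double
    support), negative when it precedes it (flight), zero for same-frame.
    """
    if camera_rate <= 0:
        raise ValueError("camera_rate must be positive")
    return (toe_off_frame - heel_strike_frame) / camera_rate


def _label(frame_diff: int) -> str:
    if frame_diff < 0:
        return "illegal"
    if frame_diff == 0:
        return "threshold"
    return "legal"


def label_camera_steps(annotation: CameraAnnotation) -> list[CameraStepResult]:
    """One labelled result per annotated step (empty annotation -> empty list)."""
    out = []
    for k, (to, hs) in enumerate(annotation.steps):
        out.append(
            CameraStepResult(
                step_index=k,
                overlap_time=camera_ground_overlap(to, hs, annotation.camera_rate),
                label=_label(to - hs),
            )
        )
    return out


def reliability_trial(event_frames) -> np.ndarray:
    """Per-event disagreement counts from repeated frame identifications.

    ``event_frames`` is an events x repeats table of integer frame numbers
    (>= 2 repeats per event; ragged tables are rejected).  For each event
    the modal frame is taken as the consensus and the count of repeats that
    differ from it is returned.  Modal ties are broken toward the value
    closest to the event median, then toward the smaller frame.
    """
    arr = np.asarray(event_frames)
    if arr.ndim != 2:
        raise ValueError("event_frames must be a rectangular events x repeats table")
    if arr.shape[1] < 2:
        raise ValueError("at least two repeats per event are required")
    counts = np.empty(arr.shape[0], dtype=int)
    for i, row in enumerate(arr):
        tally = Counter(row.tolist())
        top = max(tally.values())
        med = float(np.median(row))
        mode = min((v for v, c in tally.items() if c == top), key=lambda v: (abs(v - med), v))
        counts[i] = int(np.sum(row != mode))
    return counts
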