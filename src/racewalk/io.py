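"""Readers and writers for the pipeline's plain-text artefacts.

CSV uses comma separators, dot decimals and a header row; JSON is written
with sorted keys and stable indentation so re-runs from the same seed are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .camera import CameraAnnotation, CameraStepResult
from .detect import AccelTrace, StepAssessment, StepAssessments
from .stats import StepComparison

G_TO_MS2 = 9.80665


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_trace_csv(trace: AccelTrace, path, units: str = "g") -> None:
    """Write a trace as time_s, ap_g, vert_g, ml_g (optionally in m/s^2)."""
    df = trace.to_frame()
    if units == "m/s2":
        for c in ("ap_g", "vert_g", "ml_g"):
            df[c.replace("_g", "_ms2")] = df.pop(c) * G_TO_MS2
    elif units != "g":
        raise ValueError("units must be 'g' or 'm/s2'")
    df.to_csv(path, index=False)


def read_trace_csv(path) -> AccelTrace:
    return AccelTrace.from_frame(pd.read_csv(path))


def write_annotation_json(annotation: CameraAnnotation, path) -> None:
    obj = {
        "camera_rate_hz": annotation.camera_rate,
        "steps": [
            {
                "step_index": k,
                "toe_off_frame": int(to),
                "heel_strike_frame": int(hs),
                "toe_off_time_s": to / annotation.camera_rate,
                "heel_strike_time_s": hs / annotation.camera_rate,
            }
            for k, (to, hs) in enumerate(annotation.steps)
        ],
    }
    write_json(obj, path)


def read_annotation(path) -> CameraAnnotation:
    """Read a camera annotation from JSON or CSV (toe_off_frame, heel_strike_frame)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        rate = float(df["camera_rate_hz"].iloc[0]) if "camera_rate_hz" in df else 125.0
        steps = list(zip(df["toe_off_frame"].astype(int), df["heel_strike_frame"].astype(int)))
        return CameraAnnotation(camera_rate=rate, steps=steps)
    obj = read_json(path)
    steps = [(int(s["toe_off_frame"]), int(s["heel_strike_frame"])) for s in obj["steps"]]
    return CameraAnnotation(camera_rate=float(obj["camera_rate_hz"]), steps=steps)


def write_ground_truth_json(truth, path) -> None:
    obj = {
        "steps": [
            {
                "step_index": k,
                "toe_off_time_s": float(truth.toe_off_times[k]),
                "heel_strike_time_s": float(truth.heel_strike_times[k]),
                "overlap_time_s": float(truth.overlap_times[k]),
                "legality": truth.legality[k],
            }
            for k in range(truth.n_steps)
        ]
    }
    write_json(obj, path)


def write_assessments_csv(assessments: Sequence[StepAssessment], path) -> None:
    df = pd.DataFrame(
        [
            {
                "step_index": a.step_index,
                "vert_min_time_s": a.vert_min_time,
                "heel_strike_time_s": a.heel_strike_time,
                "offset_s": a.offset,
                "verdict": a.verdict,
            }
            for a in assessments
        ],
        columns=["step_index", "vert_min_time_s", "heel_strike_time_s", "offset_s", "verdict"],
    )
    df.to_csv(path, index=False)


def read_assessments_csv(path) -> StepAssessments:
    df = pd.read_csv(path)
    return StepAssessments(
        StepAssessment(
            step_index=int(r.step_index),
            vert_min_time=float(r.vert_min_time_s),
            heel_strike_time=float(r.heel_strike_time_s),
            offset=float(r.offset_s),
            verdict=str(r.verdict),
        )
        for r in df.itertuples()
    )


def write_camera_results_csv(results: Sequence[CameraStepResult], path) -> None:
    df = pd.DataFrame(
        [
            {"step_index": r.step_index, "overlap_s": r.overlap_time, "label": r.label}
            for r in results
        ],
        columns=["step_index", "overlap_s", "label"],
    )
    df.to_csv(path, index=False)


def read_camera_results_csv(path) -> list[CameraStepResult]:
    df = pd.read_csv(path)
    return [
        CameraStepResult(
            step_index=int(r.step_index),
            overlap_time=float(r.overlap_s),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]


def write_comparisons_csv(pairs: Sequence[StepComparison], path) -> None:
    df = pd.DataFrame(
        [
            {
                "step_index": p.step_index,
                "camera_overlap_s": p.camera_overlap,
                "camera_label": p.camera_label,
                "sensor_offset_s": p.sensor_offset,
                "sensor_verdict": p.sensor_verdict,
            }
            for p in pairs
        ],
        columns=[
            "step_index",
            "camera_overlap_s",
            "camera_label",
            "sensor_offset_s",
            "sensor_verdict",
        ],
    )
    df.to_csv(path, index=False)


def read_comparisons_csv(path) -> list[StepComparison]:
    df = pd.read_csv(path)
    return [
        StepComparison(
            step_index=int(r.step_index),
            camera_overlap=float(r.camera_overlap_s),
            sensor_offset=float(r.sensor_offset_s),
            camera_label=str(r.camera_label),
            sensor_verdict=str(r.sensor_verdict),
        )
        for r in df.itertuples()
    ]
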