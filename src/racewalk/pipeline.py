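"""End-to-end orchestration: simulate/load -> detect -> camera-label -> compare.

Every run writes its artefacts (trace CSV, annotation JSON, assessment and
camera-result CSVs, the merged comparison table, agreement/confusion report
and a manifest echoing the configuration and seed) into one output
directory, so a run can be reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io
from .camera import CameraAnnotation, label_camera_steps
from .detect import DetectionConfig, StepAssessments, analyse_trace, _pair_events
from .sim import GaitParams, simulate_walk
from .stats import (
    AgreementError,
    AgreementReport,
    ConfusionSummary,
    StepComparison,
    agreement_from_comparisons,
    confusion,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "StageError",
    "run_pipeline",
    "match_comparisons",
    "quadrant_report",
]

logger = logging.getLogger("racewalk")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending path."""

    def __init__(self, stage: str, message: str, path=None):
        super().__init__(f"[{stage}] {message}" + (f" ({path})" if path else ""))
        self.stage = stage
        self.path = path


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``mode`` is "simulate" (generate inputs from ``gait``) or "files"
    (read ``trace_path`` and ``annotation_path``).  Detection settings and
    the camera rate apply in both modes.
    """

    out_dir: str = "racewalk_out"
    mode: str = "simulate"
    gait: GaitParams = field(default_factory=GaitParams)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    camera_rate: float = 125.0
    trace_path: str | None = None
    annotation_path: str | None = None
    make_plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a flat YAML key-value document.

        Keys mirror the CLI flags: mode, out_dir, trace, annotation,
        camera_rate, plot, the GaitParams fields (step_rate, n_steps,
        overlap_time, noise_sd, seed, ...) and the DetectionConfig fields
        (cutoff_hz, flight_threshold, min_peak_separation,
        peak_prominence).
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_flat(raw)

    @classmethod
    def from_flat(cls, raw: dict) -> "PipelineConfig":
        gait_fields = set(GaitParams.__dataclass_fields__)
        det_fields = set(DetectionConfig.__dataclass_fields__)
        gait = GaitParams(**{k: v for k, v in raw.items() if k in gait_fields})
        det = DetectionConfig(**{k: v for k, v in raw.items() if k in det_fields})
        return cls(
            out_dir=raw.get("out_dir", "racewalk_out"),
            mode=raw.get("mode", "simulate"),
            gait=gait,
            detection=det,
            camera_rate=raw.get("camera_rate", gait.camera_rate),
            trace_path=raw.get("trace"),
            annotation_path=raw.get("annotation"),
            make_plot=bool(raw.get("plot", False)),
        )

    def to_flat(self) -> dict:
        flat = {
            "mode": self.mode,
            "out_dir": str(self.out_dir),
            "camera_rate": self.camera_rate,
            "trace": self.trace_path,
            "annotation": self.annotation_path,
            "plot": self.make_plot,
        }
        for k, v in vars(self.gait).items():
            flat[k] = v if not isinstance(v, np.ndarray) else v.tolist()
        for k, v in vars(self.detection).items():
            flat[k] = v
        return flat


@dataclass
class PipelineResult:
    comparisons: list
    confusion: ConfusionSummary | None
    agreement: AgreementReport | None
    assessments: StepAssessments
    camera_results: list
    manifest: dict
    paths: dict


def match_comparisons(
    camera_results: Sequence,
    annotation: CameraAnnotation,
    assessments: Sequence,
) -> list[StepComparison]:
    """Pair camera steps with sensor assessments by heel-strike time.

    Each camera step's heel-strike frame time is matched to the nearest
    sensor heel-strike time within half the median camera step interval
    (greedy one-to-one).  Steps left unmatched on either side are dropped
    from the comparison (and logged).
    """
    if not camera_results or not assessments:
        return []
    cam_times = np.array(
        [hs / annotation.camera_rate for _, hs in annotation.steps], dtype=float
    )
    sen_times = np.array([a.heel_strike_time for a in assessments], dtype=float)
    if len(cam_times) >= 2:
        window = 0.5 * float(np.median(np.diff(np.sort(cam_times))))
    else:
        window = 0.5 / annotation.camera_rate * 25  # ~0.1 s fallback
    pairs, orphan_c, orphan_s = _pair_events(cam_times, sen_times, window)
    if orphan_c or orphan_s:
        logger.warning(
            "compare: %d camera steps and %d sensor steps unmatched",
            len(orphan_c),
            len(orphan_s),
        )
    out = []
    for ci, si in pairs:
        cam = camera_results[ci]
        a = assessments[si]
        out.append(
            StepComparison(
                step_index=cam.step_index,
                camera_overlap=cam.overlap_time,
                sensor_offset=a.offset,
                camera_label=cam.label,
                sensor_verdict=a.verdict,
            )
        )
    return out


def quadrant_report(
    pairs: Sequence[StepComparison],
    path=None,
    threshold: float = 0.03,
) -> dict:
    """Scatter camera overlap (x) vs sensor signed timing (y) by quadrant.

    Positive data from either system indicate legal steps, negative data
    illegal steps: top-right = both legal, bottom-left = both illegal,
    top-left = camera-illegal steps the sensor missed, bottom-right =
    camera-legal steps the sensor flagged (threshold steps, on the y axis,
    included).  Returns the per-quadrant counts; writes a figure if
    ``path`` is given.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("quadrant report requires at least one pair")
    counts = {"top_right": 0, "bottom_left": 0, "top_left": 0, "bottom_right": 0}
    for p in pairs:
        cam_illegal = p.camera_label == "illegal"
        sen_illegal = p.sensor_verdict == "illegal"
        if cam_illegal and sen_illegal:
            counts["bottom_left"] += 1
        elif cam_illegal:
            counts["top_left"] += 1
        elif sen_illegal:
            counts["bottom_right"] += 1
        else:
            counts["top_right"] += 1

    if path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        x = [p.camera_overlap for p in pairs]
        y = [p.sensor_margin(threshold) for p in pairs]
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(x, y, s=18, alpha=0.6, edgecolor="none")
        ax.axhline(0, color="0.4", lw=0.8)
        ax.axvline(0, color="0.4", lw=0.8)
        ax.set_xlabel("camera ground-contact overlap (s)")
        ax.set_ylabel("sensor signed timing (s)")
        ax.set_title(
            "agree legal {top_right} / agree illegal {bottom_left} / "
            "missed {top_left} / flagged {bottom_right}".format(**counts),
            fontsize=9,
        )
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return counts


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(name, str(exc)) from exc
    logger.info("%s: done in %.3f s", name, time.perf_counter() - t0)
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate/load -> detect -> camera-label -> compare and write artefacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    # --- acquire inputs -------------------------------------------------
    if config.mode == "simulate":
        trace, annotation, truth = _stage("simulate", simulate_walk, config.gait)
        paths["trace"] = out / "trace.csv"
        paths["annotation"] = out / "annotation.json"
        paths["ground_truth"] = out / "ground_truth.json"
        io.write_trace_csv(trace, paths["trace"])
        io.write_annotation_json(annotation, paths["annotation"])
        io.write_ground_truth_json(truth, paths["ground_truth"])
    elif config.mode == "files":
        if not config.trace_path or not Path(config.trace_path).exists():
            raise StageError("load", "trace file missing", config.trace_path)
        if not config.annotation_path or not Path(config.annotation_path).exists():
            raise StageError("load", "annotation file missing", config.annotation_path)
        trace = _stage("load", io.read_trace_csv, config.trace_path)
        annotation = _stage("load", io.read_annotation, config.annotation_path)
    else:
        raise StageError("config", f"unknown mode {config.mode!r}")

    manifest = {
        "config": config.to_flat(),
        "seed": config.gait.seed,
        "flight_threshold_s": config.detection.flight_threshold,
        "cutoff_hz": config.detection.cutoff_hz,
        "version": _version(),
    }

    if len(trace) == 0 or annotation.n_steps == 0:
        logger.warning("pipeline: zero steps, writing empty report")
        empty = StepAssessments()
        paths["report"] = out / "report.json"
        manifest["n_steps"] = 0
        io.write_json({"n_steps": 0, "note": "no steps to assess"}, paths["report"])
        paths["manifest"] = out / "manifest.json"
        io.write_json(manifest, paths["manifest"])
        return PipelineResult([], None, None, empty, [], manifest, paths)

    # --- sensor detection ------------------------------------------------
    assessments = _stage("detect", analyse_trace, trace, config.detection)
    paths["assessments"] = out / "assessments.csv"
    io.write_assessments_csv(assessments, paths["assessments"])
    logger.info(
        "detect: %d steps assessed, %d minima unpaired",
        len(assessments),
        assessments.n_unpaired_minima,
    )

    # --- camera reference -------------------------------------------------
    camera_results = _stage("camera-label", label_camera_steps, annotation)
    paths["camera_results"] = out / "camera_results.csv"
    io.write_camera_results_csv(camera_results, paths["camera_results"])

    # --- comparison and statistics ----------------------------------------
    comparisons = _stage(
        "compare", match_comparisons, camera_results, annotation, assessments
    )
    paths["comparisons"] = out / "comparisons.csv"
    io.write_comparisons_csv(comparisons, paths["comparisons"])

    conf = confusion(comparisons) if comparisons else None
    try:
        agr = (
            agreement_from_comparisons(comparisons, config.detection.flight_threshold)
            if len(comparisons) >= 3
            else None
        )
    except AgreementError as exc:
        logger.warning("compare: agreement not computed (%s)", exc)
        agr = None

    report = {
        "n_pairs": len(comparisons),
        "confusion": conf.to_dict() if conf else None,
        "agreement": agr.to_dict() if agr else None,
    }
    paths["report"] = out / "report.json"
    io.write_json(report, paths["report"])
    paths["report_txt"] = out / "report.txt"
    Path(paths["report_txt"]).write_text(_format_report(report))

    if config.make_plot and comparisons:
        paths["quadrant_plot"] = out / "quadrant.png"
        quadrant_report(
            comparisons, paths["quadrant_plot"], config.detection.flight_threshold
        )

    manifest["n_steps"] = len(comparisons)
    paths["manifest"] = out / "manifest.json"
    io.write_json(manifest, paths["manifest"])
    return PipelineResult(
        comparisons, conf, agr, assessments, camera_results, manifest, paths
    )


def _format_report(report: dict) -> str:
    lines = [f"paired steps: {report['n_pairs']}"]
    conf = report.get("confusion")
    if conf:
        lines += [
            "",
            "confusion (camera vs sensor):",
            f"  illegal agreed : {conf['illegal_agree']}",
            f"  illegal missed : {conf['illegal_missed']}",
            f"  legal agreed   : {conf['legal_agree']}",
            f"  legal flagged  : {conf['legal_flagged']}",
            f"  accuracy       : {conf['accuracy_pct']:.2f}% "
            f"(~{conf['accuracy_pct_rounded']}%)",
            f"  illegal-only   : {conf['illegal_only_pct']:.2f}%",
        ]
    agr = report.get("agreement")
    if agr:
        lines += [
            "",
            "agreement (sensor vs camera):",
            f"  n        : {agr['n']}",
            f"  r        : {agr['pearson_r']:.3f}",
            f"  TEE      : {agr['tee_s']:.4f} s "
            f"(95% CL {agr['tee_lower_cl_s']:.4f}-{agr['tee_upper_cl_s']:.4f})",
            f"  bias     : {agr['bias_mean_s']:.4f} s (SD {agr['bias_sd_s']:.4f})",
        ]
    return "\n".join(lines) + "\n"


def _version() -> str:
    from . import __version__

    return __version__
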