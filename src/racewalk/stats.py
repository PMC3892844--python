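"""Agreement and reliability statistics for sensor-vs-camera validation.

Three analyses validate the inertial sensor against the high-speed camera:

* **Limits of agreement** — the practical measure (sensor) is regressed on
  the criterion (camera).  The Typical Error of the Estimate (TEE) is the
  standard error of the estimate, sqrt(RSS / (n - 2)), with 95% confidence
  limits from the chi-square distribution on n - 2 degrees of freedom;
  Pearson's r and the mean bias (mean of sensor - camera differences,
  with their standard deviation) complete the report.
* **Operator reliability** — repeated frame identifications of the same
  events decompose into between-event and within-event variance.  The
  typical error is the within-event standard deviation (square root of the
  one-way mean-square error, in frames, chi-square confidence limits) and
  the intraclass correlation is the two-way mixed, consistency,
  single-measure form ICC(3,1) = (MSB - MSE) / (MSB + (k-1) MSE), with MSE
  taken from the two-way residual.
* **Confusion summary** — per-step legality verdicts are cross-tabulated
  against the camera labels (threshold steps pooled with legal), yielding
  the overall percent agreement and an "only considering illegal steps"
  variant defined as 100 x (total - legal_flagged) / total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "StepComparison",
    "AgreementReport",
    "ReliabilityReport",
    "ConfusionSummary",
    "AgreementError",
    "agreement",
    "agreement_from_comparisons",
    "reliability",
    "confusion",
]

DEFAULT_FLIGHT_THRESHOLD = 0.03


class AgreementError(ValueError):
    """The paired data cannot support an agreement analysis."""


@dataclass(frozen=True)
class StepComparison:
    """Paired camera and sensor results for one step.

    ``camera_overlap`` is the signed camera ground-contact overlap in
    seconds; ``sensor_offset`` the heel-strike-to-vertical-minimum offset
    measured by the sensor.  The sensor's signed timing on the camera's
    scale is ``threshold - sensor_offset`` (positive = legal margin).
    """

    step_index: int
    camera_overlap: float
    sensor_offset: float
    camera_label: str
    sensor_verdict: str

    def sensor_margin(self, threshold: float = DEFAULT_FLIGHT_THRESHOLD) -> float:
        return threshold - self.sensor_offset


@dataclass(frozen=True)
class AgreementReport:
    """Limits-of-agreement summary of practical vs criterion measures."""

    n: int
    pearson_r: float
    tee: float
    tee_lower_cl: float
    tee_upper_cl: float
    bias_mean: float
    bias_sd: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "tee_s": self.tee,
            "tee_lower_cl_s": self.tee_lower_cl,
            "tee_upper_cl_s": self.tee_upper_cl,
            "bias_mean_s": self.bias_mean,
            "bias_sd_s": self.bias_sd,
        }


@dataclass(frozen=True)
class ReliabilityReport:
    """Operator-reliability summary, in frames."""

    typical_error: float
    te_lower_cl: float
    te_upper_cl: float
    icc: float

    def to_dict(self) -> dict:
        return {
            "typical_error_frames": self.typical_error,
            "te_lower_cl_frames": self.te_lower_cl,
            "te_upper_cl_frames": self.te_upper_cl,
            "icc": self.icc,
        }


@dataclass(frozen=True)
class ConfusionSummary:
    """Four-cell legality cross-tabulation of sensor verdicts vs camera labels."""

    illegal_agree: int
    illegal_missed: int
    legal_agree: int
    legal_flagged: int

    @property
    def total(self) -> int:
        return self.illegal_agree + self.illegal_missed + self.legal_agree + self.legal_flagged

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.illegal_agree + self.legal_agree) / self.total

    @property
    def accuracy_pct_rounded(self) -> int:
        return round(self.accuracy_pct)

    @property
    def illegal_only_pct(self) -> float:
        """The "only considering illegal steps" accuracy variant.

        Defined as 100 x (total - legal_flagged) / total, i.e. only steps
        wrongly flagged as illegal count against the sensor.  This is not
        the standard sensitivity illegal_agree / (illegal_agree +
        illegal_missed); see the methods note.
        """
        return 100.0 * (self.total - self.legal_flagged) / self.total

    @property
    def misidentified(self) -> int:
        return self.illegal_missed + self.legal_flagged

    def to_dict(self) -> dict:
        return {
            "illegal_agree": self.illegal_agree,
            "illegal_missed": self.illegal_missed,
            "legal_agree": self.legal_agree,
            "legal_flagged": self.legal_flagged,
            "total": self.total,
            "accuracy_pct": self.accuracy_pct,
            "accuracy_pct_rounded": self.accuracy_pct_rounded,
            "illegal_only_pct": self.illegal_only_pct,
            "misidentified": self.misidentified,
        }


def agreement(criterion, practical) -> AgreementReport:
    """Limits-of-agreement analysis of paired measures.

    Parameters
    ----------
    criterion:
        The reference measure (camera overlap times), length n >= 3.
    practical:
        The measure under validation (sensor timings), same length.

    The TEE is the standard error of the estimate from ordinary least
    squares of ``practical`` on ``criterion``; its 95% confidence limits
    scale the TEE by sqrt(df / chi2) at the 97.5th and 2.5th percentiles
    of chi-square with df = n - 2.
    """
    x = np.asarray(criterion, dtype=float)
    y = np.asarray(practical, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError("criterion and practical must be 1-d and equal length")
    n = len(x)
    if n < 3:
        raise AgreementError(f"need at least 3 pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AgreementError("non-finite values in paired measures")
    if np.ptp(x) == 0:
        raise AgreementError("criterion measure has zero variance")
    sxx = float(np.sum((x - x.mean()) ** 2))

    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    df = n - 2
    tee = math.sqrt(float(np.sum(resid**2)) / df)
    tee_lo = tee * math.sqrt(df / sstats.chi2.ppf(0.975, df))
    tee_hi = tee * math.sqrt(df / sstats.chi2.ppf(0.025, df))

    syy = float(np.sum((y - y.mean()) ** 2))
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else float("nan")
    d = y - x
    return AgreementReport(
        n=n,
        pearson_r=r,
        tee=tee,
        tee_lower_cl=tee_lo,
        tee_upper_cl=tee_hi,
        bias_mean=float(d.mean()),
        bias_sd=float(d.std(ddof=1)),
    )


def agreement_from_comparisons(
    pairs: Sequence[StepComparison], threshold: float = DEFAULT_FLIGHT_THRESHOLD
) -> AgreementReport:
    """Agreement of sensor signed timings against camera overlaps.

    The sensor offset is mapped to the camera's signed scale as
    ``threshold - offset`` so both measures share sign semantics
    (positive = legal, negative = flight).
    """
    x = [p.camera_overlap for p in pairs]
    y = [p.sensor_margin(threshold) for p in pairs]
    return agreement(x, y)


def reliability(table) -> ReliabilityReport:
    """Within-operator reliability of repeated event identifications.

    ``table`` is an events x repeats array (>= 2 events, >= 2 repeats).
    Typical error is the within-event SD from the one-way decomposition
    (df = n_events x (repeats - 1)); the ICC is the two-way mixed,
    consistency, single-measure form, which ignores a fixed offset per
    repeat.  Zero between-event variance leaves the ICC undefined (NaN).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be a rectangular events x repeats array")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 events and 2 repeats")

    event_means = arr.mean(axis=1)
    ss_within = float(np.sum((arr - event_means[:, None]) ** 2))
    df_w = n * (k - 1)
    te = math.sqrt(ss_within / df_w)
    te_lo = te * math.sqrt(df_w / sstats.chi2.ppf(0.975, df_w))
    te_hi = te * math.sqrt(df_w / sstats.chi2.ppf(0.025, df_w))

    grand = arr.mean()
    repeat_means = arr.mean(axis=0)
    ss_total = float(np.sum((arr - grand) ** 2))
    ss_event = k * float(np.sum((event_means - grand) ** 2))
    ss_repeat = n * float(np.sum((repeat_means - grand) ** 2))
    ss_resid = max(ss_total - ss_event - ss_repeat, 0.0)
    msb = ss_event / (n - 1)
    mse = ss_resid / ((n - 1) * (k - 1))
    if msb + (k - 1) * mse == 0:
        icc = float("nan")  # no between-event variance: ICC undefined
    else:
        icc = (msb - mse) / (msb + (k - 1) * mse)
    return ReliabilityReport(typical_error=te, te_lower_cl=te_lo, te_upper_cl=te_hi, icc=icc)


def confusion(pairs: Sequence[StepComparison]) -> ConfusionSummary:
    """Cross-tabulate sensor verdicts against camera labels.

    Camera "threshold" (0.00 s) steps are pooled with legal.  Cells always
    sum to the number of input pairs; empty input is rejected.
    """
    if len(pairs) == 0:
        raise ValueError("confusion summary requires at least one pair")
    ia = im = la = lf = 0
    for p in pairs:
        cam_illegal = p.camera_label == "illegal"
        sen_illegal = p.sensor_verdict == "illegal"
        if cam_illegal and sen_illegal:
            ia += 1
        elif cam_illegal:
            im += 1
        elif sen_illegal:
            lf += 1
        else:
            la += 1
    return ConfusionSummary(
        illegal_agree=ia, illegal_missed=im, legal_agree=la, legal_flagged=lf
    )
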