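"""Longitudinal MRD status, trajectory groups, lead times and cohort summaries.

A timepoint is MRD-positive when ctDNA and/or CTCs are detected; an
inconclusive analyte is ignored whenever the other analyte is conclusive.
Post-surgery trajectories fall into four groups (consistently negative,
intermittently positive, cleared on treatment, converted to positive), and
for relapsing patients the lead time is the interval between the earliest
post-surgery MRD-positive sample and clinically evident relapse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from scipy import stats

from .calling import CallStatus, Status

__all__ = [
    "TrajectoryGroup",
    "TimepointResult",
    "PatientTimeline",
    "DiagnosticSummary",
    "LeadTime",
    "timepoint_mrd",
    "lead_time",
    "classify_trajectory",
    "diagnostic_performance",
    "detection_rate",
]


class TrajectoryGroup(str, enum.Enum):
    ALWAYS_NEGATIVE = "always_negative"
    INTERMITTENT_POSITIVE = "intermittent_positive"
    CLEARED_ON_TREATMENT = "cleared_on_treatment"
    CONVERTED_POSITIVE = "converted_positive"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class TimepointResult:
    months_from_surgery: float  # negative before surgery
    ctdna_status: CallStatus | None = None
    ctc_status: CallStatus | None = None

    @property
    def combined(self) -> Status:
        statuses = [
            s.status
            for s in (self.ctdna_status, self.ctc_status)
            if s is not None
        ]
        return timepoint_mrd(*statuses) if statuses else Status.INCONCLUSIVE


@dataclass
class PatientTimeline:
    patient_id: str
    timepoints: list[TimepointResult]
    pcr_status: bool | None = None
    high_risk: bool | None = None
    relapse_months_from_surgery: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        months = [t.months_from_surgery for t in self.timepoints]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError(
                f"{self.patient_id}: timepoints must be strictly ordered in time"
            )

    def follow_up_points(self) -> list[TimepointResult]:
        """Post-surgery timepoints with a conclusive combined status."""
        return [
            t
            for t in self.timepoints
            if t.months_from_surgery > 0 and t.combined is not Status.INCONCLUSIVE
        ]


def timepoint_mrd(*statuses: Status) -> Status:
    """Combine per-analyte calls into one MRD status (positive = any positive).

    Detection of ctDNA and/or CTCs makes the timepoint positive; it is
    negative only when every conclusive analyte is negative, and inconclusive
    when no analyte is conclusive.
    """
    if not statuses:
        raise ValueError("at least one component status required")
    conclusive = [s for s in statuses if s is not Status.INCONCLUSIVE]
    if not conclusive:
        return Status.INCONCLUSIVE
    if Status.POSITIVE in conclusive:
        return Status.POSITIVE
    return Status.NEGATIVE


@dataclass(frozen=True)
class LeadTime:
    months: float
    detection_after_relapse: bool = False


def lead_time(relapse_months: float, detection_months: float) -> LeadTime:
    """Months by which blood MRD detection preceded clinical relapse.

    Both arguments are measured from surgery. A negative value (detection
    after relapse) is returned with a warning flag rather than rejected.
    """
    months = relapse_months - detection_months
    return LeadTime(months=months, detection_after_relapse=months < 0)


def classify_trajectory(timeline: PatientTimeline) -> TrajectoryGroup:
    """Assign one of the four follow-up trajectory groups.

    Inconclusive timepoints are dropped first. With ``S`` the remaining
    post-surgery status sequence:

    - all negative               -> ``always_negative``
    - some positive, ends neg    -> ``cleared_on_treatment``
    - starts negative, ends pos  -> ``converted_positive``
    - starts positive, ends pos  -> ``intermittent_positive``

    The partition is exhaustive and mutually exclusive over every binary
    sequence. No conclusive post-surgery timepoint -> ``unclassifiable``.
    """
    seq = [t.combined for t in timeline.follow_up_points()]
    if not seq:
        return TrajectoryGroup.UNCLASSIFIABLE
    if Status.POSITIVE not in seq:
        return TrajectoryGroup.ALWAYS_NEGATIVE
    if seq[-1] is Status.NEGATIVE:
        return TrajectoryGroup.CLEARED_ON_TREATMENT
    if seq[0] is Status.NEGATIVE:
        return TrajectoryGroup.CONVERTED_POSITIVE
    return TrajectoryGroup.INTERMITTENT_POSITIVE


@dataclass(frozen=True)
class DiagnosticSummary:
    true_positives: int
    false_negatives: int
    sensitivity: float  # percent
    ci_low: float  # percent
    ci_high: float  # percent
    alpha: float = 0.05


def diagnostic_performance(
    tp: int, fn: int, alpha: float = 0.05
) -> DiagnosticSummary:
    """Sensitivity with the exact (Clopper-Pearson) binomial confidence interval.

    Bounds come from inverting the binomial tail probabilities, evaluated via
    the beta-quantile form of the Clopper-Pearson interval.
    """
    if tp < 0 or fn < 0:
        raise ValueError("counts must be >= 0")
    n = tp + fn
    if n == 0:
        raise ValueError("tp + fn must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sens = 100.0 * tp / n
    lo = 0.0 if tp == 0 else float(stats.beta.ppf(alpha / 2, tp, n - tp + 1))
    hi = 1.0 if tp == n else float(stats.beta.ppf(1 - alpha / 2, tp + 1, n - tp))
    return DiagnosticSummary(
        true_positives=tp,
        false_negatives=fn,
        sensitivity=round(sens, 2),
        ci_low=round(100.0 * lo, 2),
        ci_high=round(100.0 * hi, 2),
        alpha=alpha,
    )


def detection_rate(n_positive: int, n_total: int) -> float:
    """Detection percentage, truncated to two decimals.

    Cohort detection percentages are conventionally reported truncated
    (6/9 -> 66.66, 19/21 -> 90.47) rather than rounded.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must be in [0, n_total]")
    pct = 100.0 * n_positive / n_total
    # Truncate (not round) at the second decimal; guard float representation
    # so exact values like 50.0 are not nudged down.
    return int(pct * 100 + 1e-9) / 100.0
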