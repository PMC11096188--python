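"""Positivity calling for ddPCR replicates and samples.

A replicate (20 mL plasma or 200 million blood cells) is positive when it
holds two or more FAM-positive droplets. A sample timepoint is positive when
at least one replicate is individually positive; one FAM droplet in each of
two replicates is negative (the droplets must co-occur within a replicate).
Any positivity in the matched germline or no-template controls renders the
timepoint inconclusive. Very low positives (2-3 FAM droplets in total) are
flagged for confirmation with two extra germline-control wells, and a
germline sample that itself calls positive flags the mutation as a likely
clonal-hematopoiesis (CHIP) event rather than tumor-derived signal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "CallLevel",
    "Status",
    "Reason",
    "CallStatus",
    "call_replicate",
    "call_sample",
    "flag_chip",
]

DEFAULT_MIN_FAM_DROPLETS = 2

#: FAM totals that trigger the low-positive confirmation workflow.
LOW_POSITIVE_RANGE = (2, 3)


class CallLevel(str, enum.Enum):
    REPLICATE = "replicate"
    SAMPLE = "sample"


class Status(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INCONCLUSIVE = "inconclusive"


class Reason(str, enum.Enum):
    GE2_FAM_SINGLE_REPLICATE = "ge2_fam_single_replicate"
    SPLIT_DROPLETS_ACROSS_REPLICATES = "split_droplets_across_replicates"
    LT2_FAM_TOTAL = "lt2_fam_total"
    CONTROL_POSITIVE = "control_positive"
    NO_VALID_REPLICATES = "no_valid_replicates"


@dataclass(frozen=True)
class CallStatus:
    level: CallLevel
    status: Status
    reason: Reason
    low_positive_flag: bool = False
    only_double_positives: bool = False
    chip_flag: bool = False
    combine_wells_for_quant: bool = False

    def __post_init__(self) -> None:
        if self.reason is Reason.CONTROL_POSITIVE and self.status is not Status.INCONCLUSIVE:
            raise ValueError("control_positive reason requires inconclusive status")
        if self.low_positive_flag and self.status is not Status.POSITIVE:
            raise ValueError("low_positive_flag requires a positive status")

    @property
    def is_positive(self) -> bool:
        return self.status is Status.POSITIVE


def call_replicate(
    pooled_fam_positive: int,
    min_fam_droplets: int = DEFAULT_MIN_FAM_DROPLETS,
) -> CallStatus:
    """Call one replicate from its pooled FAM-positive droplet total."""
    if pooled_fam_positive < 0:
        raise ValueError("droplet count must be >= 0")
    if pooled_fam_positive >= min_fam_droplets:
        return CallStatus(
            level=CallLevel.REPLICATE,
            status=Status.POSITIVE,
            reason=Reason.GE2_FAM_SINGLE_REPLICATE,
        )
    return CallStatus(
        level=CallLevel.REPLICATE,
        status=Status.NEGATIVE,
        reason=Reason.LT2_FAM_TOTAL,
    )


def call_sample(
    replicate_fam_counts: list[int],
    control_statuses: list[CallStatus] | None = None,
    replicate_fam_only_counts: list[int] | None = None,
    min_fam_droplets: int = DEFAULT_MIN_FAM_DROPLETS,
) -> CallStatus:
    """Call one sample timepoint from its replicates and matched controls.

    Parameters
    ----------
    replicate_fam_counts:
        Pooled FAM-positive droplet total per replicate, in run order.
    control_statuses:
        Calls for the matched germline and no-template control wells; any
        positive control invalidates the timepoint (inconclusive).
    replicate_fam_only_counts:
        Optional FAM-only (non-double-positive) totals per replicate, used to
        record whether a low positive consisted solely of double-positive
        droplets — the configuration singled out for extra germline controls.
    """
    if not replicate_fam_counts:
        return CallStatus(
            level=CallLevel.SAMPLE,
            status=Status.INCONCLUSIVE,
            reason=Reason.NO_VALID_REPLICATES,
        )
    if any(c < 0 for c in replicate_fam_counts):
        raise ValueError("droplet counts must be >= 0")

    if control_statuses and any(c.is_positive for c in control_statuses):
        return CallStatus(
            level=CallLevel.SAMPLE,
            status=Status.INCONCLUSIVE,
            reason=Reason.CONTROL_POSITIVE,
        )

    replicate_calls = [
        call_replicate(c, min_fam_droplets) for c in replicate_fam_counts
    ]
    total_fam = sum(replicate_fam_counts)

    if any(r.is_positive for r in replicate_calls):
        # Quantification merges wells from an initially negative replicate
        # with the later positive one.
        first_positive = next(
            i for i, r in enumerate(replicate_calls) if r.is_positive
        )
        combine = first_positive > 0
        low_pos = LOW_POSITIVE_RANGE[0] <= total_fam <= LOW_POSITIVE_RANGE[1]
        only_double = False
        if low_pos and replicate_fam_only_counts is not None:
            only_double = sum(replicate_fam_only_counts) == 0
        return CallStatus(
            level=CallLevel.SAMPLE,
            status=Status.POSITIVE,
            reason=Reason.GE2_FAM_SINGLE_REPLICATE,
            low_positive_flag=low_pos,
            only_double_positives=only_double,
            combine_wells_for_quant=combine,
        )

    if total_fam >= min_fam_droplets:
        # Enough droplets overall, but spread across replicates: negative.
        return CallStatus(
            level=CallLevel.SAMPLE,
            status=Status.NEGATIVE,
            reason=Reason.SPLIT_DROPLETS_ACROSS_REPLICATES,
        )
    return CallStatus(
        level=CallLevel.SAMPLE,
        status=Status.NEGATIVE,
        reason=Reason.LT2_FAM_TOTAL,
    )


def flag_chip(
    sample_status: CallStatus,
    matched_germline_fam_positive: int,
    min_fam_droplets: int = DEFAULT_MIN_FAM_DROPLETS,
) -> bool:
    """True when the matched germline DNA itself calls positive.

    A mutation detectable in germline (blood-cell) DNA with the same assay is
    a clonal-hematopoiesis event, not tumor signal. The flag is evaluated
    regardless of the sample's own status so it can be carried in reports.
    """
    if matched_germline_fam_positive < 0:
        raise ValueError("droplet count must be >= 0")
    return matched_germline_fam_positive >= min_fam_droplets
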