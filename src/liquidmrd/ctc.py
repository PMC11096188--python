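"""CTC enumeration via the MCF7 spike-in calibration.

Circulating tumor cells are counted indirectly: PBMC aliquots are depleted of
CD45-positive leukocytes, DNA is extracted, and the patient's truncal mutation
is quantified by ddPCR. A spike-in experiment (64 or 128 MCF7 cells in 200
million background PBMCs, in triplicate) yields a linear map from mutant
copies per eluate to cell count; inverting that line converts a patient
sample's mutant copies into total CTCs, and dividing by drawn blood volume
gives CTCs per mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "CtcCalibration",
    "SpikeInRecord",
    "DEFAULT_CALIBRATION",
    "fit_ctc_calibration",
    "ctc_total",
    "ctc_per_ml_blood",
    "depletion_efficiency",
]


@dataclass(frozen=True)
class CtcCalibration:
    """Spike-in line: mutant copies per eluate = slope x cells + intercept."""

    slope: float  # copies per cell
    intercept: float  # copies
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must be in [0, 1]")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


#: Published calibration constants, used when no spike-in table is provided.
DEFAULT_CALIBRATION = CtcCalibration(
    slope=0.1992, intercept=0.3072, r_squared=0.9952, n_points=6
)


@dataclass(frozen=True)
class SpikeInRecord:
    spiked_cells: int
    mutant_copies_eluate: float
    replicate_index: int = 0
    pbmc_background: float = 200e6

    def __post_init__(self) -> None:
        if self.spiked_cells < 0:
            raise ValueError("spiked_cells must be >= 0")
        if self.mutant_copies_eluate < 0:
            raise ValueError("mutant_copies_eluate must be >= 0")


def fit_ctc_calibration(records: list[SpikeInRecord]) -> CtcCalibration:
    """Ordinary least squares of mutant copies per eluate on spiked cells.

    Fit through the individual replicate points (not replicate means).
    """
    if len(records) < 2:
        raise ValueError("need at least two spike-in points")
    x = [r.spiked_cells for r in records]
    y = [r.mutant_copies_eluate for r in records]
    if len(set(x)) < 2:
        raise ValueError("degenerate design: all spiked_cells levels identical")
    fit = stats.linregress(x, y)
    return CtcCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(records),
    )


def ctc_total(
    mutant_copies_eluate: float,
    calibration: CtcCalibration = DEFAULT_CALIBRATION,
) -> float:
    """Total CTCs = (mutant copies per eluate - intercept) / slope.

    Copy yields below the intercept would invert to negative cell counts,
    which are non-physical; those are clamped to zero.
    """
    if mutant_copies_eluate < 0:
        raise ValueError("mutant_copies_eluate must be >= 0")
    cells = (mutant_copies_eluate - calibration.intercept) / calibration.slope
    return max(cells, 0.0)


def ctc_per_ml_blood(total_ctcs: float, ml_blood: float) -> float:
    """CTCs per mL of drawn blood."""
    if ml_blood <= 0:
        raise ValueError("ml_blood must be > 0")
    if total_ctcs < 0:
        raise ValueError("total_ctcs must be >= 0")
    return total_ctcs / ml_blood


def depletion_efficiency(cells_before: float, cells_after: float) -> float:
    """Log10 reduction of background leukocytes by immunomagnetic depletion.

    Returns ``inf`` when no cells remain (complete depletion).
    """
    if cells_before <= 0:
        raise ValueError("cells_before must be > 0")
    if cells_after < 0:
        raise ValueError("cells_after must be >= 0")
    if cells_after == 0:
        return math.inf
    return math.log10(cells_before / cells_after)
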