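"""Droplet digital PCR quantification.

Converts four-class droplet counts (FAM-only, VIC-only, double-positive,
empty) into channel concentrations via the Poisson occupancy model, then into
variant allele frequency (VAF), mutant copies per eluate, mutant copies per mL
of plasma, mutant genomic equivalents (MGE) and the per-experiment maximum
sensitivity.

The FAM channel labels the mutant allele and VIC the wild-type allele; a
double-positive droplet contains at least one molecule of each, so the
FAM-positive total is ``n_fam_only + n_double_pos`` and the VIC-positive total
is ``n_vic_only + n_double_pos``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Timepoint",
    "SampleType",
    "WellRole",
    "SaturationError",
    "DropletWellRecord",
    "ReplicateSpec",
    "QuantResult",
    "poisson_concentration",
    "pool_replicate_wells",
    "vaf_from_concentrations",
    "copies_per_eluate",
    "copies_per_ml_plasma",
    "mge",
    "max_sensitivity",
    "quantify_replicate",
]

#: Haploid genome equivalent mass in picograms.
PG_PER_HAPLOID_GE = 3.3

#: Default droplet volume in nanoliters (QX200-class instruments).
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Default elution volume in microliters.
DEFAULT_ELUTION_VOLUME_UL = 20.0


class Timepoint(str, enum.Enum):
    PRE_TREATMENT = "pre_treatment"
    POST_NAC = "post_nac"
    POST_SURGERY = "post_surgery"
    FOLLOW_UP = "follow_up"


class SampleType(str, enum.Enum):
    PLASMA = "plasma"
    PBMC = "pbmc"


class WellRole(str, enum.Enum):
    SAMPLE = "sample"
    GERMLINE_CONTROL = "germline_control"
    NO_TEMPLATE_CONTROL = "no_template_control"


class SaturationError(ValueError):
    """All droplets positive: the concentration is not quantifiable."""


@dataclass(frozen=True)
class DropletWellRecord:
    """Four-class droplet counts for one well plus its metadata."""

    patient_id: str
    timepoint: Timepoint
    sample_type: SampleType
    assay_id: str
    well_id: str
    role: WellRole
    replicate_id: str
    n_fam_only: int
    n_vic_only: int
    n_double_pos: int
    n_empty: int

    def __post_init__(self) -> None:
        counts = (self.n_fam_only, self.n_vic_only, self.n_double_pos, self.n_empty)
        if any(c < 0 for c in counts):
            raise ValueError(f"well {self.well_id}: negative droplet count {counts}")
        if sum(counts) <= 0:
            raise ValueError(f"well {self.well_id}: zero total droplets")

    @property
    def n_total(self) -> int:
        return self.n_fam_only + self.n_vic_only + self.n_double_pos + self.n_empty

    @property
    def fam_positive(self) -> int:
        """Droplets containing mutant molecules (FAM-only + double-positive)."""
        return self.n_fam_only + self.n_double_pos

    @property
    def vic_positive(self) -> int:
        """Droplets containing wild-type molecules (VIC-only + double-positive)."""
        return self.n_vic_only + self.n_double_pos


@dataclass(frozen=True)
class ReplicateSpec:
    """Material backing one replicate: 20 mL plasma or 200 million blood cells.

    ``material_amount`` is mL of plasma for plasma samples and millions of
    PBMCs for cell samples; ``cfdna_mass`` is the total cfDNA in the eluate
    (ng), used for MGE; ``ml_blood`` is the drawn blood volume a PBMC aliquot
    represents, used for CTCs per mL.
    """

    replicate_id: str
    material_amount: float
    elution_volume: float = DEFAULT_ELUTION_VOLUME_UL
    cfdna_mass: float | None = None
    ml_blood: float | None = None
    wells: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.material_amount <= 0:
            raise ValueError("material_amount must be > 0")
        if self.elution_volume <= 0:
            raise ValueError("elution_volume must be > 0")


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one sample-timepoint replicate (or merged replicates)."""

    mutant_conc: float  # copies/uL of reaction
    wildtype_conc: float
    vaf: float | None  # undefined when both channels are empty
    mutant_copies_eluate: float
    mutant_copies_per_ml: float | None  # plasma samples only
    mge: float | None  # requires cfDNA mass
    max_sensitivity: float | None
    n_wells: int
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_NL


def poisson_concentration(
    k_positive: int,
    n_total: int,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_NL,
) -> float:
    """Concentration (copies/uL) from positive-droplet counts.

    Under Poisson loading the per-droplet occupancy rate is
    ``lambda = -ln(1 - k/n)``; dividing by the droplet volume (converted from
    nL to uL) gives copies per microliter of reaction.

    Raises
    ------
    SaturationError
        If every droplet is positive (``k == n``); the estimator diverges.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if k_positive < 0 or k_positive > n_total:
        raise ValueError(f"k_positive={k_positive} outside [0, {n_total}]")
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be > 0")
    if k_positive == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: concentration unquantifiable"
        )
    if k_positive == 0:
        return 0.0
    lam = -math.log1p(-k_positive / n_total)
    return lam / (droplet_volume * 1e-3)


def pool_replicate_wells(
    wells: list[DropletWellRecord],
) -> tuple[int, int, int, int]:
    """Element-wise sum of the four droplet classes across one replicate's wells.

    Returns ``(n_fam_only, n_vic_only, n_double_pos, n_empty)``. All wells
    must share ``replicate_id`` and ``assay_id``.
    """
    if not wells:
        raise ValueError("cannot pool an empty well list")
    rep_ids = {w.replicate_id for w in wells}
    assay_ids = {w.assay_id for w in wells}
    if len(rep_ids) > 1:
        raise ValueError(f"mixed replicate_ids in pool: {sorted(rep_ids)}")
    if len(assay_ids) > 1:
        raise ValueError(f"mixed assay_ids in pool: {sorted(assay_ids)}")
    return (
        sum(w.n_fam_only for w in wells),
        sum(w.n_vic_only for w in wells),
        sum(w.n_double_pos for w in wells),
        sum(w.n_empty for w in wells),
    )


def vaf_from_concentrations(mutant_conc: float, wildtype_conc: float) -> float:
    """VAF = mutant / (mutant + wild-type), on concentrations.

    Defined on channel concentrations rather than raw droplet counts so that
    double-positive droplets contribute to both channels.
    """
    if mutant_conc < 0 or wildtype_conc < 0:
        raise ValueError("concentrations must be >= 0")
    total = mutant_conc + wildtype_conc
    if total == 0:
        raise ValueError("VAF undefined: both channel concentrations are zero")
    return mutant_conc / total


def copies_per_eluate(
    conc: float,
    n_wells: int,
    elution_volume: float = DEFAULT_ELUTION_VOLUME_UL,
) -> float:
    """Mutant copies per eluate = conc (copies/uL) x elution volume x wells."""
    if conc < 0:
        raise ValueError("conc must be >= 0")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if elution_volume <= 0:
        raise ValueError("elution_volume must be > 0")
    return conc * elution_volume * n_wells


def copies_per_ml_plasma(copies_eluate: float, ml_plasma: float) -> float:
    """Mutant copies per mL of plasma employed."""
    if ml_plasma <= 0:
        raise ValueError("ml_plasma must be > 0")
    if copies_eluate < 0:
        raise ValueError("copies_eluate must be >= 0")
    return copies_eluate / ml_plasma


def mge(cfdna_mass: float, vaf: float) -> float:
    """Mutant genomic equivalents from cfDNA mass (ng) and VAF.

    MGE = ng cfDNA x (1000 pg/ng / 3.3 pg per haploid GE) x VAF.
    """
    if cfdna_mass < 0:
        raise ValueError("cfdna_mass must be >= 0")
    if not 0 <= vaf <= 1:
        raise ValueError(f"vaf={vaf} outside [0, 1]")
    return cfdna_mass * (1000.0 / PG_PER_HAPLOID_GE) * vaf


def max_sensitivity(
    total_copies_assayed: float, min_detectable_copies: int = 2
) -> float:
    """Smallest callable VAF given the DNA input of an experiment.

    With a calling floor of ``min_detectable_copies`` mutant molecules, the
    lowest detectable fraction is that floor divided by the total (mutant +
    wild-type) copies interrogated.
    """
    if total_copies_assayed <= 0:
        raise ValueError("total_copies_assayed must be > 0")
    if min_detectable_copies <= 0:
        raise ValueError("min_detectable_copies must be > 0")
    return min(min_detectable_copies / total_copies_assayed, 1.0)


def quantify_replicate(
    wells: list[DropletWellRecord],
    spec: ReplicateSpec | None = None,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_NL,
    min_detectable_copies: int = 2,
) -> QuantResult:
    """Full quantification chain for one replicate (or merged replicates).

    Pools droplet counts across wells, estimates both channel concentrations,
    and applies the eluate / per-mL / MGE transforms where the replicate spec
    provides the material amounts. Plasma-specific quantities are ``None`` for
    cell samples (no ``material_amount`` in mL) and MGE is ``None`` without a
    cfDNA mass.
    """
    fam_only, vic_only, double, empty = pool_replicate_wells(wells)
    n_total = fam_only + vic_only + double + empty
    n_wells = len(wells)
    mut_conc = poisson_concentration(fam_only + double, n_total, droplet_volume)
    wt_conc = poisson_concentration(vic_only + double, n_total, droplet_volume)

    vaf: float | None
    if mut_conc + wt_conc > 0:
        vaf = vaf_from_concentrations(mut_conc, wt_conc)
    else:
        vaf = None

    elution = spec.elution_volume if spec is not None else DEFAULT_ELUTION_VOLUME_UL
    mut_eluate = copies_per_eluate(mut_conc, n_wells, elution)
    wt_eluate = copies_per_eluate(wt_conc, n_wells, elution)

    per_ml = None
    sample_type = wells[0].sample_type
    if spec is not None and sample_type is SampleType.PLASMA:
        per_ml = copies_per_ml_plasma(mut_eluate, spec.material_amount)

    mge_value = None
    if spec is not None and spec.cfdna_mass is not None and vaf is not None:
        mge_value = mge(spec.cfdna_mass, vaf)

    total_copies = mut_eluate + wt_eluate
    max_sens = (
        max_sensitivity(total_copies, min_detectable_copies)
        if total_copies > 0
        else None
    )

    return QuantResult(
        mutant_conc=mut_conc,
        wildtype_conc=wt_conc,
        vaf=vaf,
        mutant_copies_eluate=mut_eluate,
        mutant_copies_per_ml=per_ml,
        mge=mge_value,
        max_sensitivity=max_sens,
        n_wells=n_wells,
        droplet_volume=droplet_volume,
    )
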