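"""Synthetic cohorts with the statistical structure of a dual ctDNA/CTC study.

The generator forward-models the whole measurement chain so every pipeline
stage can be exercised and checked against emitted ground truth:

* each patient carries one truncal mutation whose plasma burden (mutant
  copies per mL) is log-normal around the observed pre-treatment median of
  0.73 copies/mL, with responders (pathological complete response, pCR)
  carrying a higher pre-treatment burden and clearing it far more strongly
  after neoadjuvant chemotherapy;
* every sample-timepoint partitions the eluate across ~20,000-droplet wells;
  mutant molecules are placed individually into droplets (so the realized
  molecular ground truth is known exactly), while the abundant wild-type
  background enters as independent per-droplet Poisson occupancy;
* matched germline controls share the sample's partitioning and are clean
  except for rare false-positive droplets — or carry the mutation outright
  for CHIP (clonal hematopoiesis) patients; no-template controls are empty;
* CTC burdens follow a Poisson count per mL of blood and are translated to
  mutant copies through the spike-in line before droplet simulation;
* post-surgery MRD carriage and relapse times are drawn from per-patient
  latent states and recorded in the ground truth.

Ground truth is emitted separately from the pipeline-facing tables and is
never read by the pipeline itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ctc import DEFAULT_CALIBRATION

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "simulate_well_counts",
    "simulate_spikein",
    "simulate_cohort",
    "WELL_TABLE_COLUMNS",
]

WELL_TABLE_COLUMNS = [
    "patient_id",
    "timepoint",
    "sample_type",
    "assay_id",
    "well_id",
    "role",
    "replicate_id",
    "n_fam_only",
    "n_vic_only",
    "n_double_pos",
    "n_empty",
    "material_amount",
    "elution_volume_ul",
    "cfdna_ng",
    "ml_blood",
]

#: Months from surgery for the four study visits (negative = before surgery).
DEFAULT_TIMEPOINT_MONTHS = {
    "pre_treatment": -6.0,
    "post_nac": -0.5,
    "post_surgery": 1.15,
    "follow_up": 12.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the design of the emulated study: 20 mL of plasma or a
    200-million-PBMC aliquot per replicate, eight ~20,000-droplet wells per
    replicate, a pCR rate of 7/21, a pre-treatment burden of 0.73 mutant
    copies/mL of plasma (median) and 0.60 CTCs/mL of blood, and
    treatment-driven clearance of 0.01 (responders) versus 0.3
    (non-responders). Responders carry 4.84x the pre-treatment burden so the
    median pre-to-post MGE change is ~6.85x that of non-responders
    (4.84 x 0.99 / 0.70).
    """

    n_patients: int = 21
    seed: int = 0
    pcr_rate: float = 7 / 21
    plasma_ml_per_timepoint: float = 20.0
    pbmc_millions: float = 200.0
    ml_blood_pbmc: float = 50.0
    n_droplets_per_well: int = 20000
    wells_per_replicate: int = 8
    n_ntc_wells: int = 2
    droplet_volume: float = 0.85  # nL
    elution_volume_ul: float = 20.0
    # log-normal burden: median 0.73 copies/mL, geometric sd exp(1.2)
    pre_mutant_copies_per_ml_median: float = 0.73
    pre_mutant_copies_per_ml_sigma: float = 1.2
    responder_burden_factor: float = 4.84
    # plasma cfDNA yield per mL, log-normal
    cfdna_ng_per_ml_median: float = 8.0
    cfdna_ng_per_ml_sigma: float = 0.5
    responder_clearance: float = 0.01
    nonresponder_clearance: float = 0.3
    ctc_rate_per_ml: float = 0.6
    ctc_copies_noise_sd: float = 0.05
    depletion_log10: float = 3.48
    false_positive_droplet_rate: float = 1e-6
    chip_prevalence: float = 0.05
    chip_vaf: float = 0.02
    high_risk_rate: float = 0.6
    mrd_persistence_responder: float = 0.15
    mrd_persistence_nonresponder: float = 0.5
    mrd_carrier_level: float = 0.1  # fraction of pre-treatment burden
    relapse_hazard_given_mrd_positive: float = 0.03  # per month
    max_followup_months: float = 36.0
    timepoint_months: dict = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINT_MONTHS)
    )

    def __post_init__(self) -> None:
        for name in (
            "pcr_rate",
            "chip_prevalence",
            "chip_vaf",
            "high_risk_rate",
            "mrd_persistence_responder",
            "mrd_persistence_nonresponder",
            "false_positive_droplet_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("n_patients", "n_droplets_per_well", "wells_per_replicate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SimulatedCohort:
    wells: pd.DataFrame
    sample_sheet: pd.DataFrame
    spikein: pd.DataFrame
    ground_truth: dict


def simulate_well_counts(
    mutant_conc: float,
    wildtype_conc: float,
    n_droplets: int = 20000,
    droplet_volume: float = 0.85,
    seed: int | np.random.Generator = 0,
) -> tuple[int, int, int, int]:
    """Draw four-class droplet counts for one well under Poisson loading.

    Each channel occupies droplets independently with probability
    ``1 - exp(-conc * Vd)``; double positives arise by co-occupancy. Returns
    ``(n_fam_only, n_vic_only, n_double_pos, n_empty)``.
    """
    if mutant_conc < 0 or wildtype_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if n_droplets <= 0 or droplet_volume <= 0:
        raise ValueError("n_droplets and droplet_volume must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    vd_ul = droplet_volume * 1e-3
    p_m = 1.0 - math.exp(-mutant_conc * vd_ul)
    p_w = 1.0 - math.exp(-wildtype_conc * vd_ul)
    probs = [
        p_m * (1 - p_w),  # FAM only
        (1 - p_m) * p_w,  # VIC only
        p_m * p_w,  # double positive
        (1 - p_m) * (1 - p_w),  # empty
    ]
    counts = rng.multinomial(n_droplets, probs)
    return int(counts[0]), int(counts[1]), int(counts[2]), int(counts[3])


def simulate_spikein(
    cells_levels: list[int] = (64, 128),
    slope: float = DEFAULT_CALIBRATION.slope,
    intercept: float = DEFAULT_CALIBRATION.intercept,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Spike-in table: mutant copies per eluate vs spiked MCF7 cells."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if any(c < 0 for c in cells_levels):
        raise ValueError("cell levels must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for cells in cells_levels:
        for rep in range(n_reps):
            copies = slope * cells + intercept
            if noise_sd > 0:
                copies += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "spiked_cells": cells,
                    "replicate_index": rep,
                    "mutant_copies_eluate": max(copies, 0.0),
                }
            )
    return pd.DataFrame(rows)


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(rng.normal(0.0, sigma)))


def _mutant_droplets_per_well(
    n_molecules: int,
    n_wells: int,
    n_droplets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place molecules into droplets; count occupied droplets per well."""
    if n_molecules == 0:
        return np.zeros(n_wells, dtype=int)
    pos = rng.integers(0, n_wells * n_droplets, size=n_molecules)
    occupied = np.unique(pos)
    return np.bincount(occupied // n_droplets, minlength=n_wells)


def _simulate_replicate(
    rng: np.random.Generator,
    mutant_conc: float,
    p_wt: float,
    n_wells: int,
    n_droplets: int,
    droplet_volume: float,
    fp_rate: float,
) -> tuple[list[tuple[int, int, int, int]], int, int]:
    """Simulate one replicate's wells at the molecule level for the mutant.

    Returns (per-well four-class counts, realized mutant-occupied droplets,
    false-positive droplets added).
    """
    vd_ul = droplet_volume * 1e-3
    mean_loaded = mutant_conc * vd_ul * n_wells * n_droplets
    n_mol = int(rng.poisson(mean_loaded)) if mean_loaded > 0 else 0
    fam_per_well = _mutant_droplets_per_well(n_mol, n_wells, n_droplets, rng)

    wells: list[tuple[int, int, int, int]] = []
    total_fp = 0
    for w in range(n_wells):
        fam_pos = int(fam_per_well[w])
        double = int(rng.binomial(fam_pos, p_wt)) if fam_pos else 0
        fam_only = fam_pos - double
        rest = n_droplets - fam_pos
        vic_only = int(rng.binomial(rest, p_wt)) if rest else 0
        empty = rest - vic_only
        if fp_rate > 0:
            k_fp = int(rng.poisson(n_droplets * fp_rate))
            k_fp = min(k_fp, empty)
            fam_only += k_fp
            empty -= k_fp
            total_fp += k_fp
        wells.append((fam_only, vic_only, double, empty))
    return wells, int(fam_per_well.sum()), total_fp


def _wt_occupancy(conc: float, droplet_volume: float) -> float:
    return 1.0 - math.exp(-conc * droplet_volume * 1e-3)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort with ground truth.

    Emits the well table and sample sheet the pipeline consumes, a spike-in
    calibration table, and a ground-truth record (true concentrations,
    realized mutant molecules, true MRD states, relapse months) kept separate
    from the pipeline inputs.
    """
    if config.n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    rng = np.random.default_rng(config.seed)

    well_rows: list[dict] = []
    sheet_rows: list[dict] = []
    truth_patients: dict[str, dict] = {}

    elution = config.elution_volume_ul
    n_wells = config.wells_per_replicate
    n_drop = config.n_droplets_per_well
    vd = config.droplet_volume
    total_reaction_ul = elution * n_wells  # per Eq.-style accounting

    ge_per_ng = 1000.0 / 3.3

    def add_wells(
        pid: str,
        timepoint: str,
        sample_type: str,
        role: str,
        replicate_id: str,
        wells: list[tuple[int, int, int, int]],
        material_amount: float,
        cfdna_ng: float | None,
        ml_blood: float | None,
    ) -> None:
        for i, (fo, vo, dp, em) in enumerate(wells):
            well_rows.append(
                {
                    "patient_id": pid,
                    "timepoint": timepoint,
                    "sample_type": sample_type,
                    "assay_id": f"{pid}_assay",
                    "well_id": f"{pid}_{timepoint}_{sample_type}_{role}_{replicate_id}_w{i}",
                    "role": role,
                    "replicate_id": replicate_id,
                    "n_fam_only": fo,
                    "n_vic_only": vo,
                    "n_double_pos": dp,
                    "n_empty": em,
                    "material_amount": material_amount,
                    "elution_volume_ul": elution,
                    "cfdna_ng": "" if cfdna_ng is None else round(cfdna_ng, 4),
                    "ml_blood": "" if ml_blood is None else ml_blood,
                }
            )

    subtypes = ["HR+/HER2-", "HER2+", "TNBC"]
    nodal_levels = ["N0", "N1", "N2", "N3"]

    for idx in range(config.n_patients):
        pid = f"SIM-{idx + 1:03d}"
        pcr = bool(rng.random() < config.pcr_rate)
        chip = bool(rng.random() < config.chip_prevalence)
        high_risk = bool(rng.random() < config.high_risk_rate)
        subtype = subtypes[int(rng.integers(0, len(subtypes)))]
        nodal = nodal_levels[int(rng.integers(0, len(nodal_levels)))]

        pre_burden = _lognormal(
            rng,
            config.pre_mutant_copies_per_ml_median,
            config.pre_mutant_copies_per_ml_sigma,
        )
        if pcr:
            pre_burden *= config.responder_burden_factor
        clearance = (
            config.responder_clearance if pcr else config.nonresponder_clearance
        )
        persist_p = (
            config.mrd_persistence_responder
            if pcr
            else config.mrd_persistence_nonresponder
        )
        mrd_carrier = bool(rng.random() < persist_p)

        # Per-timepoint true plasma burden (mutant copies per mL) and CTC rate.
        burden = {
            "pre_treatment": pre_burden,
            "post_nac": pre_burden * clearance,
            "post_surgery": pre_burden * config.mrd_carrier_level
            if mrd_carrier
            else 0.0,
            "follow_up": pre_burden * config.mrd_carrier_level * 1.5
            if mrd_carrier
            else 0.0,
        }
        pre_ctc_rate = config.ctc_rate_per_ml * (pre_burden / config.pre_mutant_copies_per_ml_median)
        ctc_rate = {
            "pre_treatment": pre_ctc_rate,
            "post_nac": pre_ctc_rate * clearance,
            "post_surgery": pre_ctc_rate * config.mrd_carrier_level
            if mrd_carrier
            else 0.0,
            "follow_up": pre_ctc_rate * config.mrd_carrier_level * 1.5
            if mrd_carrier
            else 0.0,
        }

        timepoints = ["pre_treatment", "post_nac", "post_surgery"]
        if high_risk:
            timepoints.append("follow_up")

        tp_truth: dict[str, dict] = {}
        for tp in timepoints:
            tp_record: dict[str, dict] = {}

            # ---- plasma (ctDNA) ----
            plasma_ml = config.plasma_ml_per_timepoint
            cfdna_ml = _lognormal(
                rng, config.cfdna_ng_per_ml_median, config.cfdna_ng_per_ml_sigma
            )
            cfdna_total = cfdna_ml * plasma_ml
            wt_conc = cfdna_total * ge_per_ng / total_reaction_ul
            mut_total = burden[tp] * plasma_ml
            mut_conc = mut_total / total_reaction_ul
            p_wt = _wt_occupancy(wt_conc, vd)
            wells, realized, n_fp = _simulate_replicate(
                rng, mut_conc, p_wt, n_wells, n_drop, vd,
                config.false_positive_droplet_rate,
            )
            add_wells(pid, tp, "plasma", "sample", "R1", wells, plasma_ml,
                      cfdna_total, None)
            # matched germline control: same partitioning, same DNA amount
            g_mut_conc = config.chip_vaf * wt_conc if chip else 0.0
            g_wells, g_realized, _ = _simulate_replicate(
                rng, g_mut_conc, p_wt, n_wells, n_drop, vd,
                config.false_positive_droplet_rate,
            )
            add_wells(pid, tp, "plasma", "germline_control", "G1", g_wells,
                      plasma_ml, cfdna_total, None)
            ntc = [
                (0, 0, 0, n_drop) for _ in range(config.n_ntc_wells)
            ]
            add_wells(pid, tp, "plasma", "no_template_control", "N1", ntc,
                      plasma_ml, None, None)
            tp_record["plasma"] = {
                "true_mutant_copies_per_ml": burden[tp],
                "true_mutant_conc": mut_conc,
                "true_wildtype_conc": wt_conc,
                "cfdna_ng_total": cfdna_total,
                "true_vaf": mut_conc / (mut_conc + wt_conc)
                if mut_conc + wt_conc > 0
                else None,
                "realized_mutant_droplets": realized,
                "false_positive_droplets": n_fp,
                "germline_mutant_droplets": g_realized,
                "true_positive": realized >= 2,
            }

            # ---- PBMC (CTC) ----
            ml_blood = config.ml_blood_pbmc
            cells = int(rng.poisson(ctc_rate[tp] * ml_blood))
            copies_eluate = (
                DEFAULT_CALIBRATION.slope * cells + DEFAULT_CALIBRATION.intercept
            )
            if config.ctc_copies_noise_sd > 0:
                copies_eluate += rng.normal(0.0, config.ctc_copies_noise_sd)
            copies_eluate = max(copies_eluate, 0.0)
            remaining = config.pbmc_millions * 1e6 / 10**config.depletion_log10
            wt_conc_c = remaining / total_reaction_ul  # one GE per residual cell
            mut_conc_c = copies_eluate / total_reaction_ul
            p_wt_c = _wt_occupancy(wt_conc_c, vd)
            c_wells, c_realized, c_fp = _simulate_replicate(
                rng, mut_conc_c, p_wt_c, n_wells, n_drop, vd,
                config.false_positive_droplet_rate,
            )
            add_wells(pid, tp, "pbmc", "sample", "R1", c_wells,
                      config.pbmc_millions, None, ml_blood)
            g_mut_conc_c = config.chip_vaf * wt_conc_c if chip else 0.0
            gc_wells, gc_realized, _ = _simulate_replicate(
                rng, g_mut_conc_c, p_wt_c, n_wells, n_drop, vd,
                config.false_positive_droplet_rate,
            )
            add_wells(pid, tp, "pbmc", "germline_control", "G1", gc_wells,
                      config.pbmc_millions, None, ml_blood)
            add_wells(pid, tp, "pbmc", "no_template_control", "N1",
                      [(0, 0, 0, n_drop) for _ in range(config.n_ntc_wells)],
                      config.pbmc_millions, None, ml_blood)
            tp_record["pbmc"] = {
                "true_cells": cells,
                "true_ctc_per_ml": cells / ml_blood,
                "true_mutant_copies_eluate": copies_eluate,
                "true_mutant_conc": mut_conc_c,
                "realized_mutant_droplets": c_realized,
                "false_positive_droplets": c_fp,
                "germline_mutant_droplets": gc_realized,
                "true_positive": c_realized >= 2,
            }

            tp_record["mrd_true"] = bool(
                tp_record["plasma"]["true_positive"]
                or tp_record["pbmc"]["true_positive"]
            )
            tp_truth[tp] = tp_record

        # relapse: MRD carriers relapse with a constant monthly hazard,
        # censored at the follow-up horizon
        relapse_months = None
        if mrd_carrier and config.relapse_hazard_given_mrd_positive > 0:
            t_rel = float(
                rng.exponential(1.0 / config.relapse_hazard_given_mrd_positive)
            )
            first_pos = config.timepoint_months["post_surgery"]
            cand = first_pos + t_rel
            if cand <= config.max_followup_months:
                relapse_months = round(cand, 2)

        months = config.timepoint_months
        sheet_rows.append(
            {
                "patient_id": pid,
                "subtype": subtype,
                "nodal_status": nodal,
                "pcr": "yes" if pcr else "no",
                "high_risk": "yes" if high_risk else "no",
                "relapse_months_from_surgery": ""
                if relapse_months is None
                else relapse_months,
                "months_pre_treatment": months["pre_treatment"],
                "months_post_nac": months["post_nac"],
                "months_post_surgery": months["post_surgery"],
                "months_follow_up": months["follow_up"] if high_risk else "",
            }
        )
        truth_patients[pid] = {
            "pcr": pcr,
            "chip": chip,
            "high_risk": high_risk,
            "mrd_carrier": mrd_carrier,
            "pre_burden_copies_per_ml": pre_burden,
            "relapse_months_from_surgery": relapse_months,
            "timepoints": tp_truth,
        }

    spikein = simulate_spikein(
        cells_levels=[64, 128], noise_sd=0.2, n_reps=3, seed=rng
    )
    cfg = asdict(config)
    ground_truth = {"config": cfg, "patients": truth_patients}

    wells_df = pd.DataFrame(well_rows, columns=WELL_TABLE_COLUMNS)
    sheet_df = pd.DataFrame(sheet_rows)
    return SimulatedCohort(
        wells=wells_df,
        sample_sheet=sheet_df,
        spikein=spikein,
        ground_truth=ground_truth,
    )
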