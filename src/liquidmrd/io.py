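"""File formats, run configuration and the end-to-end pipeline.

Inputs are comma-separated (well table, sample sheet, spike-in table);
outputs are tab-separated tables plus JSON reports validated against the
pydantic models in :mod:`liquidmrd.reports`. Every input row is accounted for
in the run log as used, rejected or excluded.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calling, ctc, ddpcr, mrd, response
from .ddpcr import DropletWellRecord, ReplicateSpec, SampleType, Timepoint, WellRole
from .reports import (
    CohortSummary,
    ModelReport,
    MrdReport,
    PatientMrd,
    TimepointStatus,
)

__all__ = [
    "RunConfig",
    "WellTableError",
    "load_well_table",
    "load_sample_sheet",
    "load_spikein_table",
    "quantify_and_call",
    "build_mrd_report",
    "run_pipeline",
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

TIMEPOINT_ORDER = ["pre_treatment", "post_nac", "post_surgery", "follow_up"]


class WellTableError(ValueError):
    """Schema or row-level failure while reading a well table."""


@dataclass
class RunConfig:
    """End-to-end run configuration; flags mirror these fields in the CLI."""

    well_table: Path
    sample_sheet: Path | None = None
    spikein_table: Path | None = None
    output_dir: Path = Path("liquidmrd_out")
    droplet_volume: float = ddpcr.DEFAULT_DROPLET_VOLUME_NL
    elution_volume: float = ddpcr.DEFAULT_ELUTION_VOLUME_UL
    min_fam_droplets: int = calling.DEFAULT_MIN_FAM_DROPLETS
    ci_alpha: float = 0.05
    model_mode: str = "best"  # one selection mode, or "best" across all
    covariates: list[str] = field(default_factory=list)
    exclude_patients: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.well_table = Path(self.well_table)
        self.output_dir = Path(self.output_dir)
        if self.sample_sheet is not None:
            self.sample_sheet = Path(self.sample_sheet)
        if self.spikein_table is not None:
            self.spikein_table = Path(self.spikein_table)
        if self.droplet_volume <= 0 or self.elution_volume <= 0:
            raise ValueError("volumes must be > 0")
        if self.min_fam_droplets < 1:
            raise ValueError("min_fam_droplets must be >= 1")
        if not 0 < self.ci_alpha < 1:
            raise ValueError("ci_alpha must be in (0, 1)")
        if self.model_mode not in ("best", *response.SELECTION_MODES):
            raise ValueError(f"unknown model_mode {self.model_mode!r}")


def _parse_count(value: str, column: str, line: int) -> int:
    try:
        n = int(value)
    except (TypeError, ValueError):
        raise WellTableError(
            f"line {line}: non-numeric count in column {column!r}: {value!r}"
        ) from None
    if n < 0:
        raise WellTableError(f"line {line}: negative count in column {column!r}")
    return n


def _parse_float(value: str, column: str, line: int) -> float | None:
    if value is None or value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise WellTableError(
            f"line {line}: non-numeric value in column {column!r}: {value!r}"
        ) from None


def load_well_table(
    path: Path,
) -> tuple[list[DropletWellRecord], dict[tuple, ReplicateSpec]]:
    """Read and validate a well table CSV.

    Returns the validated records plus a replicate-spec index keyed by
    ``(patient_id, timepoint, sample_type, role, replicate_id)``. Rows failing
    the schema raise :class:`WellTableError` with the offending line number.
    """
    records: list[DropletWellRecord] = []
    specs: dict[tuple, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in WELL_TABLE_COLUMNS if c not in header]
        if missing:
            raise WellTableError(f"missing column(s): {', '.join(missing)}")
        for line, row in enumerate(reader, start=2):
            try:
                record = DropletWellRecord(
                    patient_id=row["patient_id"],
                    timepoint=Timepoint(row["timepoint"]),
                    sample_type=SampleType(row["sample_type"]),
                    assay_id=row["assay_id"],
                    well_id=row["well_id"],
                    role=WellRole(row["role"]),
                    replicate_id=row["replicate_id"],
                    n_fam_only=_parse_count(row["n_fam_only"], "n_fam_only", line),
                    n_vic_only=_parse_count(row["n_vic_only"], "n_vic_only", line),
                    n_double_pos=_parse_count(
                        row["n_double_pos"], "n_double_pos", line
                    ),
                    n_empty=_parse_count(row["n_empty"], "n_empty", line),
                )
            except WellTableError:
                raise
            except ValueError as exc:
                raise WellTableError(f"line {line}: {exc}") from None
            records.append(record)
            key = (
                record.patient_id,
                record.timepoint.value,
                record.sample_type.value,
                record.role.value,
                record.replicate_id,
            )
            spec = specs.setdefault(
                key,
                {
                    "material_amount": _parse_float(
                        row["material_amount"], "material_amount", line
                    ),
                    "elution_volume": _parse_float(
                        row["elution_volume_ul"], "elution_volume_ul", line
                    ),
                    "cfdna_mass": _parse_float(row["cfdna_ng"], "cfdna_ng", line),
                    "ml_blood": _parse_float(row["ml_blood"], "ml_blood", line),
                    "wells": [],
                },
            )
            spec["wells"].append(record.well_id)
    spec_index = {
        key: ReplicateSpec(
            replicate_id=key[-1],
            material_amount=s["material_amount"] or 1.0,
            elution_volume=s["elution_volume"]
            or ddpcr.DEFAULT_ELUTION_VOLUME_UL,
            cfdna_mass=s["cfdna_mass"],
            ml_blood=s["ml_blood"],
            wells=tuple(s["wells"]),
        )
        for key, s in specs.items()
    }
    return records, spec_index


def load_sample_sheet(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise WellTableError("sample sheet missing column patient_id")
    return df.set_index("patient_id")


def load_spikein_table(path: Path) -> ctc.CtcCalibration:
    df = pd.read_csv(path)
    needed = {"spiked_cells", "replicate_index", "mutant_copies_eluate"}
    missing = needed - set(df.columns)
    if missing:
        raise WellTableError(
            f"spike-in table missing column(s): {', '.join(sorted(missing))}"
        )
    records = [
        ctc.SpikeInRecord(
            spiked_cells=int(r.spiked_cells),
            mutant_copies_eluate=float(r.mutant_copies_eluate),
            replicate_index=int(r.replicate_index),
        )
        for r in df.itertuples()
    ]
    return ctc.fit_ctc_calibration(records)


def _group_key(r: DropletWellRecord) -> tuple:
    return (r.patient_id, r.timepoint.value, r.sample_type.value)


def quantify_and_call(
    records: list[DropletWellRecord],
    spec_index: dict[tuple, ReplicateSpec],
    calibration: ctc.CtcCalibration = ctc.DEFAULT_CALIBRATION,
    droplet_volume: float = ddpcr.DEFAULT_DROPLET_VOLUME_NL,
    min_fam_droplets: int = calling.DEFAULT_MIN_FAM_DROPLETS,
    log: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify and call every sample-timepoint.

    Returns ``(quant_table, call_table)``, one row per
    patient x timepoint x sample_type. Quantification merges the wells of an
    initially negative replicate with a later positive one, following the
    combine-for-quantification rule; otherwise the positive replicates (or
    all replicates, when none is positive) are pooled.
    """
    by_sample: dict[tuple, list[DropletWellRecord]] = {}
    for r in records:
        by_sample.setdefault(_group_key(r), []).append(r)

    quant_rows, call_rows = [], []
    for (pid, tp, stype), wells in sorted(by_sample.items()):
        sample_wells = [w for w in wells if w.role is WellRole.SAMPLE]
        control_wells = [w for w in wells if w.role is not WellRole.SAMPLE]

        # replicate-level pooled FAM totals, in replicate-id order
        rep_ids = sorted({w.replicate_id for w in sample_wells})
        rep_wells = {
            rid: [w for w in sample_wells if w.replicate_id == rid]
            for rid in rep_ids
        }
        fam_totals = [
            sum(w.fam_positive for w in rep_wells[rid]) for rid in rep_ids
        ]
        fam_only_totals = [
            sum(w.n_fam_only for w in rep_wells[rid]) for rid in rep_ids
        ]

        control_statuses = []
        germline_fam = 0
        for rid in sorted({w.replicate_id for w in control_wells}):
            cw = [w for w in control_wells if w.replicate_id == rid]
            pooled_fam = sum(w.fam_positive for w in cw)
            if cw[0].role is WellRole.GERMLINE_CONTROL:
                germline_fam += pooled_fam
            control_statuses.append(
                calling.call_replicate(pooled_fam, min_fam_droplets)
            )

        status = calling.call_sample(
            fam_totals,
            control_statuses,
            replicate_fam_only_counts=fam_only_totals,
            min_fam_droplets=min_fam_droplets,
        )
        chip = calling.flag_chip(status, germline_fam, min_fam_droplets)

        # wells used for quantification
        if not sample_wells:
            continue
        rep_calls = [
            calling.call_replicate(f, min_fam_droplets) for f in fam_totals
        ]
        if status.is_positive and status.combine_wells_for_quant:
            used_ids = rep_ids
        elif status.is_positive:
            used_ids = [
                rid
                for rid, c in zip(rep_ids, rep_calls)
                if c.is_positive
            ]
        else:
            used_ids = rep_ids
        used_wells = [w for rid in used_ids for w in rep_wells[rid]]
        used_specs = [
            spec_index[(pid, tp, stype, "sample", rid)] for rid in used_ids
        ]
        material = sum(s.material_amount for s in used_specs)
        cfdna = (
            sum(s.cfdna_mass for s in used_specs)
            if all(s.cfdna_mass is not None for s in used_specs)
            else None
        )
        ml_blood = used_specs[0].ml_blood
        merged_spec = ReplicateSpec(
            replicate_id="+".join(used_ids),
            material_amount=material,
            elution_volume=used_specs[0].elution_volume,
            cfdna_mass=cfdna,
            ml_blood=ml_blood,
        )
        q = ddpcr.quantify_replicate(
            used_wells, merged_spec, droplet_volume=droplet_volume
        )

        ctc_total_cells = ctc_per_ml = None
        if stype == "pbmc":
            ctc_total_cells = ctc.ctc_total(q.mutant_copies_eluate, calibration)
            if ml_blood:
                ctc_per_ml = ctc.ctc_per_ml_blood(ctc_total_cells, ml_blood)

        quant_rows.append(
            {
                "patient_id": pid,
                "timepoint": tp,
                "sample_type": stype,
                "n_wells": q.n_wells,
                "mutant_conc": q.mutant_conc,
                "wildtype_conc": q.wildtype_conc,
                "vaf": q.vaf,
                "mutant_copies_eluate": q.mutant_copies_eluate,
                "mutant_copies_per_ml": q.mutant_copies_per_ml,
                "mge": q.mge,
                "max_sensitivity": q.max_sensitivity,
                "ctc_total": ctc_total_cells,
                "ctc_per_ml_blood": ctc_per_ml,
            }
        )
        call_rows.append(
            {
                "patient_id": pid,
                "timepoint": tp,
                "sample_type": stype,
                "status": status.status.value,
                "reason": status.reason.value,
                "low_positive_flag": status.low_positive_flag,
                "only_double_positives": status.only_double_positives,
                "chip_flag": chip,
                "combine_wells_for_quant": status.combine_wells_for_quant,
            }
        )
    if log is not None:
        log.append(
            f"quantify_and_call: {len(records)} wells in, "
            f"{len(quant_rows)} sample-timepoints quantified"
        )
    return pd.DataFrame(quant_rows), pd.DataFrame(call_rows)


def _status_from_row(row) -> calling.Status:
    return calling.Status(row["status"])


def build_mrd_report(
    call_table: pd.DataFrame,
    sample_sheet: pd.DataFrame | None,
    ci_alpha: float = 0.05,
) -> MrdReport:
    """Assemble per-patient timelines, trajectory groups and lead times."""
    months_cols = {
        "pre_treatment": "months_pre_treatment",
        "post_nac": "months_post_nac",
        "post_surgery": "months_post_surgery",
        "follow_up": "months_follow_up",
    }
    default_months = {
        "pre_treatment": -6.0,
        "post_nac": -0.5,
        "post_surgery": 1.15,
        "follow_up": 12.0,
    }

    patients: list[PatientMrd] = []
    for pid, sub in call_table.groupby("patient_id"):
        relapse = None
        pcr = None
        months_map = dict(default_months)
        if sample_sheet is not None and pid in sample_sheet.index:
            row = sample_sheet.loc[pid]
            rel = row.get("relapse_months_from_surgery")
            if rel is not None and str(rel) not in ("", "nan"):
                relapse = float(rel)
            pcr_val = row.get("pcr")
            if pcr_val is not None and str(pcr_val) not in ("", "nan"):
                pcr = str(pcr_val).lower() in ("yes", "true", "1")
            for tp, col in months_cols.items():
                v = row.get(col)
                if v is not None and str(v) not in ("", "nan"):
                    months_map[tp] = float(v)

        tps: list[TimepointStatus] = []
        tl_points: list[mrd.TimepointResult] = []
        for tp in TIMEPOINT_ORDER:
            tp_rows = sub[sub["timepoint"] == tp]
            if tp_rows.empty:
                continue
            statuses = {}
            for _, r in tp_rows.iterrows():
                statuses[r["sample_type"]] = _status_from_row(r)
            combined = mrd.timepoint_mrd(*statuses.values())
            tps.append(
                TimepointStatus(
                    timepoint=tp,
                    months_from_surgery=months_map[tp],
                    ctdna_status=statuses.get("plasma", calling.Status.INCONCLUSIVE).value
                    if "plasma" in statuses
                    else None,
                    ctc_status=statuses["pbmc"].value if "pbmc" in statuses else None,
                    combined_status=combined.value,
                )
            )
            tl_points.append(
                mrd.TimepointResult(
                    months_from_surgery=months_map[tp],
                    ctdna_status=calling.CallStatus(
                        level=calling.CallLevel.SAMPLE,
                        status=statuses["plasma"],
                        reason=calling.Reason.GE2_FAM_SINGLE_REPLICATE
                        if statuses["plasma"] is calling.Status.POSITIVE
                        else calling.Reason.LT2_FAM_TOTAL,
                    )
                    if "plasma" in statuses
                    else None,
                    ctc_status=calling.CallStatus(
                        level=calling.CallLevel.SAMPLE,
                        status=statuses["pbmc"],
                        reason=calling.Reason.GE2_FAM_SINGLE_REPLICATE
                        if statuses["pbmc"] is calling.Status.POSITIVE
                        else calling.Reason.LT2_FAM_TOTAL,
                    )
                    if "pbmc" in statuses
                    else None,
                )
            )

        timeline = mrd.PatientTimeline(
            patient_id=pid,
            timepoints=tl_points,
            pcr_status=pcr,
            relapse_months_from_surgery=relapse,
        )
        group = mrd.classify_trajectory(timeline)
        lead = None
        detection_after = False
        if relapse is not None:
            positives = [
                t.months_from_surgery
                for t in timeline.follow_up_points()
                if t.combined is calling.Status.POSITIVE
            ]
            if positives:
                lt = mrd.lead_time(relapse, min(positives))
                lead = lt.months
                detection_after = lt.detection_after_relapse
        patients.append(
            PatientMrd(
                patient_id=pid,
                pcr=pcr,
                relapse_months_from_surgery=relapse,
                trajectory_group=group.value,
                lead_time_months=lead,
                detection_after_relapse=detection_after,
                timepoints=tps,
            )
        )

    # cohort summaries: detection rates per timepoint + post-NAC blood RD
    # sensitivity against tissue residual disease (non-pCR patients)
    rates = {}
    for tp in TIMEPOINT_ORDER:
        combined = [
            t for p in patients for t in p.timepoints if t.timepoint == tp
        ]
        conclusive = [t for t in combined if t.combined_status != "inconclusive"]
        if conclusive:
            pos = sum(t.combined_status == "positive" for t in conclusive)
            rates[tp] = mrd.detection_rate(pos, len(conclusive))
    diag = None
    with_pcr = [p for p in patients if p.pcr is not None]
    rd_patients = [p for p in with_pcr if p.pcr is False]
    if rd_patients:
        tp_count = 0
        fn_count = 0
        for p in rd_patients:
            post_nac = [t for t in p.timepoints if t.timepoint == "post_nac"]
            if not post_nac or post_nac[0].combined_status == "inconclusive":
                continue
            if post_nac[0].combined_status == "positive":
                tp_count += 1
            else:
                fn_count += 1
        if tp_count + fn_count > 0:
            d = mrd.diagnostic_performance(tp_count, fn_count, ci_alpha)
            diag = {
                "true_positives": d.true_positives,
                "false_negatives": d.false_negatives,
                "sensitivity_percent": d.sensitivity,
                "ci_low_percent": d.ci_low,
                "ci_high_percent": d.ci_high,
                "alpha": d.alpha,
            }
    summary = CohortSummary(
        n_patients=len(patients),
        detection_rate_percent_by_timepoint=rates,
        blood_rd_sensitivity=diag,
        trajectory_group_counts={
            g.value: sum(p.trajectory_group == g.value for p in patients)
            for g in mrd.TrajectoryGroup
        },
    )
    return MrdReport(patients=patients, cohort=summary)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run quantification, calling, MRD assembly and response modelling.

    Writes quant.tsv, calls.tsv, mrd_report.json, model_report.json and
    run.log under ``config.output_dir`` and returns their paths. Deterministic
    given identical inputs and seed.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"run_pipeline: seed={config.seed}"]

    records, spec_index = load_well_table(config.well_table)
    log.append(f"well table: {len(records)} rows loaded from {config.well_table}")

    sheet = None
    if config.sample_sheet is not None:
        sheet = load_sample_sheet(config.sample_sheet)
        log.append(f"sample sheet: {len(sheet)} patients")

    calibration = ctc.DEFAULT_CALIBRATION
    if config.spikein_table is not None:
        calibration = load_spikein_table(config.spikein_table)
        log.append(
            "spike-in calibration: slope=%.4f intercept=%.4f r2=%.4f"
            % (calibration.slope, calibration.intercept, calibration.r_squared)
        )
    else:
        log.append("spike-in calibration: published defaults")

    quant, calls = quantify_and_call(
        records,
        spec_index,
        calibration=calibration,
        droplet_volume=config.droplet_volume,
        min_fam_droplets=config.min_fam_droplets,
        log=log,
    )
    n_patients = quant["patient_id"].nunique() if len(quant) else 0
    log.append(f"patients quantified: {n_patients}")

    quant_path = out / "quant.tsv"
    calls_path = out / "calls.tsv"
    quant.to_csv(quant_path, sep="\t", index=False, float_format="%.6g")
    calls.to_csv(calls_path, sep="\t", index=False)

    report = build_mrd_report(calls, sheet, ci_alpha=config.ci_alpha)
    mrd_path = out / "mrd_report.json"
    mrd_path.write_text(report.model_dump_json(indent=2) + "\n", encoding="utf-8")

    # response model from plasma MGE at pre-treatment and post-NAC
    model_path = out / "model_report.json"
    model_report = None
    if sheet is not None and "pcr" in sheet.columns:
        inputs = []
        plasma = quant[quant["sample_type"] == "plasma"]
        for pid in sorted(plasma["patient_id"].unique()):
            if pid in config.exclude_patients:
                log.append(f"model: patient {pid} excluded by config")
                continue
            sub = plasma[plasma["patient_id"] == pid].set_index("timepoint")
            if (
                "pre_treatment" not in sub.index
                or "post_nac" not in sub.index
                or pid not in sheet.index
            ):
                log.append(f"model: patient {pid} lacks paired MGE, dropped")
                continue
            pre = sub.loc["pre_treatment", "mge"]
            post = sub.loc["post_nac", "mge"]
            if pd.isna(pre) or pd.isna(post):
                log.append(f"model: patient {pid} has undefined MGE, dropped")
                continue
            pcr_val = str(sheet.loc[pid, "pcr"]).lower() in ("yes", "true", "1")
            inputs.append(
                response.ModelInput(
                    patient_id=pid,
                    mge_pre=float(pre),
                    mge_post=float(post),
                    outcome=pcr_val,
                )
            )
        outcomes = {m.outcome for m in inputs}
        if len(inputs) >= 6 and len(outcomes) == 2:
            if config.model_mode == "best":
                fitted = response.build_final_model(inputs)
            else:
                fitted = response.select_model(inputs, mode=config.model_mode)
            model_report = ModelReport(
                mode=fitted.mode,
                selected_predictors=list(fitted.selected_predictors),
                coefficients=fitted.coefficients,
                auc=fitted.auc,
                auc_loocv=fitted.auc_loocv,
                delong_p=fitted.delong_p,
                youden_cutoff=fitted.youden_cutoff,
                sensitivity_at_cutoff=fitted.sensitivity_at_cutoff,
                specificity_at_cutoff=fitted.specificity_at_cutoff,
                n_patients=len(inputs),
                intercept_only_flag=fitted.intercept_only_flag,
                separation_flag=fitted.separation_flag,
            )
            log.append(
                f"model: {fitted.mode} selected {fitted.selected_predictors}, "
                f"AUC={fitted.auc:.3f}"
            )
        else:
            log.append(
                f"model: skipped ({len(inputs)} usable patients, "
                f"{len(outcomes)} outcome classes)"
            )
    if model_report is not None:
        model_path.write_text(
            model_report.model_dump_json(indent=2) + "\n", encoding="utf-8"
        )

    log_path = out / "run.log"
    log_path.write_text("\n".join(log) + "\n", encoding="utf-8")

    paths = {
        "quant": quant_path,
        "calls": calls_path,
        "mrd_report": mrd_path,
        "log": log_path,
    }
    if model_report is not None:
        paths["model_report"] = model_path
    return paths


def write_cohort(cohort, outdir: Path) -> dict[str, Path]:
    """Write a simulated cohort in the pipeline's input dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wells = outdir / "wells.csv"
    sheet = outdir / "sample_sheet.csv"
    spike = outdir / "spikein.csv"
    truth = outdir / "ground_truth.json"
    cohort.wells.to_csv(wells, index=False)
    cohort.sample_sheet.to_csv(sheet, index=False)
    cohort.spikein.to_csv(spike, index=False)
    truth.write_text(
        json.dumps(cohort.ground_truth, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return {
        "wells": wells,
        "sample_sheet": sheet,
        "spikein": spike,
        "ground_truth": truth,
    }
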