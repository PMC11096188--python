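"""Pydantic models for the JSON reports.

The JSON Schemas exported from these models are shipped under
``liquidmrd/schemas/`` and define the published report contract; writing a
report goes through model validation, so emitted files always conform.
"""

from __future__ import annotations

from pydantic import BaseModel, Field


class TimepointStatus(BaseModel):
    timepoint: str
    months_from_surgery: float
    ctdna_status: str | None = None
    ctc_status: str | None = None
    combined_status: str


class PatientMrd(BaseModel):
    patient_id: str
    pcr: bool | None = None
    relapse_months_from_surgery: float | None = None
    trajectory_group: str
    lead_time_months: float | None = None
    detection_after_relapse: bool = False
    timepoints: list[TimepointStatus]


class CohortSummary(BaseModel):
    n_patients: int = Field(ge=0)
    detection_rate_percent_by_timepoint: dict[str, float]
    blood_rd_sensitivity: dict | None = None
    trajectory_group_counts: dict[str, int]


class MrdReport(BaseModel):
    patients: list[PatientMrd]
    cohort: CohortSummary


class ModelReport(BaseModel):
    mode: str
    selected_predictors: list[str]
    coefficients: dict[str, float]
    auc: float = Field(ge=0, le=1)
    auc_loocv: float | None = Field(default=None, ge=0, le=1)
    delong_p: float | None = Field(default=None, ge=0, le=1)
    youden_cutoff: float = Field(ge=0, le=1)
    sensitivity_at_cutoff: float = Field(ge=0, le=1)
    specificity_at_cutoff: float = Field(ge=0, le=1)
    n_patients: int = Field(ge=0)
    intercept_only_flag: bool = False
    separation_flag: bool = False
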