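{
  "$defs": {
    "CohortSummary": {
      "properties": {
        "n_patients": {
          "minimum": 0,
          "title": "N Patients",
          "type": "integer"
        },
        "detection_rate_percent_by_timepoint": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Detection Rate Percent By Timepoint",
          "type": "object"
        },
        "blood_rd_sensitivity": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Blood Rd Sensitivity"
        },
        "trajectory_group_counts": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Trajectory Group Counts",
          "type": "object"
        }
      },
      "required": [
        "n_patients",
        "detection_rate_percent_by_timepoint",
        "trajectory_group_counts"
      ],
      "title": "CohortSummary",
      "type": "object"
    },
    "PatientMrd": {
      "properties": {
        "patient_id": {
          "title": "Patient Id",
          "type": "string"
        },
        "pcr": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Pcr"
        },
        "relapse_months_from_surgery": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Relapse Months From Surgery"
        },
        "trajectory_group": {
          "title": "Trajectory Group",
          "type": "string"
        },
        "lead_time_months": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Lead Time Months"
        },
        "detection_after_relapse": {
          "default": false,
          "title": "Detection After Relapse",
          "type": "boolean"
        },
        "timepoints": {
          "items": {
            "$ref": "#/$defs/TimepointStatus"
          },
          "title": "Timepoints",
          "type": "array"
        }
      },
      "required": [
        "patient_id",
        "trajectory_group",
        "timepoints"
      ],
      "title": "PatientMrd",
      "type": "object"
    },
    "TimepointStatus": {
      "properties": {
        "timepoint": {
          "title": "Timepoint",
          "type": "string"
        },
        "months_from_surgery": {
          "title": "Months From Surgery",
          "type": "number"
        },
        "ctdna_status": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ctdna Status"
        },
        "ctc_status": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ctc Status"
        },
        "combined_status": {
          "title": "Combined Status",
          "type": "string"
        }
      },
      "required": [
        "timepoint",
        "months_from_surgery",
        "combined_status"
      ],
      "title": "TimepointStatus",
      "type": "object"
    }
  },
  "properties": {
    "patients": {
      "items": {
        "$ref": "#/$defs/PatientMrd"
      },
      "title": "Patients",
      "type": "array"
    },
    "cohort": {
      "$ref": "#/$defs/CohortSummary"
    }
  },
  "required": [
    "patients",
    "cohort"
  ],
  "title": "MrdReport",
  "type": "object"
}
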