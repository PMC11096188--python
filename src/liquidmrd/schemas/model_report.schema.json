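{
  "properties": {
    "mode": {
      "title": "Mode",
      "type": "string"
    },
    "selected_predictors": {
      "items": {
        "type": "string"
      },
      "title": "Selected Predictors",
      "type": "array"
    },
    "coefficients": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Coefficients",
      "type": "object"
    },
    "auc": {
      "maximum": 1,
      "minimum": 0,
      "title": "Auc",
      "type": "number"
    },
    "auc_loocv": {
      "anyOf": [
        {
          "maximum": 1,
          "minimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Auc Loocv"
    },
    "delong_p": {
      "anyOf": [
        {
          "maximum": 1,
          "minimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Delong P"
    },
    "youden_cutoff": {
      "maximum": 1,
      "minimum": 0,
      "title": "Youden Cutoff",
      "type": "number"
    },
    "sensitivity_at_cutoff": {
      "maximum": 1,
      "minimum": 0,
      "title": "Sensitivity At Cutoff",
      "type": "number"
    },
    "specificity_at_cutoff": {
      "maximum": 1,
      "minimum": 0,
      "title": "Specificity At Cutoff",
      "type": "number"
    },
    "n_patients": {
      "minimum": 0,
      "title": "N Patients",
      "type": "integer"
    },
    "intercept_only_flag": {
      "default": false,
      "title": "Intercept Only Flag",
      "type": "boolean"
    },
    "separation_flag": {
      "default": false,
      "title": "Separation Flag",
      "type": "boolean"
    }
  },
  "required": [
    "mode",
    "selected_predictors",
    "coefficients",
    "auc",
    "youden_cutoff",
    "sensitivity_at_cutoff",
    "specificity_at_cutoff",
    "n_patients"
  ],
  "title": "ModelReport",
  "type": "object"
}
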