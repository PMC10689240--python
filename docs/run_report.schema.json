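{
  "$defs": {
    "StimulusSummary": {
      "properties": {
        "mean_fz_investigation": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Mean Fz Investigation"
        },
        "introduction_peak": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Introduction Peak"
        },
        "session_mean_fz": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Session Mean Fz"
        }
      },
      "title": "StimulusSummary",
      "type": "object"
    }
  },
  "description": "Machine-readable run report with provenance.",
  "properties": {
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "config_hash": {
      "title": "Config Hash",
      "type": "string"
    },
    "stimuli": {
      "additionalProperties": {
        "$ref": "#/$defs/StimulusSummary"
      },
      "title": "Stimuli",
      "type": "object"
    },
    "preference_indices": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Preference Indices",
      "type": "object"
    },
    "percent_responsive_male": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Percent Responsive Male"
    },
    "mean_latency_s": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Mean Latency S"
    },
    "mean_bout_duration_s": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Mean Bout Duration S"
    }
  },
  "required": [
    "package_version",
    "seed",
    "config_hash"
  ],
  "title": "RunReport",
  "type": "object"
}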