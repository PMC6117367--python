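{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "predscan pipeline configuration",
  "type": "object",
  "required": [
    "biomarker"
  ],
  "properties": {
    "biomarker": {
      "type": "string"
    },
    "seed": {
      "type": "integer"
    },
    "adjust": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "mcmc": {
      "type": "object",
      "properties": {
        "n_steps": {
          "type": "integer",
          "minimum": 2
        },
        "n_burn": {
          "type": "integer",
          "minimum": 0
        },
        "thin": {
          "type": "integer",
          "minimum": 1
        }
      }
    },
    "thresholds": {
      "type": "object",
      "properties": {
        "alpha": {
          "type": "number",
          "exclusiveMinimum": 0,
          "maximum": 1
        },
        "fdr_q": {
          "type": "number",
          "exclusiveMinimum": 0,
          "maximum": 1
        },
        "min_cases": {
          "type": "integer",
          "minimum": 1
        },
        "min_site_cases": {
          "type": "integer",
          "minimum": 0
        },
        "rank_cutoff": {
          "type": "integer",
          "minimum": 1
        },
        "p_filter": {
          "type": "number",
          "exclusiveMinimum": 0,
          "maximum": 1
        },
        "n_biomarkers": {
          "type": "integer",
          "minimum": 1
        }
      }
    },
    "fdr_family": {
      "enum": [
        "per_biomarker",
        "global"
      ]
    },
    "simulate": {
      "type": "object"
    },
    "inputs": {
      "type": "object"
    }
  }
}
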