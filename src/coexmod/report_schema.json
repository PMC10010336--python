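{
  "$defs": {
    "ModuleSurvival": {
      "properties": {
        "module": {
          "title": "Module",
          "type": "string"
        },
        "logrank_statistic": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Logrank Statistic"
        },
        "logrank_p": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Logrank P"
        },
        "median_survival": {
          "additionalProperties": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "null"
              }
            ]
          },
          "title": "Median Survival",
          "type": "object"
        }
      },
      "required": [
        "module"
      ],
      "title": "ModuleSurvival",
      "type": "object"
    }
  },
  "description": "Machine-readable run summary written as report.json.",
  "properties": {
    "version": {
      "title": "Version",
      "type": "string"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    },
    "seed_streams": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Seed Streams",
      "type": "object"
    },
    "n_proteins_input": {
      "title": "N Proteins Input",
      "type": "integer"
    },
    "n_samples": {
      "title": "N Samples",
      "type": "integer"
    },
    "n_proteins_complete": {
      "title": "N Proteins Complete",
      "type": "integer"
    },
    "n_proteins_selected": {
      "title": "N Proteins Selected",
      "type": "integer"
    },
    "chosen_beta": {
      "title": "Chosen Beta",
      "type": "integer"
    },
    "scale_free_r2": {
      "title": "Scale Free R2",
      "type": "number"
    },
    "module_sizes": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Module Sizes",
      "type": "object"
    },
    "n_unassigned": {
      "title": "N Unassigned",
      "type": "integer"
    },
    "sample_cluster_sizes": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "integer"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Sample Cluster Sizes"
    },
    "trait_association": {
      "anyOf": [
        {
          "items": {
            "additionalProperties": true,
            "type": "object"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Trait Association"
    },
    "module_survival": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/ModuleSurvival"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Module Survival"
    },
    "best_module": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Best Module"
    },
    "n_de_significant": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "N De Significant"
    },
    "top_enriched_sets": {
      "anyOf": [
        {
          "items": {
            "additionalProperties": true,
            "type": "object"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Top Enriched Sets"
    }
  },
  "required": [
    "version",
    "parameters",
    "seed_streams",
    "n_proteins_input",
    "n_samples",
    "n_proteins_complete",
    "n_proteins_selected",
    "chosen_beta",
    "scale_free_r2",
    "module_sizes",
    "n_unassigned"
  ],
  "title": "RunReport",
  "type": "object"
}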