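{
  "$defs": {
    "DatasetSummary": {
      "properties": {
        "n_species": {
          "title": "N Species",
          "type": "integer"
        },
        "n_genes": {
          "title": "N Genes",
          "type": "integer"
        },
        "na_fraction": {
          "title": "Na Fraction",
          "type": "number"
        },
        "has_branch_lengths": {
          "title": "Has Branch Lengths",
          "type": "boolean"
        },
        "warnings": {
          "items": {
            "type": "string"
          },
          "title": "Warnings",
          "type": "array"
        }
      },
      "required": [
        "n_species",
        "n_genes",
        "na_fraction",
        "has_branch_lengths"
      ],
      "title": "DatasetSummary",
      "type": "object"
    },
    "EventEntry": {
      "properties": {
        "event_id": {
          "title": "Event Id",
          "type": "integer"
        },
        "parent": {
          "title": "Parent",
          "type": "string"
        },
        "child": {
          "title": "Child",
          "type": "string"
        },
        "type": {
          "title": "Type",
          "type": "string"
        },
        "genes": {
          "items": {
            "type": "string"
          },
          "title": "Genes",
          "type": "array"
        }
      },
      "required": [
        "event_id",
        "parent",
        "child",
        "type",
        "genes"
      ],
      "title": "EventEntry",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "package": {
          "default": "ylinkage",
          "title": "Package",
          "type": "string"
        },
        "version": {
          "title": "Version",
          "type": "string"
        },
        "schema_version": {
          "default": "1.0",
          "title": "Schema Version",
          "type": "string"
        },
        "config": {
          "additionalProperties": true,
          "title": "Config",
          "type": "object"
        },
        "timestamp": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Timestamp"
        }
      },
      "required": [
        "version",
        "config"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "RateEntry": {
      "properties": {
        "n": {
          "title": "N",
          "type": "integer"
        },
        "exposure": {
          "title": "Exposure",
          "type": "number"
        },
        "rate": {
          "title": "Rate",
          "type": "number"
        },
        "ci": {
          "items": {
            "type": "number"
          },
          "title": "Ci",
          "type": "array"
        },
        "conf": {
          "title": "Conf",
          "type": "number"
        },
        "method": {
          "title": "Method",
          "type": "string"
        }
      },
      "required": [
        "n",
        "exposure",
        "rate",
        "ci",
        "conf",
        "method"
      ],
      "title": "RateEntry",
      "type": "object"
    },
    "ReconstructionEntry": {
      "properties": {
        "gene": {
          "title": "Gene",
          "type": "string"
        },
        "min_cost": {
          "title": "Min Cost",
          "type": "number"
        },
        "node_states": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Node States",
          "type": "object"
        },
        "changes": {
          "items": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "title": "Changes",
          "type": "array"
        }
      },
      "required": [
        "gene",
        "min_cost",
        "node_states",
        "changes"
      ],
      "title": "ReconstructionEntry",
      "type": "object"
    },
    "TestEntry": {
      "properties": {
        "p": {
          "title": "P",
          "type": "number"
        },
        "method": {
          "title": "Method",
          "type": "string"
        },
        "statistic": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Statistic"
        },
        "table": {
          "anyOf": [
            {
              "items": {
                "type": "integer"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Table"
        }
      },
      "required": [
        "p",
        "method"
      ],
      "title": "TestEntry",
      "type": "object"
    }
  },
  "description": "Full output of one pipeline run.",
  "properties": {
    "dataset": {
      "$ref": "#/$defs/DatasetSummary"
    },
    "mode": {
      "title": "Mode",
      "type": "string"
    },
    "reconstructions": {
      "items": {
        "$ref": "#/$defs/ReconstructionEntry"
      },
      "title": "Reconstructions",
      "type": "array"
    },
    "events": {
      "items": {
        "$ref": "#/$defs/EventEntry"
      },
      "title": "Events",
      "type": "array"
    },
    "events_nearly_all": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/EventEntry"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Events Nearly All"
    },
    "n_independent_events": {
      "title": "N Independent Events",
      "type": "integer"
    },
    "loss_rate": {
      "anyOf": [
        {
          "$ref": "#/$defs/RateEntry"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "incorporation_rate": {
      "anyOf": [
        {
          "$ref": "#/$defs/RateEntry"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "reacquisition": {
      "anyOf": [
        {
          "$ref": "#/$defs/TestEntry"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "poisson_ratio": {
      "anyOf": [
        {
          "$ref": "#/$defs/TestEntry"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "dataset",
    "mode",
    "reconstructions",
    "events",
    "n_independent_events",
    "provenance"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
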