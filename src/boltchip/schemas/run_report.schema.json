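{
  "$defs": {
    "Recovery": {
      "properties": {
        "planted": {
          "title": "Planted",
          "type": "integer"
        },
        "called": {
          "title": "Called",
          "type": "integer"
        },
        "true_positive": {
          "title": "True Positive",
          "type": "integer"
        },
        "false_positive": {
          "title": "False Positive",
          "type": "integer"
        },
        "false_negative": {
          "title": "False Negative",
          "type": "integer"
        },
        "recall": {
          "title": "Recall",
          "type": "number"
        },
        "precision": {
          "title": "Precision",
          "type": "number"
        },
        "direction_errors": {
          "title": "Direction Errors",
          "type": "integer"
        }
      },
      "required": [
        "planted",
        "called",
        "true_positive",
        "false_positive",
        "false_negative",
        "recall",
        "precision",
        "direction_errors"
      ],
      "title": "Recovery",
      "type": "object"
    },
    "StageCounts": {
      "properties": {
        "designed": {
          "title": "Designed",
          "type": "integer"
        },
        "filtered": {
          "title": "Filtered",
          "type": "integer"
        },
        "called": {
          "title": "Called",
          "type": "integer"
        }
      },
      "required": [
        "designed",
        "filtered",
        "called"
      ],
      "title": "StageCounts",
      "type": "object"
    },
    "Thresholds": {
      "properties": {
        "fc": {
          "default": 2.0,
          "title": "Fc",
          "type": "number"
        },
        "alpha_deg": {
          "default": 0.05,
          "title": "Alpha Deg",
          "type": "number"
        },
        "alpha_dmr_primary": {
          "default": 0.01,
          "title": "Alpha Dmr Primary",
          "type": "number"
        },
        "alpha_dmr_screen": {
          "default": 0.05,
          "title": "Alpha Dmr Screen",
          "type": "number"
        },
        "k_background": {
          "default": 2.6,
          "title": "K Background",
          "type": "number"
        },
        "rank_tolerance": {
          "default": 0.05,
          "title": "Rank Tolerance",
          "type": "number"
        },
        "locus_max_gap": {
          "default": 5000,
          "title": "Locus Max Gap",
          "type": "integer"
        },
        "locus_min_probes": {
          "default": 3,
          "title": "Locus Min Probes",
          "type": "integer"
        }
      },
      "title": "Thresholds",
      "type": "object"
    }
  },
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "parameters": {
      "$ref": "#/$defs/Thresholds"
    },
    "stages": {
      "items": {
        "type": "string"
      },
      "title": "Stages",
      "type": "array"
    },
    "counts": {
      "additionalProperties": {
        "$ref": "#/$defs/StageCounts"
      },
      "title": "Counts",
      "type": "object"
    },
    "n_dems": {
      "title": "N Dems",
      "type": "integer"
    },
    "dems_recovery_exact": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Dems Recovery Exact"
    },
    "expression_recovery": {
      "anyOf": [
        {
          "$ref": "#/$defs/Recovery"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "methylation_recovery": {
      "anyOf": [
        {
          "$ref": "#/$defs/Recovery"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "meth_expr_pearson_r": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Meth Expr Pearson R"
    },
    "meth_expr_spearman_rho": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Meth Expr Spearman Rho"
    },
    "mito_r_vs_s_p": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Mito R Vs S P"
    },
    "mito_coding_vs_noncoding_p": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Mito Coding Vs Noncoding P"
    },
    "mito_loci_spans_bp": {
      "items": {
        "type": "integer"
      },
      "title": "Mito Loci Spans Bp",
      "type": "array"
    },
    "phenotype_classes": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Phenotype Classes",
      "type": "object"
    },
    "snp_pc_variance_fraction": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Snp Pc Variance Fraction"
    },
    "runtime_s": {
      "title": "Runtime S",
      "type": "number"
    }
  },
  "required": [
    "seed",
    "parameters",
    "stages",
    "counts",
    "n_dems",
    "runtime_s"
  ],
  "title": "RunReport",
  "type": "object"
}
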