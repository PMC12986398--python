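{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "methassay pipeline report",
  "type": "object",
  "required": [
    "cobra",
    "designs",
    "islands",
    "locus",
    "pyro",
    "schema_version",
    "screening",
    "seed"
  ],
  "properties": {
    "schema_version": {
      "type": "string"
    },
    "seed": {
      "type": "integer"
    },
    "locus": {
      "type": "object",
      "required": [
        "length",
        "n_cpg",
        "name",
        "tss"
      ],
      "properties": {
        "name": {
          "type": "string"
        },
        "length": {
          "type": "integer"
        },
        "tss": {
          "type": "integer"
        },
        "n_cpg": {
          "type": "integer"
        }
      }
    },
    "islands": {
      "type": "array"
    },
    "screening": {
      "type": "object",
      "required": [
        "comparisons",
        "group_means"
      ],
      "properties": {
        "group_means": {
          "type": "object"
        },
        "comparisons": {
          "type": "array"
        }
      }
    },
    "designs": {
      "type": "array"
    },
    "cobra": {
      "type": "object",
      "required": [
        "enzyme",
        "fragments_methylated",
        "fragments_unmethylated",
        "group_frequencies_pct",
        "informative_sites"
      ],
      "properties": {
        "enzyme": {
          "type": "string"
        },
        "informative_sites": {
          "type": "array"
        },
        "fragments_methylated": {
          "type": "array"
        },
        "fragments_unmethylated": {
          "type": "array"
        },
        "group_frequencies_pct": {
          "type": "object"
        }
      }
    },
    "pyro": {
      "type": "object",
      "required": [
        "background_pct",
        "n_cpg_pairs",
        "per_cpg_pct",
        "qc_pass",
        "region_mean_pct"
      ],
      "properties": {
        "n_cpg_pairs": {
          "type": "integer"
        },
        "region_mean_pct": {
          "type": "number"
        },
        "per_cpg_pct": {
          "type": "object"
        },
        "qc_pass": {
          "type": "boolean"
        },
        "background_pct": {
          "type": "number"
        }
      }
    }
  }
}
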