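{
  "$defs": {
    "VariantMetrics": {
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "mechanism": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "title": "Mechanism"
        },
        "core_rmsd_median": {
          "title": "Core Rmsd Median",
          "type": "number"
        },
        "core_rmsd_q90": {
          "title": "Core Rmsd Q90",
          "type": "number"
        },
        "rmsf_174_182": {
          "title": "Rmsf 174 182",
          "type": "number"
        },
        "rmsf_192_198": {
          "title": "Rmsf 192 198",
          "type": "number"
        },
        "rmsf_205_215": {
          "title": "Rmsf 205 215",
          "type": "number"
        },
        "hbond_166_185_occupancy": {
          "title": "Hbond 166 185 Occupancy",
          "type": "number"
        },
        "beta_segment_distance": {
          "title": "Beta Segment Distance",
          "type": "number"
        },
        "loop_205_215_gyration": {
          "title": "Loop 205 215 Gyration",
          "type": "number"
        },
        "rca": {
          "title": "Rca",
          "type": "number"
        }
      },
      "required": [
        "name",
        "mechanism",
        "core_rmsd_median",
        "core_rmsd_q90",
        "rmsf_174_182",
        "rmsf_192_198",
        "rmsf_205_215",
        "hbond_166_185_occupancy",
        "beta_segment_distance",
        "loop_205_215_gyration",
        "rca"
      ],
      "title": "VariantMetrics",
      "type": "object"
    }
  },
  "properties": {
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "config_digest": {
      "title": "Config Digest",
      "type": "string"
    },
    "seeds": {
      "items": {
        "type": "integer"
      },
      "title": "Seeds",
      "type": "array"
    },
    "n_steps": {
      "title": "N Steps",
      "type": "integer"
    },
    "variants": {
      "additionalProperties": {
        "$ref": "#/$defs/VariantMetrics"
      },
      "title": "Variants",
      "type": "object"
    }
  },
  "required": [
    "package_version",
    "config_digest",
    "seeds",
    "n_steps",
    "variants"
  ],
  "title": "VariantReport",
  "type": "object"
}
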