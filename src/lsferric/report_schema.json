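{
  "$defs": {
    "BandRow": {
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "energy_cm": {
          "title": "Energy Cm",
          "type": "number"
        },
        "fwhm_cm": {
          "title": "Fwhm Cm",
          "type": "number"
        },
        "epsilon": {
          "title": "Epsilon",
          "type": "number"
        },
        "delta_epsilon": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Delta Epsilon"
        },
        "cd_ratio_x1e4": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cd Ratio X1E4"
        }
      },
      "required": [
        "label",
        "energy_cm",
        "fwhm_cm",
        "epsilon"
      ],
      "title": "BandRow",
      "type": "object"
    },
    "MixtureReport": {
      "properties": {
        "fractions": {
          "items": {
            "type": "number"
          },
          "title": "Fractions",
          "type": "array"
        },
        "residual_norm": {
          "title": "Residual Norm",
          "type": "number"
        }
      },
      "required": [
        "fractions",
        "residual_norm"
      ],
      "title": "MixtureReport",
      "type": "object"
    },
    "PKaResult": {
      "properties": {
        "pka": {
          "title": "Pka",
          "type": "number"
        },
        "rmse": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Rmse"
        },
        "n_points": {
          "title": "N Points",
          "type": "integer"
        }
      },
      "required": [
        "pka",
        "n_points"
      ],
      "title": "PKaResult",
      "type": "object"
    },
    "TaylorResult": {
      "properties": {
        "g_signed": {
          "maxItems": 3,
          "minItems": 3,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "G Signed",
          "type": "array"
        },
        "coefficients": {
          "maxItems": 3,
          "minItems": 3,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Coefficients",
          "type": "array"
        },
        "coefficients_table_scaled": {
          "maxItems": 3,
          "minItems": 3,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Coefficients Table Scaled",
          "type": "array"
        },
        "delta_cm": {
          "title": "Delta Cm",
          "type": "number"
        },
        "v_abs_cm": {
          "title": "V Abs Cm",
          "type": "number"
        },
        "rhombicity": {
          "title": "Rhombicity",
          "type": "number"
        },
        "trans1_cm": {
          "title": "Trans1 Cm",
          "type": "number"
        },
        "trans2_cm": {
          "title": "Trans2 Cm",
          "type": "number"
        },
        "residual": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Residual"
        }
      },
      "required": [
        "g_signed",
        "coefficients",
        "coefficients_table_scaled",
        "delta_cm",
        "v_abs_cm",
        "rhombicity",
        "trans1_cm",
        "trans2_cm"
      ],
      "title": "TaylorResult",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Machine-readable pipeline output.",
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "taylor": {
      "anyOf": [
        {
          "$ref": "#/$defs/TaylorResult"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "epr_fit": {
      "anyOf": [
        {
          "$ref": "#/$defs/MixtureReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "band_table": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/BandRow"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Band Table"
    },
    "pka": {
      "anyOf": [
        {
          "$ref": "#/$defs/PKaResult"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "seed"
  ],
  "title": "Report",
  "type": "object"
}
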