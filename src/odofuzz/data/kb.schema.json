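{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "odofuzz knowledge base",
  "description": "Expert knowledge base: per-species fuzzy sets over day-of-year and altitude, per-sex colour matrices (additive A and exclusion E stored as permissibility), a 7x7 colour-similarity matrix S and the biotope vocabulary.",
  "type": "object",
  "required": ["schema_version", "species"],
  "properties": {
    "schema_version": {"const": 1},
    "colour_similarity": {
      "description": "Symmetric 7x7 matrix with unit diagonal, entries in [0,1]; row/column order: yellow, orange, red, green, blue, brown, black.",
      "type": "array",
      "minItems": 7,
      "maxItems": 7,
      "items": {
        "type": "array",
        "minItems": 7,
        "maxItems": 7,
        "items": {"type": "number", "minimum": 0, "maximum": 1}
      }
    },
    "biotopes": {
      "description": "Habitat vocabulary as lowercase snake_case codes; uniqueness required.",
      "type": "array",
      "items": {"type": "string", "pattern": "^[a-z][a-z0-9_]*$"},
      "uniqueItems": true,
      "minItems": 1
    },
    "species": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "suborder", "seasonality", "altitude", "colours"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "suborder": {"enum": ["anisoptera", "zygoptera"]},
          "seasonality": {
            "description": "Trapezoid corners [a,b,c,d] on day-of-year 1..366, a<=b<=c<=d.",
            "type": "array",
            "minItems": 4,
            "maxItems": 4,
            "items": {"type": "number", "minimum": 1, "maximum": 366}
          },
          "altitude": {
            "description": "Trapezoid corners [a,b,c,d] in metres, a<=b<=c<=d.",
            "type": "array",
            "minItems": 4,
            "maxItems": 4,
            "items": {"type": "number"}
          },
          "colours": {
            "type": "object",
            "required": ["male", "female"],
            "additionalProperties": false,
            "properties": {
              "male": {"$ref": "#/$defs/sexColours"},
              "female": {"$ref": "#/$defs/sexColours"}
            }
          }
        }
      }
    }
  },
  "$defs": {
    "colourMap": {
      "type": "object",
      "propertyNames": {
        "enum": ["yellow", "orange", "red", "green", "blue", "brown", "black"]
      },
      "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
    },
    "sexColours": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "additive": {
          "$ref": "#/$defs/colourMap",
          "description": "Column of A; unspecified colours default to 0."
        },
        "permissibility": {
          "$ref": "#/$defs/colourMap",
          "description": "Column of E as permissibility; unspecified colours default to 1 (no penalty)."
        }
      }
    }
  }
}
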