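{
  "type": "object",
  "required": ["format", "version", "hash_scheme", "r", "records"],
  "properties": {
    "format": {"type": "string", "enum": ["templex-catalog"]},
    "version": {"type": "integer", "minimum": 1},
    "hash_scheme": {"type": "string"},
    "r": {"type": "number"},
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "identifier",
          "smarts",
          "radii",
          "directions",
          "datasets",
          "domains",
          "ec_numbers",
          "sequence_score",
          "source_reaction_count",
          "omitted_cofactors"
        ],
        "properties": {
          "identifier": {
            "type": "string",
            "pattern": "^RR:[A-Z2-7]{6}-[A-Z2-7]{6}-[A-Z2-7]{6}$"
          },
          "smarts": {"type": "string"},
          "radii": {
            "type": "array",
            "items": {"type": "integer", "minimum": 0}
          },
          "directions": {
            "type": "array",
            "items": {"type": "string", "enum": ["forward", "reverse"]}
          },
          "datasets": {
            "type": "object",
            "additionalProperties": {
              "type": "array",
              "items": {"type": "string"}
            }
          },
          "domains": {
            "type": "array",
            "items": {
              "type": "string",
              "enum": ["biochemical", "organic chemistry"]
            }
          },
          "ec_numbers": {"type": "array", "items": {"type": "string"}},
          "sequence_score": {"type": ["number", "null"]},
          "source_reaction_count": {"type": "integer", "minimum": 1},
          "omitted_cofactors": {"type": "array", "items": {"type": "string"}}
        }
      }
    }
  }
}
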