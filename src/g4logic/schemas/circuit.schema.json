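{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "g4logic-circuit-1.schema.json",
  "title": "g4logic circuit specification",
  "description": "Declarative spec for one DNAzyme logic gate: strand roster as ordered 5'->3' domain-token lists, two input strands, and the declared Boolean function over input states (0,0),(1,0),(0,1),(1,1). Domain token syntax: name[*][/role][:length_nt].",
  "type": "object",
  "required": ["format", "name", "declared_function", "strands", "inputs"],
  "properties": {
    "format": {"const": "g4logic-circuit/1"},
    "name": {"type": "string", "minLength": 1},
    "provenance": {"enum": ["reference", "reconstructed"]},
    "declared_function": {
      "type": "array",
      "items": {"enum": [0, 1]},
      "minItems": 4,
      "maxItems": 4
    },
    "strands": {"type": "array", "items": {"$ref": "#/$defs/strand"}, "minItems": 1},
    "inputs": {"type": "array", "items": {"$ref": "#/$defs/strand"}, "minItems": 2, "maxItems": 2}
  },
  "$defs": {
    "strand": {
      "type": "object",
      "required": ["name", "domains"],
      "properties": {
        "name": {"type": "string", "minLength": 1},
        "domains": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "string",
            "pattern": "^[^*/:]+\\*?(/(toehold|recognition_arm|catalytic_core_I|catalytic_core_II|substrate_arm|g4_segment|generic))?(:[1-9][0-9]*)?$"
          }
        },
        "ra_site": {"type": "integer", "minimum": 1},
        "caged_g4": {
          "type": "array",
          "items": {"type": "integer", "minimum": 0},
          "minItems": 2,
          "maxItems": 2
        },
        "sequence": {"type": "string", "pattern": "^[ACGT]+$"}
      }
    }
  }
}
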