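{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "causal-JSON (mi2cast dialect, version 1.0)",
  "description": "Lossless interchange document for MI2CAST-annotated molecular causal statements. Terms are always {id, label} objects; readers must ignore (with a warning) unknown keys. This document describes the format; the reference validator is mi2cast.causaljson.read_causal_json.",
  "type": "object",
  "required": ["format_version", "statements"],
  "properties": {
    "format_version": {"const": "1.0"},
    "statements": {
      "type": "array",
      "items": {"$ref": "#/$defs/statement"}
    }
  },
  "$defs": {
    "term": {
      "type": "object",
      "required": ["id", "label"],
      "properties": {
        "id": {"type": "string", "pattern": "^[^:]+:.+$"},
        "label": {"type": "string", "minLength": 1}
      }
    },
    "modification": {
      "type": "object",
      "required": ["term"],
      "properties": {
        "term": {"$ref": "#/$defs/term"},
        "residue": {"$ref": "#/$defs/term"},
        "position": {"type": "integer", "minimum": 1}
      }
    },
    "entity": {
      "type": "object",
      "required": ["id", "label"],
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "label": {"type": "string", "minLength": 1},
        "biological_type": {"$ref": "#/$defs/term"},
        "modifications": {
          "type": "array",
          "items": {"$ref": "#/$defs/modification"}
        },
        "compartment": {"$ref": "#/$defs/term"}
      }
    },
    "statement": {
      "type": "object",
      "required": ["source", "target", "relation", "references", "evidence"],
      "properties": {
        "source": {"$ref": "#/$defs/entity"},
        "target": {"$ref": "#/$defs/entity"},
        "relation": {"$ref": "#/$defs/term"},
        "references": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "object",
            "required": ["id"],
            "properties": {"id": {"type": "string", "pattern": "^[^:]+:.+$"}}
          }
        },
        "evidence": {
          "type": "array",
          "minItems": 1,
          "items": {"$ref": "#/$defs/term"}
        },
        "mechanism": {"$ref": "#/$defs/term"},
        "compartment": {"$ref": "#/$defs/term"},
        "cell_line": {"$ref": "#/$defs/term"},
        "cell_type": {"$ref": "#/$defs/term"},
        "tissue": {"$ref": "#/$defs/term"},
        "taxon": {"$ref": "#/$defs/term"}
      }
    }
  }
}
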