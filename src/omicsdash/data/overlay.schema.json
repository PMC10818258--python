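{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/omicsdash/overlay.schema.json",
  "title": "omicsdash pathway-overlay export",
  "description": "Per-entity values and bin colors for painting one base pathway's diagram in an external layout tool; one independent color scale per omics datatype.",
  "type": "object",
  "required": ["pathway_id", "node", "entities", "scales"],
  "additionalProperties": false,
  "properties": {
    "pathway_id": {"type": "string"},
    "node": {"type": "string"},
    "entities": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["entity", "datatype", "values"],
        "additionalProperties": false,
        "properties": {
          "entity": {"type": "string"},
          "datatype": {"enum": ["metabolomics", "transcriptomics", "proteomics", "flux"]},
          "values": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["column", "value", "color"],
              "properties": {
                "column": {"type": "string"},
                "value": {"type": ["number", "null"]},
                "bin": {"type": "integer", "minimum": 0},
                "color": {"type": ["string", "null"], "pattern": "^#[0-9a-f]{6}$"}
              }
            }
          }
        }
      }
    },
    "scales": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["datatype", "min", "max", "n_bins", "breakpoints", "colors", "palette"],
        "properties": {
          "datatype": {"type": "string"},
          "min": {"type": "number"},
          "max": {"type": "number"},
          "n_bins": {"type": "integer", "minimum": 1},
          "breakpoints": {"type": "array", "items": {"type": "number"}},
          "colors": {"type": "array", "items": {"type": "string"}},
          "palette": {"enum": ["diverging", "sequential"]}
        }
      }
    }
  }
}
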