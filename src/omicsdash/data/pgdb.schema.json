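{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/omicsdash/pgdb.schema.json",
  "title": "omicsdash pathway/genome database document",
  "description": "Organism database consumed by omicsdash: compounds with a chemical-class DAG, pathways with class memberships and curator-designated primary inputs/outputs, genes with GO and activity annotations, and the GO term DAG. All parent links must be acyclic and all cross-references must resolve (enforced by the loader beyond what JSON Schema can express).",
  "type": "object",
  "required": ["schema_version", "organism", "compounds", "pathway_classes", "pathways", "go_terms", "genes"],
  "additionalProperties": false,
  "properties": {
    "schema_version": {"const": 1},
    "organism": {"type": "string", "minLength": 1},
    "compounds": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "synonyms": {"type": "array", "items": {"type": "string"}},
          "parent_ids": {"type": "array", "items": {"type": "string"}},
          "is_class": {"type": "boolean"}
        }
      }
    },
    "pathway_classes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "parent_ids": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "pathways": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "class_ids"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "class_ids": {"type": "array", "items": {"type": "string"}, "minItems": 1},
          "compound_ids": {"type": "array", "items": {"type": "string"}},
          "gene_ids": {"type": "array", "items": {"type": "string"}},
          "primary_input_ids": {"type": "array", "items": {"type": "string"}},
          "primary_output_ids": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "go_terms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "parent_ids": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "genes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "synonyms": {"type": "array", "items": {"type": "string"}},
          "go_term_ids": {"type": "array", "items": {"type": "string"}},
          "activity_tags": {"type": "array", "items": {"enum": ["transporter", "regulator"]}},
          "product_name": {"type": ["string", "null"]},
          "operon_id": {"type": ["string", "null"]}
        }
      }
    }
  }
}
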