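{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/hboc-triage/pedigree-1.0.schema.json",
  "title": "hboc-pedigree",
  "description": "Proband-rooted family history record, schema version 1.0. The CSV dialect (one row per individual, diagnoses as repeated rows sharing the id) carries the same fields; this JSON form is canonical.",
  "type": "object",
  "required": ["proband_id", "individuals"],
  "properties": {
    "format": {"const": "hboc-pedigree"},
    "version": {"const": "1.0"},
    "proband_id": {"type": "string"},
    "individuals": {
      "type": "array",
      "items": {"$ref": "#/$defs/individual"}
    }
  },
  "$defs": {
    "trilean": {"enum": ["yes", "no", "unknown"]},
    "individual": {
      "type": "object",
      "required": ["id", "sex"],
      "properties": {
        "id": {"type": "string"},
        "sex": {"enum": ["female", "male"]},
        "age": {"type": "integer", "minimum": 0, "description": "current age, or age at death if not alive; omit if unknown"},
        "alive": {"$ref": "#/$defs/trilean"},
        "mother_id": {"type": "string"},
        "father_id": {"type": "string"},
        "diagnoses": {"type": "array", "items": {"$ref": "#/$defs/diagnosis"}}
      },
      "additionalProperties": false
    },
    "diagnosis": {
      "type": "object",
      "required": ["site"],
      "properties": {
        "site": {"enum": ["breast", "ovary"]},
        "age_at_onset": {"type": "integer", "minimum": 0},
        "laterality": {"enum": ["unilateral", "bilateral", "unknown"], "description": "breast only; a bilateral cancer is one diagnosis"},
        "triple_negative": {"$ref": "#/$defs/trilean", "description": "breast only"},
        "mucinous": {"$ref": "#/$defs/trilean", "description": "ovary only"},
        "borderline": {"$ref": "#/$defs/trilean", "description": "ovary only"}
      },
      "additionalProperties": false
    }
  }
}
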