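{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "spinemorph subject contour document",
  "description": "Per-subject endplate contours in the right-handed patient frame: +x left->right, +y posterior->anterior, +z caudal->cranial, units mm. Validation is performed in code (spinemorph.io_cli.subject_from_dict); this schema documents the format.",
  "type": "object",
  "required": ["subject_id", "frame", "levels"],
  "properties": {
    "subject_id": {"type": "string"},
    "frame": {"const": "RAS-mm"},
    "group": {"type": "string"},
    "meta": {
      "type": "object",
      "properties": {
        "curve_pattern": {"type": "string"},
        "standing_cobb_deg": {"type": "object", "additionalProperties": {"type": "number"}}
      }
    },
    "levels": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["level", "side", "points", "canal_centroid"],
        "properties": {
          "level": {"enum": ["T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5", "S1"]},
          "side": {"enum": ["superior", "inferior"]},
          "points": {
            "type": "array",
            "minItems": 12,
            "items": {"type": "array", "minItems": 3, "maxItems": 3, "items": {"type": "number"}}
          },
          "canal_centroid": {"type": "array", "minItems": 3, "maxItems": 3, "items": {"type": "number"}}
        }
      }
    }
  }
}
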