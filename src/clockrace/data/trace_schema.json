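{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "clockrace long-format trace table (CSV columns)",
  "description": "One row per (cell, frame). Channels a trace does not carry are empty fields. 'divided' is a 0/1 anaphase event flag at that frame. 'treatment' encodes LABEL[@dose][+delay{h}][+const].",
  "type": "object",
  "properties": {
    "cell_id": {"type": "string"},
    "time_h": {"type": "number", "minimum": 0},
    "cdk2": {"type": ["number", "null"], "minimum": 0},
    "apc": {"type": ["number", "null"], "minimum": 0, "maximum": 1.5},
    "ccna2": {"type": ["number", "null"], "minimum": 0},
    "divided": {"type": "integer", "enum": [0, 1]},
    "treatment": {"type": "string"},
    "treatment_time_h": {"type": "number", "minimum": 0},
    "preset": {"type": "string"}
  },
  "required": ["cell_id", "time_h", "cdk2", "apc", "ccna2", "divided",
               "treatment", "treatment_time_h", "preset"]
}
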