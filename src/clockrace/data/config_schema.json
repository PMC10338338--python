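{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "clockrace pipeline run configuration",
  "type": "object",
  "properties": {
    "seed": {"type": "integer", "minimum": 0},
    "out_dir": {"type": "string"},
    "preset": {"type": "string", "enum": ["MCF10A", "RPE1", "RPE1_CCNA2dd", "RPE1_CCNA2dd_DIA", "U2OS"]},
    "treatment": {"type": "string", "enum": ["DMSO", "MITOGEN_REMOVAL", "MEKI", "CDK46I", "CDK1I", "CDK46I_CDK1I", "MEKI_DOSE"]},
    "n_cells": {"type": "integer", "minimum": 1},
    "delay_hours": {"type": "number", "minimum": 0},
    "race_n": {"type": "integer", "minimum": 1},
    "decay_n": {"type": "integer", "minimum": 1},
    "decay_noise_cv": {"type": "number", "minimum": 0},
    "cdk2_threshold": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1.5},
    "ode_eval_time": {"type": "number", "exclusiveMinimum": 0},
    "ode_dose_step": {"type": "number", "exclusiveMinimum": 0, "maximum": 0.5},
    "ode_params_file": {"type": ["string", "null"]},
    "log_level": {"type": "string"}
  },
  "required": ["seed", "out_dir"],
  "additionalProperties": false
}
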