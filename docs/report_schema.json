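{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hubspin pipeline report",
  "type": "object",
  "required": ["config", "stage_seeds", "versions", "spin_tests", "cpm",
               "epicenters", "overlap_regions", "timing"],
  "properties": {
    "config": {
      "type": "object",
      "description": "Echo of the PipelineConfig the run was generated from",
      "required": ["seed"],
      "properties": {"seed": {"type": "integer"}}
    },
    "stage_seeds": {
      "type": "object",
      "description": "Per-stage seeds derived from the master seed",
      "required": ["template", "clinical", "population", "spin", "cpm", "epicenters"],
      "additionalProperties": {"type": "integer"}
    },
    "versions": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "spin_tests": {
      "type": "object",
      "required": ["group_vs_centrality", "ageXgroup_vs_centrality",
                   "prs_vs_centrality", "ageXprs_vs_centrality"],
      "additionalProperties": {
        "type": "object",
        "required": ["observed_r", "p_spin", "n_rotations", "tail", "seed"],
        "properties": {
          "observed_r": {"type": "number", "minimum": -1, "maximum": 1},
          "p_spin": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
          "n_rotations": {"type": "integer", "minimum": 1},
          "tail": {"enum": ["greater", "two_sided"]},
          "seed": {"type": "integer"}
        }
      }
    },
    "cpm": {
      "type": "object",
      "required": ["r_true_pred", "p_perm", "p_parametric", "n_top_predictors", "empty_folds"],
      "properties": {
        "r_true_pred": {"type": "number", "minimum": -1, "maximum": 1},
        "p_perm": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "p_parametric": {"type": "number", "minimum": 0, "maximum": 1},
        "n_top_predictors": {"type": "integer", "minimum": 0},
        "empty_folds": {"type": "array", "items": {"type": "integer"}}
      }
    },
    "epicenters": {
      "type": "object",
      "required": ["alpha", "significant_regions"],
      "properties": {
        "alpha": {"type": "number"},
        "significant_regions": {"type": "array", "items": {"type": "string"}}
      }
    },
    "overlap_regions": {
      "type": "array",
      "description": "Significant epicenters incident to a CPM top-predictor edge",
      "items": {"type": "string"}
    },
    "timing": {
      "type": "object",
      "description": "Per-stage wall-clock seconds (not part of determinism)",
      "additionalProperties": {"type": "number"}
    }
  }
}
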