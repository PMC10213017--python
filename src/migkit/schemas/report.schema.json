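{
  "type": "object",
  "required": ["schema", "software", "config", "input", "kinematics", "similarity", "directionality"],
  "properties": {
    "schema": {"type": "string", "enum": ["migkit-analysis-report/1"]},
    "software": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"}
      }
    },
    "seed": {"type": ["integer", "null"]},
    "config": {"type": "object"},
    "input": {
      "type": "object",
      "required": ["path", "sha256", "n_tracks", "n_frames", "frame_interval_min"],
      "properties": {
        "path": {"type": "string"},
        "sha256": {"type": "string"},
        "n_tracks": {"type": "integer"},
        "n_frames": {"type": "integer"},
        "n_points": {"type": "integer"},
        "frame_interval_min": {"type": "number"}
      }
    },
    "kinematics": {
      "type": "object",
      "required": ["n_vectors", "mean_speed_um_per_min", "summed_mean_displacement_um"],
      "properties": {
        "n_vectors": {"type": "integer"},
        "mean_speed_um_per_min": {"type": "number"},
        "per_frame_mean_speed": {
          "type": "object",
          "additionalProperties": {"type": "number"}
        },
        "summed_mean_displacement_um": {"type": "array", "items": {"type": "number"}}
      }
    },
    "similarity": {
      "type": "object",
      "required": ["global_raw_deg", "global_inverted_deg", "convention", "n_pairs", "n_excluded"],
      "properties": {
        "global_raw_deg": {"type": "number"},
        "global_inverted_deg": {"type": "number"},
        "convention": {"type": "string", "enum": ["raw", "inverted"]},
        "n_pairs": {"type": "integer"},
        "n_excluded": {"type": "integer"}
      }
    },
    "directionality": {
      "type": "object",
      "required": ["classes", "n_classified", "min_movement_um", "scar_center_um"],
      "properties": {
        "classes": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["count", "fraction"],
            "properties": {
              "count": {"type": "integer"},
              "fraction": {"type": "number"}
            }
          }
        },
        "n_classified": {"type": "integer"},
        "n_excluded_single_point": {"type": "integer"},
        "min_movement_um": {"type": "number"},
        "scar_center_um": {"type": "array", "items": {"type": "number"}}
      }
    }
  }
}
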