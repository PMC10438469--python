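{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "TypeTracker tracker-json dialect",
  "description": "Single-file nucleus-tracking export: per-frame points plus point-to-point links between consecutive frames. A point with two successors is a division; chains between forks become tracks. Unknown keys are ignored.",
  "type": "object",
  "required": ["positions", "links"],
  "properties": {
    "movie_end_frame": {
      "type": "integer",
      "description": "Last frame of the recording; defaults to the largest frame present."
    },
    "frame_interval_h": {
      "type": "number",
      "description": "Hours per frame; defaults to 0.2 (one frame every 12 minutes)."
    },
    "positions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "frame", "x", "y", "z"],
        "properties": {
          "id": {"type": "integer", "description": "Unique point id."},
          "frame": {"type": "integer"},
          "x": {"type": "number", "description": "micrometres"},
          "y": {"type": "number", "description": "micrometres"},
          "z": {"type": "number", "description": "micrometres (anisotropy already corrected)"},
          "track": {
            "type": "integer",
            "description": "Optional explicit track id (written by this package; assigned deterministically when absent)."
          }
        },
        "additionalProperties": true
      }
    },
    "links": {
      "type": "array",
      "description": "Pairs of point ids joining consecutive frames (either order).",
      "items": {
        "type": "array",
        "items": {"type": "integer"},
        "minItems": 2,
        "maxItems": 2
      }
    },
    "deaths": {
      "type": "array",
      "description": "Point ids at which a cell was seen to die (its track's last point). Tracks ending early without a death mark are treated as lost.",
      "items": {"type": "integer"}
    }
  },
  "additionalProperties": true
}
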