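{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "chipflow netlist",
  "description": "Graph description of a microfluidic chip: terminals, turns and intersections joined by rectangular channel segments. Lengths and positions use the declared 'units'; velocities are always m/s (positive into the chip) and pressures Pa.",
  "type": "object",
  "required": ["nodes", "segments"],
  "properties": {
    "units": {"enum": ["m", "mm", "um"], "default": "m"},
    "fluid": {
      "type": "object",
      "properties": {
        "viscosity": {"type": "number", "exclusiveMinimum": 0, "description": "Pa s"},
        "density": {"type": "number", "exclusiveMinimum": 0, "description": "kg/m^3"}
      }
    },
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind", "position"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"enum": ["terminal", "turn", "intersection"]},
          "position": {
            "type": "array", "items": {"type": "number"},
            "minItems": 2, "maxItems": 2
          },
          "arms": {
            "type": "object",
            "description": "intersections only: compass arm -> attached segment id",
            "propertyNames": {"enum": ["N", "E", "S", "W"]},
            "additionalProperties": {"type": "string"},
            "minProperties": 3,
            "maxProperties": 4
          }
        }
      }
    },
    "segments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "nodes", "width", "height", "waypoints"],
        "properties": {
          "id": {"type": "string"},
          "nodes": {
            "type": "array", "items": {"type": "string"},
            "minItems": 2, "maxItems": 2
          },
          "width": {"type": "number", "exclusiveMinimum": 0},
          "height": {"type": "number", "exclusiveMinimum": 0},
          "waypoints": {
            "type": "array",
            "description": "centerline polyline incl. both node positions; axis-aligned legs meeting at 90 degrees",
            "items": {
              "type": "array", "items": {"type": "number"},
              "minItems": 2, "maxItems": 2
            },
            "minItems": 2
          }
        }
      }
    },
    "boundary_conditions": {
      "type": "object",
      "description": "terminal id -> boundary condition",
      "additionalProperties": {
        "type": "object",
        "required": ["kind", "value"],
        "properties": {
          "kind": {"enum": ["pressure", "velocity"]},
          "value": {"type": "number", "description": "Pa, or m/s positive into the chip"}
        }
      }
    }
  }
}
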