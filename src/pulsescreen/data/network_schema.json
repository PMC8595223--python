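{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "pulsescreen arterial network config",
 "description": "Units: lengths cm, areas cm2, beta mmHg*cm, resistances mmHg*s/mL, compliances mL/mmHg, pressures mmHg, flows mL/s, times s.",
 "type": "object",
 "required": ["inlet", "inflow", "vessels", "junctions", "outlets"],
 "properties": {
  "description": {"type": "string"},
  "units": {"type": "object"},
  "inlet": {"type": "string"},
  "inflow": {
   "type": "object",
   "required": ["period_s", "phase", "flow_ml_s"],
   "properties": {
    "period_s": {"type": "number", "exclusiveMinimum": 0},
    "phase": {"type": "array", "items": {"type": "number", "minimum": 0, "exclusiveMaximum": 1}},
    "flow_ml_s": {"type": "array", "items": {"type": "number"}}
   }
  },
  "vessels": {
   "type": "array",
   "minItems": 1,
   "items": {
    "type": "object",
    "required": ["id", "length_cm", "area_proximal_cm2", "area_distal_cm2", "beta_mmhg_cm"],
    "properties": {
     "id": {"type": "string"},
     "length_cm": {"type": "number", "exclusiveMinimum": 0},
     "area_proximal_cm2": {"type": "number", "exclusiveMinimum": 0},
     "area_distal_cm2": {"type": "number", "exclusiveMinimum": 0},
     "beta_mmhg_cm": {"type": "number", "exclusiveMinimum": 0},
     "side": {"enum": ["left", "right", "none"]}
    }
   }
  },
  "junctions": {
   "type": "object",
   "additionalProperties": {"type": "array", "items": {"type": "string"}, "maxItems": 3}
  },
  "outlets": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["vessel", "r_proximal_mmhg_s_ml", "compliance_ml_mmhg", "r_distal_mmhg_s_ml"],
    "properties": {
     "vessel": {"type": "string"},
     "r_proximal_mmhg_s_ml": {"type": "number", "minimum": 0},
     "compliance_ml_mmhg": {"type": "number", "exclusiveMinimum": 0},
     "r_distal_mmhg_s_ml": {"type": "number", "minimum": 0},
     "outflow_pressure_mmhg": {"type": "number"}
    }
   }
  },
  "chains": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["name", "segments"],
    "properties": {
     "name": {"enum": ["CA", "SA", "PA", "AA"]},
     "side": {"enum": ["left", "right", "none"]},
     "segments": {"type": "array", "items": {"type": "string"}, "minItems": 1}
    }
   }
  },
  "measurement_sites": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["name", "side", "vessel"],
    "properties": {
     "name": {"enum": ["P1", "P2", "P3", "Q1", "Q2", "Q3"]},
     "side": {"enum": ["left", "right"]},
     "vessel": {"type": "string"},
     "position": {"type": "number", "minimum": 0, "maximum": 1}
    }
   }
  }
 }
}
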