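{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Genomics diagnostic report (structural schema)",
  "type": "object",
  "required": ["resourceType", "status", "code", "subject", "issued", "contained", "result"],
  "properties": {
    "resourceType": {"enum": ["DiagnosticReport"]},
    "status": {"enum": ["final"]},
    "code": {"$ref": "#/definitions/codeableConcept"},
    "subject": {
      "type": "object",
      "required": ["reference"],
      "properties": {"reference": {"type": "string", "pattern": "^Patient/"}}
    },
    "issued": {
      "type": "string",
      "pattern": "^[0-9]{4}-[0-9]{2}-[0-9]{2}T[0-9]{2}:[0-9]{2}:[0-9]{2}Z$"
    },
    "contained": {"type": "array", "items": {"$ref": "#/definitions/observation"}},
    "result": {"type": "array", "items": {"$ref": "#/definitions/reference"}}
  },
  "definitions": {
    "coding": {
      "type": "object",
      "required": ["system", "code"],
      "properties": {
        "system": {"type": "string"},
        "code": {"type": "string"},
        "display": {"type": "string"}
      }
    },
    "codeableConcept": {
      "type": "object",
      "required": ["coding"],
      "properties": {
        "coding": {"type": "array", "items": {"$ref": "#/definitions/coding"}}
      }
    },
    "reference": {
      "type": "object",
      "required": ["reference"],
      "properties": {"reference": {"type": "string", "pattern": "^#"}}
    },
    "quantity": {
      "type": "object",
      "required": ["value"],
      "properties": {"value": {"type": "integer"}}
    },
    "range": {
      "type": "object",
      "required": ["low"],
      "properties": {
        "low": {"$ref": "#/definitions/quantity"},
        "high": {"$ref": "#/definitions/quantity"}
      }
    },
    "component": {
      "type": "object",
      "required": ["code"],
      "properties": {
        "code": {"$ref": "#/definitions/codeableConcept"},
        "valueString": {"type": "string"},
        "valueCodeableConcept": {"$ref": "#/definitions/codeableConcept"},
        "valueRange": {"$ref": "#/definitions/range"}
      }
    },
    "observation": {
      "type": "object",
      "required": ["resourceType", "id", "status", "code"],
      "properties": {
        "resourceType": {"enum": ["Observation"]},
        "id": {"type": "string"},
        "status": {"enum": ["final"]},
        "category": {"type": "array", "items": {"$ref": "#/definitions/codeableConcept"}},
        "code": {"$ref": "#/definitions/codeableConcept"},
        "valueCodeableConcept": {"$ref": "#/definitions/codeableConcept"},
        "component": {"type": "array", "items": {"$ref": "#/definitions/component"}},
        "derivedFrom": {"type": "array", "items": {"$ref": "#/definitions/reference"}}
      }
    }
  }
}
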