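{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "PBN network definition",
  "description": "Definition of a probabilistic Boolean network with context switching. Truth tables are 0/1 strings over the declared inputs, first input as most significant bit; per-gene selection probabilities must sum to 1.",
  "type": "object",
  "required": ["genes", "functions", "p", "q"],
  "properties": {
    "genes": {
      "type": "array",
      "items": {"type": "string"},
      "minItems": 1,
      "uniqueItems": true
    },
    "p": {"type": "number", "minimum": 0, "maximum": 1, "description": "per-gene perturbation rate"},
    "q": {"type": "number", "minimum": 0, "maximum": 1, "description": "context switching probability"},
    "topology_incomplete": {
      "type": "boolean",
      "description": "set when truth tables are placeholders; dynamics then carry no biological meaning"
    },
    "functions": {
      "type": "object",
      "description": "one entry per gene name",
      "additionalProperties": {
        "type": "array",
        "minItems": 1,
        "items": {
          "type": "object",
          "required": ["inputs", "table", "prob"],
          "properties": {
            "inputs": {"type": "array", "items": {"type": "string"}},
            "table": {"type": "string", "pattern": "^[01]+$"},
            "prob": {"type": "number", "minimum": 0, "maximum": 1}
          }
        }
      }
    }
  }
}
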