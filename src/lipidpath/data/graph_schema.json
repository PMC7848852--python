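{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Lipid reaction network graph export",
 "type": "object",
 "required": ["meta", "nodes", "edges"],
 "properties": {
  "meta": {
   "type": "object",
   "properties": {
    "level": {"enum": ["subclass", "species", ""]},
    "type": {"enum": ["lipid", "fa", ""]},
    "alpha": {"type": ["number", "null"]},
    "condition_of_interest": {"type": ["string", "null"]},
    "control": {"type": ["string", "null"]}
   }
  },
  "nodes": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "status"],
    "properties": {
     "id": {"type": "string"},
     "status": {"enum": ["active", "suppressed", "none"]}
    }
   }
  },
  "edges": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["source", "target", "reaction", "kind", "genes", "z", "p", "status", "species_pairs"],
    "properties": {
     "source": {"type": "string"},
     "target": {"type": "string"},
     "reaction": {"type": "string"},
     "kind": {"type": "string"},
     "genes": {"type": "array", "items": {"type": "string"}},
     "z": {"type": ["number", "null"]},
     "p": {"type": ["number", "null"]},
     "status": {"enum": ["active", "suppressed", "none"]},
     "species_pairs": {"type": "array", "items": {"type": "array", "items": {"type": "string"}}}
    }
   }
  }
 }
}
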