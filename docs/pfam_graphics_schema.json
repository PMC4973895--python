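{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Pfam graphics architecture document (dialect consumed by needleplot)",
 "description": "One protein's drawable domain architecture. The historical Pfam graphics endpoint served either this object or a one-element array containing it; both are accepted. Coordinates are 1-based inclusive residue positions. Fields not listed here are ignored.",
 "type": "object",
 "required": ["length"],
 "properties": {
  "length": {
   "description": "Protein length in residues; integer or numeric string.",
   "type": ["integer", "string"]
  },
  "metadata": {
   "type": "object",
   "properties": {
    "accession": {"type": "string", "description": "UniProt accession"},
    "identifier": {"type": "string", "description": "Gene symbol"}
   }
  },
  "regions": {
   "description": "Pfam-A domains (metadata.type == 'pfama'); entries with any other metadata.type are treated as structural motifs of that kind.",
   "type": "array",
   "items": {
    "type": "object",
    "required": ["start", "end"],
    "properties": {
     "text": {"type": "string", "description": "Pfam short name, e.g. P53_TAD"},
     "start": {"type": ["integer", "string"]},
     "end": {"type": ["integer", "string"]},
     "colour": {"type": "string", "pattern": "^#[0-9A-Fa-f]{6}$"},
     "metadata": {
      "type": "object",
      "properties": {
       "accession": {"type": "string", "description": "Pfam accession, e.g. PF00870"},
       "description": {"type": "string"},
       "type": {"type": "string", "default": "pfama"}
      }
     }
    }
   }
  },
  "motifs": {
   "description": "Predicted structural regions. Known kinds: disorder, low_complexity, sig_p, coiled_coil, transmembrane; unknown kinds are dropped with a warning.",
   "type": "array",
   "items": {
    "type": "object",
    "required": ["type", "start", "end"],
    "properties": {
     "type": {"type": "string"},
     "start": {"type": ["integer", "string"]},
     "end": {"type": ["integer", "string"]}
    }
   }
  }
 }
}
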