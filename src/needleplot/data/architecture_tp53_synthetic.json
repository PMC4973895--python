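{
 "_comment": "Synthetic replay document mirroring the Pfam graphics response for human TP53 (P04637): constructed by hand for offline tests, not recorded from the live service.",
 "length": 393,
 "metadata": {
  "accession": "P04637",
  "identifier": "TP53"
 },
 "regions": [
  {
   "text": "P53_TAD",
   "start": 6,
   "end": 29,
   "colour": "#5B8AC6",
   "metadata": {
    "accession": "PF08563",
    "description": "P53 transactivation motif",
    "type": "pfama"
   }
  },
  {
   "text": "P53",
   "start": 95,
   "end": 288,
   "colour": "#C0354F",
   "metadata": {
    "accession": "PF00870",
    "description": "P53 DNA-binding domain",
    "type": "pfama"
   }
  },
  {
   "text": "P53_tetramer",
   "start": 318,
   "end": 358,
   "colour": "#3B8C6E",
   "metadata": {
    "accession": "PF07710",
    "description": "P53 tetramerisation motif",
    "type": "pfama"
   }
  }
 ],
 "motifs": [
  {"type": "disorder", "start": 36, "end": 63},
  {"type": "low_complexity", "start": 64, "end": 92},
  {"type": "disorder", "start": 291, "end": 312}
 ]
}
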