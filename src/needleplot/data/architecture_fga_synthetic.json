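{
 "_comment": "Synthetic replay document mirroring a fibrinogen-alpha-chain (FGA, P02671) style architecture: three Fib_-prefixed domains, a signal peptide, and disordered / low-complexity stretches. Constructed by hand for offline tests, not recorded from the live service.",
 "length": 866,
 "metadata": {
  "accession": "P02671",
  "identifier": "FGA"
 },
 "regions": [
  {
   "text": "Fib_alpha",
   "start": 27,
   "end": 194,
   "colour": "#2E86AB",
   "metadata": {
    "accession": "PF08702",
    "description": "Fibrinogen alpha/beta chain family",
    "type": "pfama"
   }
  },
  {
   "text": "Fib_coil",
   "start": 420,
   "end": 490,
   "colour": "#A23B72",
   "metadata": {
    "accession": "PF99901",
    "description": "Fibrinogen alpha chain coiled-coil region",
    "type": "pfama"
   }
  },
  {
   "text": "Fib_aC",
   "start": 614,
   "end": 853,
   "colour": "#F18F01",
   "metadata": {
    "accession": "PF12160",
    "description": "Fibrinogen alpha C domain",
    "type": "pfama"
   }
  }
 ],
 "motifs": [
  {"type": "sig_p", "start": 1, "end": 19},
  {"type": "disorder", "start": 225, "end": 390},
  {"type": "low_complexity", "start": 520, "end": 570}
 ]
}
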