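{
 "_comment": "Synthetic replay of a UniProt REST symbol search for TP53: hand-written to mirror the live response shape (one reviewed human entry plus a reviewed mouse entry, so the organism-preference filter is exercised).",
 "results": [
  {
   "primaryAccession": "P02340",
   "entryType": "UniProtKB reviewed (Swiss-Prot)",
   "organism": {"taxonId": 10090, "scientificName": "Mus musculus"}
  },
  {
   "primaryAccession": "P04637",
   "entryType": "UniProtKB reviewed (Swiss-Prot)",
   "organism": {"taxonId": 9606, "scientificName": "Homo sapiens"}
  }
 ]
}
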