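{
  "_comment": "Synthetic recorded-response fixture, hand-built to mirror the shape of a GBIF species-match + synonyms exchange; not captured from the live service.",
  "name_backbone": {
    "usageKey": 5219404,
    "canonicalName": "Panthera leo",
    "species": "Panthera leo",
    "matchType": "EXACT",
    "status": "SYNONYM"
  },
  "synonyms": [
    {"canonicalName": "Felis leo"},
    {"canonicalName": "Leo nobilis"}
  ]
}
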