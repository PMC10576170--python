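{
  "_comment": "Synthetic recorded-response fixture, hand-built to mirror the shape of an Entrez taxonomy esearch/efetch exchange; not captured from the live service.",
  "esearch": ["160616"],
  "efetch": [
    {
      "TaxId": "160616",
      "ScientificName": "Orthriophis taeniurus",
      "OtherNames": {
        "Synonym": ["Elaphe taeniura", "Elaphe taeniura"],
        "GenbankSynonym": [],
        "Name": [
          {"ClassCDE": "authority", "DispName": "Orthriophis taeniurus (Cope, 1861)"}
        ]
      },
      "Rank": "species",
      "Division": "snakes"
    }
  ]
}
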