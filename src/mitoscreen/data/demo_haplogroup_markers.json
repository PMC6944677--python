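{
  "_comment": "DEMO-ONLY haplogroup marker database. Entries use a handful of well-known lineage-defining positions; this is an illustrative fixture for the marker-set matcher, not a curated phylogeny.",
  "haplogroups": {
    "D4": [
      {"position": 3010, "ref": "G", "alt": "A"},
      {"position": 8414, "ref": "C", "alt": "T"},
      {"position": 14668, "ref": "C", "alt": "T"}
    ],
    "D": [
      {"position": 489, "ref": "T", "alt": "C"},
      {"position": 4883, "ref": "C", "alt": "T"},
      {"position": 5178, "ref": "C", "alt": "T"}
    ],
    "M": [
      {"position": 10400, "ref": "C", "alt": "T"},
      {"position": 14783, "ref": "T", "alt": "C"},
      {"position": 15043, "ref": "G", "alt": "A"}
    ],
    "B4": [
      {"position": 16217, "ref": "T", "alt": "C"},
      {"position": 827, "ref": "A", "alt": "G"}
    ],
    "F1": [
      {"position": 6962, "ref": "G", "alt": "A"},
      {"position": 10609, "ref": "T", "alt": "C"},
      {"position": 12406, "ref": "G", "alt": "A"}
    ]
  }
}
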