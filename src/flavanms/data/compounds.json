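{
  "catechin": {
    "units": [{"b_ring_oh": 2, "galloylated": false}],
    "retention_s": 252.0,
    "aliases": ["(+)-catechin", "C"]
  },
  "epicatechin": {
    "units": [{"b_ring_oh": 2, "galloylated": false}],
    "retention_s": 312.0,
    "aliases": ["(-)-epicatechin", "EC"]
  },
  "epigallocatechin": {
    "units": [{"b_ring_oh": 3, "galloylated": false}],
    "retention_s": 210.0,
    "aliases": ["(-)-epigallocatechin", "EGC"]
  },
  "epicatechin gallate": {
    "units": [{"b_ring_oh": 2, "galloylated": true}],
    "retention_s": 396.0,
    "aliases": ["(-)-epicatechin gallate", "ECG"]
  },
  "epigallocatechin gallate": {
    "units": [{"b_ring_oh": 3, "galloylated": true}],
    "retention_s": 348.0,
    "aliases": ["(-)-epigallocatechin gallate", "EGCG"]
  },
  "procyanidin B1": {
    "units": [
      {"b_ring_oh": 2, "galloylated": false},
      {"b_ring_oh": 2, "galloylated": false}
    ],
    "retention_s": 228.0,
    "aliases": ["B1"]
  },
  "procyanidin B2": {
    "units": [
      {"b_ring_oh": 2, "galloylated": false},
      {"b_ring_oh": 2, "galloylated": false}
    ],
    "retention_s": 288.0,
    "aliases": ["B2"]
  },
  "procyanidin C1": {
    "units": [
      {"b_ring_oh": 2, "galloylated": false},
      {"b_ring_oh": 2, "galloylated": false},
      {"b_ring_oh": 2, "galloylated": false}
    ],
    "retention_s": 330.0,
    "aliases": ["C1"]
  }
}
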