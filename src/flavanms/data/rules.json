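{
  "losses": {
    "WATER_LOSS": "H2O",
    "ETHENOL_LOSS": "C2H4O",
    "C3O2_LOSS": "C3O2",
    "C3O2_WATER_LOSS": "C3H2O3",
    "HRF": "C6H6O3",
    "RDA_152": "C8H8O3",
    "RDA_138": "C7H6O3",
    "GALLOYL_LOSS": "C7H4O4"
  },
  "monomer_chains": [
    ["WATER_LOSS"],
    ["ETHENOL_LOSS"],
    ["C3O2_LOSS"],
    ["HRF"],
    ["RDA_152"],
    ["RDA_138"],
    ["C3O2_LOSS", "WATER_LOSS"]
  ],
  "oligomer_chains": [
    ["ETHENOL_LOSS"],
    ["HRF"],
    ["RDA_152"],
    ["RDA_152", "WATER_LOSS"],
    ["HRF", "RDA_152"],
    ["RDA_152", "RDA_152"]
  ],
  "gallate_chains": [
    ["GALLOYL_LOSS"],
    ["GALLATE_ANION"]
  ],
  "intensity": {
    "WATER_LOSS": 0.7,
    "ETHENOL_LOSS": 0.9,
    "C3O2_LOSS": 0.55,
    "C3O2_WATER_LOSS": 0.5,
    "HRF": 0.5,
    "RDA_152": 0.6,
    "RDA_138": 0.45,
    "GALLOYL_LOSS": 1.0,
    "GALLATE_ANION": 0.7,
    "QM": 1.2,
    "qm_side_factor": 0.8
  }
}
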