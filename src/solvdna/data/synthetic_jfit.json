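{
  "name": "synthetic-jfit",
  "comment": "Synthetic even-tempered auxiliary density-fitting basis (s/p/d, lmax=2). This is a stand-in fitting set generated for this package, not tabulated reference data. Exponents (Bohr^-2) are capped near 16 so that every basis density is fully resolvable on the 0.2 Bohr analysis grids used by the error metrics.",
  "elements": {
    "H":  [{"l": 0, "exponents": [0.12, 0.40, 1.30, 4.20]},
           {"l": 1, "exponents": [0.60]}],
    "C":  [{"l": 0, "exponents": [0.18, 0.55, 1.70, 5.20, 16.0]},
           {"l": 1, "exponents": [0.25, 0.90, 3.20]},
           {"l": 2, "exponents": [0.70]}],
    "N":  [{"l": 0, "exponents": [0.20, 0.62, 1.90, 5.90, 16.0]},
           {"l": 1, "exponents": [0.30, 1.00, 3.40]},
           {"l": 2, "exponents": [0.80]}],
    "O":  [{"l": 0, "exponents": [0.22, 0.70, 2.20, 6.80, 16.0]},
           {"l": 1, "exponents": [0.35, 1.10, 3.60]},
           {"l": 2, "exponents": [0.90]}],
    "P":  [{"l": 0, "exponents": [0.16, 0.50, 1.60, 5.00, 15.5]},
           {"l": 1, "exponents": [0.22, 0.80, 2.80]},
           {"l": 2, "exponents": [0.55]}],
    "Mg": [{"l": 0, "exponents": [0.14, 0.45, 1.45, 4.60, 15.0]},
           {"l": 1, "exponents": [0.20, 0.70, 2.40]},
           {"l": 2, "exponents": [0.50]}],
    "Cl": [{"l": 0, "exponents": [0.17, 0.55, 1.75, 5.50, 16.0]},
           {"l": 1, "exponents": [0.28, 0.95, 3.20]},
           {"l": 2, "exponents": [0.65]}]
  }
}
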