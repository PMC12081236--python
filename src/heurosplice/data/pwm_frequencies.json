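{
  "comment": "First-order per-position base frequencies for splice-site scoring. Donor window is the 9-mer E-3..+6; acceptor window is the 23-mer -20..E+3. Values are smoothed human consensus frequencies; near-invariant positions carry a 0.001 pseudo-frequency so log-odds stay finite.",
  "background": {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
  "donor_9mer": {
    "positions": ["E-3", "E-2", "E-1", "+1", "+2", "+3", "+4", "+5", "+6"],
    "frequencies": [
      {"A": 0.33, "C": 0.37, "G": 0.18, "T": 0.12},
      {"A": 0.60, "C": 0.13, "G": 0.12, "T": 0.15},
      {"A": 0.09, "C": 0.04, "G": 0.79, "T": 0.08},
      {"A": 0.001, "C": 0.001, "G": 0.997, "T": 0.001},
      {"A": 0.001, "C": 0.001, "G": 0.001, "T": 0.997},
      {"A": 0.60, "C": 0.03, "G": 0.35, "T": 0.02},
      {"A": 0.71, "C": 0.08, "G": 0.11, "T": 0.10},
      {"A": 0.08, "C": 0.05, "G": 0.82, "T": 0.05},
      {"A": 0.17, "C": 0.17, "G": 0.19, "T": 0.47}
    ]
  },
  "acceptor_23mer": {
    "positions": ["-20", "-19", "-18", "-17", "-16", "-15", "-14", "-13", "-12", "-11", "-10", "-9", "-8", "-7", "-6", "-5", "-4", "-3", "-2", "-1", "E+1", "E+2", "E+3"],
    "frequencies": [
      {"A": 0.10, "C": 0.31, "G": 0.10, "T": 0.49},
      {"A": 0.10, "C": 0.32, "G": 0.09, "T": 0.49},
      {"A": 0.10, "C": 0.32, "G": 0.10, "T": 0.48},
      {"A": 0.09, "C": 0.33, "G": 0.09, "T": 0.49},
      {"A": 0.09, "C": 0.34, "G": 0.09, "T": 0.48},
      {"A": 0.09, "C": 0.35, "G": 0.08, "T": 0.48},
      {"A": 0.09, "C": 0.36, "G": 0.08, "T": 0.47},
      {"A": 0.08, "C": 0.37, "G": 0.08, "T": 0.47},
      {"A": 0.08, "C": 0.38, "G": 0.08, "T": 0.46},
      {"A": 0.08, "C": 0.39, "G": 0.07, "T": 0.46},
      {"A": 0.08, "C": 0.40, "G": 0.07, "T": 0.45},
      {"A": 0.08, "C": 0.40, "G": 0.07, "T": 0.45},
      {"A": 0.08, "C": 0.41, "G": 0.06, "T": 0.45},
      {"A": 0.09, "C": 0.41, "G": 0.06, "T": 0.44},
      {"A": 0.08, "C": 0.42, "G": 0.05, "T": 0.45},
      {"A": 0.07, "C": 0.44, "G": 0.04, "T": 0.45},
      {"A": 0.24, "C": 0.30, "G": 0.16, "T": 0.30},
      {"A": 0.05, "C": 0.63, "G": 0.01, "T": 0.31},
      {"A": 0.997, "C": 0.001, "G": 0.001, "T": 0.001},
      {"A": 0.001, "C": 0.001, "G": 0.997, "T": 0.001},
      {"A": 0.25, "C": 0.14, "G": 0.50, "T": 0.11},
      {"A": 0.28, "C": 0.22, "G": 0.26, "T": 0.24},
      {"A": 0.25, "C": 0.24, "G": 0.26, "T": 0.25}
    ]
  }
}
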