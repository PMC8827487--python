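{
 "version": 1,
 "comment": "Per-amino-acid protein-protein interface propensity scaled to [0,1].",
 "propensity": {
  "TRP": 1.0,
  "PHE": 0.9,
  "TYR": 0.88,
  "MET": 0.85,
  "ILE": 0.78,
  "LEU": 0.75,
  "CYS": 0.72,
  "VAL": 0.65,
  "HIS": 0.62,
  "ARG": 0.6,
  "ALA": 0.45,
  "GLY": 0.42,
  "THR": 0.4,
  "ASN": 0.4,
  "SER": 0.35,
  "GLN": 0.38,
  "PRO": 0.32,
  "ASP": 0.28,
  "GLU": 0.22,
  "LYS": 0.18
 }
}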