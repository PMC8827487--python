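{
 "version": 1,
 "comment": "Coarse-grained pseudoatom parameter table: side-chain pseudoatom atom groups (centroid placement), per-pseudoatom charge (e) and LJ-type code. lj_types gives 8-6 parameters B (energy*A^8), C (energy*A^6) and the 12-6 radius sigma (A); pair values combine as B_ij=sqrt(B_i*B_j), C_ij=sqrt(C_i*C_j), sigma_ij=(sigma_i+sigma_j)/2.",
 "lj_types": {
  "CA": {
   "B": 60142.836696,
   "C": 3789.718758,
   "sigma": 4.098134
  },
  "SML": {
   "B": 126806.761931,
   "C": 7338.354278,
   "sigma": 4.276314
  },
  "MED": {
   "B": 320758.371189,
   "C": 15816.487731,
   "sigma": 4.632673
  },
  "POL": {
   "B": 210937.5,
   "C": 11250.0,
   "sigma": 4.454494
  },
  "ARO": {
   "B": 870455.804166,
   "C": 37009.175347,
   "sigma": 4.989033
  },
  "POS": {
   "B": 240568.778392,
   "C": 11862.365798,
   "sigma": 4.632673
  },
  "NEG": {
   "B": 175781.25,
   "C": 9375.0,
   "sigma": 4.454494
  }
 },
 "residues": {
  "GLY": {
   "groups": [],
   "charges": [],
   "types": []
  },
  "ALA": {
   "groups": [
    [
     "CB"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "SML"
   ]
  },
  "SER": {
   "groups": [
    [
     "CB",
     "OG"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "SML"
   ]
  },
  "CYS": {
   "groups": [
    [
     "CB",
     "SG"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "SML"
   ]
  },
  "THR": {
   "groups": [
    [
     "CB",
     "OG1",
     "CG2"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "SML"
   ]
  },
  "VAL": {
   "groups": [
    [
     "CB",
     "CG1",
     "CG2"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "MED"
   ]
  },
  "LEU": {
   "groups": [
    [
     "CB",
     "CG",
     "CD1",
     "CD2"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "MED"
   ]
  },
  "ILE": {
   "groups": [
    [
     "CB",
     "CG1",
     "CG2",
     "CD1"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "MED"
   ]
  },
  "PRO": {
   "groups": [
    [
     "CB",
     "CG",
     "CD"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "SML"
   ]
  },
  "MET": {
   "groups": [
    [
     "CB",
     "CG"
    ],
    [
     "SD",
     "CE"
    ]
   ],
   "charges": [
    0,
    0
   ],
   "types": [
    "MED",
    "MED"
   ]
  },
  "ASN": {
   "groups": [
    [
     "CB",
     "CG",
     "OD1",
     "ND2"
    ]
   ],
   "charges": [
    0
   ],
   "types": [
    "POL"
   ]
  },
  "GLN": {
   "groups": [
    [
     "CB",
     "CG"
    ],
    [
     "CD",
     "OE1",
     "NE2"
    ]
   ],
   "charges": [
    0,
    0
   ],
   "types": [
    "MED",
    "POL"
   ]
  },
  "ASP": {
   "groups": [
    [
     "CB"
    ],
    [
     "CG",
     "OD1",
     "OD2"
    ]
   ],
   "charges": [
    0,
    -1
   ],
   "types": [
    "SML",
    "NEG"
   ]
  },
  "GLU": {
   "groups": [
    [
     "CB",
     "CG"
    ],
    [
     "CD",
     "OE1",
     "OE2"
    ]
   ],
   "charges": [
    0,
    -1
   ],
   "types": [
    "MED",
    "NEG"
   ]
  },
  "LYS": {
   "groups": [
    [
     "CB",
     "CG",
     "CD"
    ],
    [
     "CE",
     "NZ"
    ]
   ],
   "charges": [
    0,
    1
   ],
   "types": [
    "MED",
    "POS"
   ]
  },
  "ARG": {
   "groups": [
    [
     "CB",
     "CG",
     "CD"
    ],
    [
     "NE",
     "CZ",
     "NH1",
     "NH2"
    ]
   ],
   "charges": [
    0,
    1
   ],
   "types": [
    "MED",
    "POS"
   ]
  },
  "HIS": {
   "groups": [
    [
     "CB",
     "CG"
    ],
    [
     "ND1",
     "CD2",
     "CE1",
     "NE2"
    ]
   ],
   "charges": [
    0,
    0
   ],
   "types": [
    "MED",
    "ARO"
   ]
  },
  "PHE": {
   "groups": [
    [
     "CB",
     "CG"
    ],
    [
     "CD1",
     "CD2",
     "CE1",
     "CE2",
     "CZ"
    ]
   ],
   "charges": [
    0,
    0
   ],
   "types": [
    "MED",
    "ARO"
   ]
  },
  "TYR": {
   "groups": [
    [
     "CB",
     "CG"
    ],
    [
     "CD1",
     "CD2",
     "CE1",
     "CE2",
     "CZ",
     "OH"
    ]
   ],
   "charges": [
    0,
    0
   ],
   "types": [
    "MED",
    "ARO"
   ]
  },
  "TRP": {
   "groups": [
    [
     "CB",
     "CG"
    ],
    [
     "CD1",
     "CD2",
     "NE1",
     "CE2",
     "CE3",
     "CZ2",
     "CZ3",
     "CH2"
    ]
   ],
   "charges": [
    0,
    0
   ],
   "types": [
    "MED",
    "ARO"
   ]
  }
 }
}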