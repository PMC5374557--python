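{
  "_comment": "Atomic contributions to protein surface tension (cal/(mol*A^2) magnitudes, atomic-solvation-parameter style): per-element defaults plus overrides for formally charged side-chain atoms. A residue's contribution is the sum over its atoms; the complex-level score sums over surface residues.",
  "element": {
    "C": 16.0,
    "N": -6.0,
    "O": -6.0,
    "S": 21.0,
    "P": -6.0
  },
  "charged_overrides": {
    "ASP": {"OD1": -24.0, "OD2": -24.0},
    "GLU": {"OE1": -24.0, "OE2": -24.0},
    "LYS": {"NZ": -50.0},
    "ARG": {"NE": -50.0, "NH1": -50.0, "NH2": -50.0}
  }
}
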