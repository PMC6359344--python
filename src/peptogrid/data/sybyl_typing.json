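{
  "comment": "Tripos SYBYL atom types for the 20 standard L-amino acids using PDB atom naming, plus Bondi element van der Waals radii (Angstrom). Protonation follows standard physiological-pH preparation: charged termini (N.4 amine, O.co2 carboxylate), charged Asp/Glu/Lys/Arg side chains, neutral His. Hydrogens are typed 'H' regardless of name.",
  "radii": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8
  },
  "backbone": {
    "N": "N.am",
    "CA": "C.3",
    "C": "C.2",
    "O": "O.2"
  },
  "nterm": {
    "N": "N.4"
  },
  "cterm": {
    "O": "O.co2",
    "OXT": "O.co2"
  },
  "sidechains": {
    "ALA": {"CB": "C.3"},
    "ARG": {"CB": "C.3", "CG": "C.3", "CD": "C.3", "NE": "N.pl3", "CZ": "C.cat", "NH1": "N.pl3", "NH2": "N.pl3"},
    "ASN": {"CB": "C.3", "CG": "C.2", "OD1": "O.2", "ND2": "N.am"},
    "ASP": {"CB": "C.3", "CG": "C.2", "OD1": "O.co2", "OD2": "O.co2"},
    "CYS": {"CB": "C.3", "SG": "S.3"},
    "GLN": {"CB": "C.3", "CG": "C.3", "CD": "C.2", "OE1": "O.2", "NE2": "N.am"},
    "GLU": {"CB": "C.3", "CG": "C.3", "CD": "C.2", "OE1": "O.co2", "OE2": "O.co2"},
    "GLY": {},
    "HIS": {"CB": "C.3", "CG": "C.ar", "ND1": "N.ar", "CD2": "C.ar", "CE1": "C.ar", "NE2": "N.ar"},
    "ILE": {"CB": "C.3", "CG1": "C.3", "CG2": "C.3", "CD1": "C.3"},
    "LEU": {"CB": "C.3", "CG": "C.3", "CD1": "C.3", "CD2": "C.3"},
    "LYS": {"CB": "C.3", "CG": "C.3", "CD": "C.3", "CE": "C.3", "NZ": "N.4"},
    "MET": {"CB": "C.3", "CG": "C.3", "SD": "S.3", "CE": "C.3"},
    "PHE": {"CB": "C.3", "CG": "C.ar", "CD1": "C.ar", "CD2": "C.ar", "CE1": "C.ar", "CE2": "C.ar", "CZ": "C.ar"},
    "PRO": {"CB": "C.3", "CG": "C.3", "CD": "C.3"},
    "SER": {"CB": "C.3", "OG": "O.3"},
    "THR": {"CB": "C.3", "OG1": "O.3", "CG2": "C.3"},
    "TRP": {"CB": "C.3", "CG": "C.ar", "CD1": "C.ar", "CD2": "C.ar", "NE1": "N.ar", "CE2": "C.ar", "CE3": "C.ar", "CZ2": "C.ar", "CZ3": "C.ar", "CH2": "C.ar"},
    "TYR": {"CB": "C.3", "CG": "C.ar", "CD1": "C.ar", "CD2": "C.ar", "CE1": "C.ar", "CE2": "C.ar", "CZ": "C.ar", "OH": "O.3"},
    "VAL": {"CB": "C.3", "CG1": "C.3", "CG2": "C.3"}
  }
}
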