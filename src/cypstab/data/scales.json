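{
  "version": "1.0",
  "kd_hydropathy": {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
  },
  "average_residue_mass": {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "B": 114.5962, "Z": 128.6231
  },
  "water_mass": 18.0153,
  "pka": {
    "N_TERMINUS": 8.6, "C_TERMINUS": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1
  },
  "acidic_side_chains": ["C", "D", "E", "Y"],
  "basic_side_chains": ["H", "K", "R"],
  "residue_charge": {
    "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5,
    "B": -0.5, "Z": -0.5
  },
  "categories": {
    "Tiny": ["A", "C", "G", "S", "T"],
    "Small": ["A", "B", "C", "D", "G", "N", "P", "S", "T", "V"],
    "Aliphatic": ["I", "L", "V"],
    "Aromatic": ["F", "H", "W", "Y"],
    "Non-polar": ["A", "C", "F", "G", "I", "L", "M", "P", "V", "W", "Y"],
    "Polar": ["D", "E", "H", "K", "N", "Q", "R", "S", "T", "Z"],
    "Charged": ["B", "D", "E", "H", "K", "R", "Z"],
    "Basic": ["H", "K", "R"],
    "Acidic": ["B", "D", "E", "Z"]
  }
}
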