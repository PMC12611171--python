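{
  "_comment": "Average (isotope-abundance-weighted) residue masses in Da for peptide-bond-linked residues; add one water (18.01528 Da) per chain. Monoisotopic masses included for the optional monoisotopic mode. pKa values are EMBOSS-style defaults used by the Henderson-Hasselbalch net-charge model.",
  "water_average": 18.01528,
  "water_monoisotopic": 18.0105646863,
  "average_mass": {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326
  },
  "monoisotopic_mass": {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694, "C": 103.00919,
    "E": 129.04259, "Q": 128.05858, "G": 57.02146, "H": 137.05891, "I": 113.08406,
    "L": 113.08406, "K": 128.09496, "M": 131.04049, "F": 147.06841, "P": 97.05276,
    "S": 87.03203, "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841
  },
  "pka": {
    "n_terminus": 8.6,
    "c_terminus": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1
  },
  "positive_side_chains": ["K", "R", "H"],
  "negative_side_chains": ["D", "E", "C", "Y"]
}
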