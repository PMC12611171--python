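{
  "_comment": "Five-component per-residue descriptor scales. zscale: Sandberg et al. 1998 (J Med Chem 41:2481) extended z-scales z1..z5 (lipophilicity, steric bulk/polarizability, polarity, electronic effects, miscellaneous). tscale: Tian et al. 2007 (J Mol Struct 830:106) topological T1..T5 scores from multidimensional scaling of 2D topological indices.",
  "zscale": {
    "A": [0.24, -2.32, 0.60, -0.14, 1.30],
    "R": [3.52, 2.50, -3.50, 1.99, -0.17],
    "N": [3.05, 1.62, 1.04, -1.15, 1.61],
    "D": [3.98, 0.93, 1.93, -2.46, 0.75],
    "C": [0.84, -1.67, 3.71, 0.18, -2.65],
    "Q": [1.75, 0.50, -1.44, -1.34, 0.66],
    "E": [3.11, 0.26, -0.11, -3.04, -0.25],
    "G": [2.05, -4.06, 0.36, -0.82, -0.38],
    "H": [2.47, 1.95, 0.26, 3.90, 0.09],
    "I": [-3.89, -1.73, -1.71, -0.84, 0.26],
    "L": [-4.28, -1.30, -1.49, -0.72, 0.84],
    "K": [2.29, 0.89, -2.49, 1.49, 0.31],
    "M": [-2.85, -0.22, 0.47, 1.94, -0.98],
    "F": [-4.22, 1.94, 1.06, 0.54, -0.62],
    "P": [-1.66, 0.27, 1.84, 0.70, 2.00],
    "S": [2.39, -1.07, 1.15, -1.39, 0.67],
    "T": [0.75, -2.18, -1.12, -1.46, -0.40],
    "W": [-4.36, 3.94, 0.59, 3.44, -1.59],
    "Y": [-2.54, 2.44, 0.43, 0.04, -1.47],
    "V": [-2.59, -2.64, -1.54, -0.85, -0.02]
  },
  "tscale": {
    "A": [-9.11, -1.63, 0.63, 1.04, 2.26],
    "R": [0.23, 3.89, -1.16, -0.39, -0.06],
    "N": [-4.62, 0.66, 1.16, -0.22, 0.93],
    "D": [-4.65, 0.75, 1.39, -0.40, 1.05],
    "C": [-7.35, -0.86, -0.33, 0.80, 0.98],
    "Q": [-3.00, 1.72, 0.28, -0.39, 0.33],
    "E": [-3.03, 1.82, 0.51, -0.58, 0.43],
    "G": [-10.61, -1.21, -0.12, 0.75, 3.25],
    "H": [-1.01, -1.31, 0.01, -1.81, -0.21],
    "I": [-4.25, -0.28, -0.15, 1.40, -0.21],
    "L": [-4.38, 0.28, -0.49, 1.45, 0.02],
    "K": [-2.59, 2.34, -1.69, 0.41, -0.21],
    "M": [-4.08, 0.98, -2.34, 1.64, -0.79],
    "F": [0.49, -0.94, -0.63, -1.27, -0.44],
    "P": [-5.11, -3.54, -0.53, -0.36, -0.29],
    "S": [-7.44, -0.65, 0.68, -0.17, 1.58],
    "T": [-5.97, -0.62, 1.11, 0.31, 0.95],
    "W": [5.73, -2.67, -0.07, -1.96, -0.54],
    "Y": [2.08, -0.47, -0.07, -1.67, -0.35],
    "V": [-5.87, -0.94, 0.28, 1.10, 0.48]
  }
}
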