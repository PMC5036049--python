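"""Amino-acid alphabets, physicochemical scales and background frequencies.

All per-type arrays are ordered by :data:`AA20` (alphabetical one-letter
codes), the canonical column order used throughout the package.
"""

from __future__ import annotations

import numpy as np

#: Canonical alphabetical one-letter order used for every 20-vector/matrix.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Index of each standard amino acid in :data:`AA20`.
AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

#: PSI-BLAST's native PSSM column order.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenium substitutions mapped to their sulfur parents
    "MSE": "M", "SEC": "C",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k not in ("MSE", "SEC")}

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# net side-chain charge at physiological pH (His partially protonated)
_CHARGE = {
    "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1,
}

# Grantham polarity
_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}

HYDROPATHY = np.array([_KD[a] for a in AA20])
CHARGE = np.array([_CHARGE.get(a, 0.0) for a in AA20])
POLARITY = np.array([_POLARITY[a] for a in AA20])

# Robinson & Robinson amino-acid background frequencies, renormalized.
_RR = {
    "A": 0.0780, "R": 0.0512, "N": 0.0448, "D": 0.0536, "C": 0.0192,
    "Q": 0.0426, "E": 0.0629, "G": 0.0738, "H": 0.0219, "I": 0.0514,
    "L": 0.0901, "K": 0.0574, "M": 0.0224, "F": 0.0385, "P": 0.0520,
    "S": 0.0712, "T": 0.0584, "W": 0.0132, "Y": 0.0321, "V": 0.0644,
}
BACKGROUND = np.array([_RR[a] for a in AA20])
BACKGROUND /= BACKGROUND.sum()

#: Heuristic prior on catalytic propensity (log2 enrichment), reflecting the
#: well-documented over-representation of charged/hydrophilic residues
#: (H, D, R, E, K, C, Y) at enzyme active sites.  Retrain with
#: :func:`crhunter.sequence_features.catalytic_propensity` whenever annotated
#: training data are available; this table is only a fallback.
DEFAULT_CATALYTIC_PROPENSITY = {
    "A": -1.0, "C": 1.3, "D": 1.6, "E": 1.2, "F": -0.7, "G": -0.5,
    "H": 2.4, "I": -1.3, "K": 0.9, "L": -1.5, "M": -0.8, "N": 0.2,
    "P": -1.0, "Q": -0.2, "R": 0.8, "S": 0.1, "T": -0.3, "V": -1.3,
    "W": -0.4, "Y": 0.8,
}

#: Number of side-chain pseudo-atoms used by the synthetic structure
#: generator, roughly proportional to residue volume (1-4, Gly has none).
SIDECHAIN_PSEUDOATOMS = {
    "G": 0, "A": 1, "S": 1, "C": 1, "T": 1, "P": 1, "V": 1,
    "D": 2, "N": 2, "L": 2, "I": 2, "E": 2, "Q": 2, "M": 2,
    "K": 3, "R": 3, "H": 3, "F": 3, "Y": 3, "W": 4,
}
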