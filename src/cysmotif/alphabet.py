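"""Residue alphabets, integer encodings and the Kyte-Doolittle hydropathy scale."""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, in the fixed column order used by every
#: position probability matrix in this package.
AA = "ACDEFGHIKLMNPQRSTVWY"

#: Integer code for a masked/unknown residue (``X``). Masked positions are
#: excluded from motif counts and from candidate motif windows.
MASK_CODE = 20

#: Protein alphabet accepted on input: the 20 standard residues plus ``X``.
PROTEIN_ALPHABET = set(AA) | {"X"}

#: Nucleotide alphabet accepted on input.
DNA_ALPHABET = set("ACGTN")

AA_INDEX = {a: i for i, a in enumerate(AA)}

# Kyte & Doolittle (1982) hydropathy indices.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


def encode_protein(residues: str) -> np.ndarray:
    """Encode a protein string as int8 codes (0-19 per :data:`AA`, 20 = X)."""
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues):
        out[i] = AA_INDEX.get(ch, MASK_CODE)
    return out


def decode_protein(codes: np.ndarray) -> str:
    alpha = AA + "X"
    return "".join(alpha[c] for c in codes)
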