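"""Alphabets, canonical orderings and symbol-level conventions.

All feature spaces in the library use fixed canonical orders:

* amino acids — alphabetical one-letter order ``ACDEFGHIKLMNPQRSTVWY``
  (self-documenting; note this differs from the PSI-BLAST PSSM file
  column order, which is preserved inside :class:`~protfeat.types.PSSMProfile`
  and remapped at the boundary);
* three-state secondary structure — ``H``, ``E``, ``C`` (helix, strand,
  coil), the order fixed by the orthogonal-encoding convention in which
  ``100`` is a helix and ``001`` a coil;
* two-state solvent accessibility — ``b`` (buried), ``e`` (exposed).

Unknown or non-standard residues (``X``, and ``B``, ``Z``, ``U``, ``O``,
``J`` after normalization) are mapped to ``X``; each characterizer defines
its own behaviour for ``X`` explicitly.
"""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError

#: Canonical amino-acid order used for every encoding/composition vector.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Residue alphabet accepted in sequences ('X' = unknown).
AA_ALPHABET = AA_ORDER + "X"

#: Column order of PSI-BLAST ASCII PSSM files.
PSSM_FILE_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Index mapping such that file_row[PSSM_TO_CANONICAL] is in AA_ORDER.
PSSM_TO_CANONICAL = np.array(
    [PSSM_FILE_ORDER.index(aa) for aa in AA_ORDER], dtype=np.intp
)

SS3_ORDER = "HEC"
SA2_ORDER = "be"

#: Non-standard one-letter codes collapsed to 'X' during normalization.
_AMBIGUOUS = set("BZUOJ")

#: DSSP eight-state symbols (blank = loop/irregular).
DSSP8_SYMBOLS = set("HGIEBTS ")

#: Eight-state to three-state collapse (EVA/CASP convention):
#: H,G,I -> helix; E,B -> strand; T,S,blank -> coil.
DSSP8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", " ": "C",
}

#: Maximum solvent accessibility per residue (theoretical upper bounds,
#: Å²), used to convert absolute DSSP accessibility to relative.
MAX_ACC = {
    "A": 129.0, "C": 167.0, "D": 193.0, "E": 223.0, "F": 240.0,
    "G": 104.0, "H": 224.0, "I": 197.0, "K": 236.0, "L": 201.0,
    "M": 224.0, "N": 195.0, "P": 159.0, "Q": 225.0, "R": 274.0,
    "S": 155.0, "T": 172.0, "V": 174.0, "W": 285.0, "Y": 263.0,
}

#: Relative-accessibility threshold calling a residue exposed.
RSA_EXPOSED_THRESHOLD = 0.25


def normalize_residue(symbol: str, *, context: str = "") -> str:
    """Normalize one residue symbol to the library alphabet.

    Upper-cases, collapses ambiguous codes (B/Z/U/O/J) to 'X'.  Raises
    :class:`AlphabetError` for anything else outside the 20+X alphabet.
    """
    up = symbol.upper()
    if up in _AMBIGUOUS:
        return "X"
    if up not in AA_ALPHABET:
        where = f" in {context}" if context else ""
        raise AlphabetError(f"illegal residue symbol {symbol!r}{where}")
    return up


def normalize_sequence(sequence: str, *, context: str = "") -> str:
    """Normalize a whole sequence (see :func:`normalize_residue`)."""
    return "".join(normalize_residue(ch, context=context) for ch in sequence)


def dssp8_to_ss3(ss8: str) -> str:
    """Collapse a DSSP 8-state symbol to H/E/C."""
    try:
        return DSSP8_TO_SS3[ss8]
    except KeyError:
        raise AlphabetError(f"not a DSSP 8-state symbol: {ss8!r}") from None


def relative_accessibility(aa: str, acc: float) -> float:
    """Absolute accessibility (Å²) to relative accessibility in [0, ~1+]."""
    aa = normalize_residue(aa)
    if aa == "X":
        denom = float(np.mean(list(MAX_ACC.values())))
    else:
        denom = MAX_ACC[aa]
    return acc / denom


def sa_two_class(aa: str, acc: float) -> str:
    """Call a residue buried ('b') or exposed ('e') at 25% relative accessibility."""
    return "e" if relative_accessibility(aa, acc) >= RSA_EXPOSED_THRESHOLD else "b"
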