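"""Orthogonal (one-hot) encodings of residue and annotation symbols.

Each legal symbol maps to a fixed-length 0/1 vector with a single 1, so no
artificial ordering is imposed on the categories: residues occupy 20
dimensions (alphabetical order), three-state secondary structure 3
dimensions (H, E, C — helix is ``100``, coil ``001``), two-state solvent
accessibility 2 dimensions (b, e).  The unknown residue ``X`` encodes to
the all-zero length-20 vector, keeping the 20-dimension contract.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .alphabets import AA_ORDER, SA2_ORDER, SS3_ORDER, normalize_residue
from .errors import AlphabetError
from .types import AnnotationString

__all__ = ["hot_encode_aa", "hot_encode_ss", "hot_encode_sa", "encode_string"]


def _one_hot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[index] = 1.0
    return v


def hot_encode_aa(aa: str) -> np.ndarray:
    """One-hot encode a residue into 20 dimensions ('X' -> all zeros)."""
    aa = normalize_residue(aa)
    if aa == "X":
        return np.zeros(20)
    return _one_hot(AA_ORDER.index(aa), 20)


def hot_encode_ss(ss: str) -> np.ndarray:
    """One-hot encode an H/E/C secondary-structure symbol into 3 dimensions."""
    if ss not in SS3_ORDER:
        raise AlphabetError(f"not a 3-state secondary-structure symbol: {ss!r}")
    return _one_hot(SS3_ORDER.index(ss), 3)


def hot_encode_sa(sa: str) -> np.ndarray:
    """One-hot encode a buried/exposed symbol into 2 dimensions."""
    if sa not in SA2_ORDER:
        raise AlphabetError(f"not a buried/exposed symbol: {sa!r}")
    return _one_hot(SA2_ORDER.index(sa), 2)


_ENCODERS = {"AA20": hot_encode_aa, "SS3": hot_encode_ss, "SA2": hot_encode_sa}


def encode_string(
    s: Union[str, AnnotationString], space: str | None = None
) -> np.ndarray:
    """Encode a whole string element-wise; returns a (length, width) array.

    ``space`` is one of ``"AA20"``, ``"SS3"``, ``"SA2"``; it may be omitted
    for an :class:`AnnotationString`, whose kind determines it.  Alphabet
    errors are re-raised with the offending position.
    """
    if isinstance(s, AnnotationString):
        space = space or s.kind
        s = s.symbols
    if space not in _ENCODERS:
        raise AlphabetError(f"unknown encoding space {space!r}")
    encode = _ENCODERS[space]
    width = {"AA20": 20, "SS3": 3, "SA2": 2}[space]
    out = np.zeros((len(s), width))
    for i, symbol in enumerate(s):
        try:
            out[i] = encode(symbol)
        except AlphabetError as exc:
            raise AlphabetError(f"position {i}: {exc}") from None
    return out
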