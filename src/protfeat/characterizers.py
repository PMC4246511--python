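"""Numerical characterization of residues, pairs, strings and profile columns.

This module turns symbolic protein data into real numbers:

* per-residue lookups — Atchley factors, hydrophobicity, and two
  residue-pair contact potentials (interface and cross-strand beta
  pairing), each with an optional min-max rescale to [0, 1];
* whole-string content — amino-acid / secondary-structure /
  solvent-accessibility composition vectors;
* profile columns — per-position residue frequencies and information
  content (in bits) from an anchored MSA or a PSI-BLAST PSSM;
* generic vector measures — Shannon entropy, Pearson correlation, cosine
  similarity, and the generalized (power) mean of order ``n`` over a
  string's scaled per-symbol values.

Unknown-residue convention, library-wide: ``'X'`` gets all-zero Atchley
factors, the table mean for potentials and hydrophobicity, and is excluded
from composition denominators.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence, Union

import numpy as np
from scipy import stats
from scipy.spatial import distance as _distance

from .alphabets import AA_ORDER, SA2_ORDER, SS3_ORDER, normalize_residue
from .errors import DomainError, UndefinedCorrelationError
from .tables import LookupTable, load_table
from .types import (
    AnchoredMSA,
    AnnotationString,
    ColumnProfile,
    CompositionVector,
    PSSMProfile,
)

__all__ = [
    "atchley_factors",
    "interface_contact_potential",
    "beta_contact_potential",
    "hydrophobicity",
    "aa_composition",
    "ss_composition",
    "sa_composition",
    "column_profiles",
    "pssm_column_profiles",
    "calculate_entropy",
    "calculate_r",
    "calculate_cosine",
    "scaled_ordered_mean",
    "logistic",
]

_LOG2_20 = math.log2(20)


# ---------------------------------------------------------------------------
# table-backed residue characterizers

def _check_standard(aa: str) -> str:
    aa = normalize_residue(aa)
    return aa


def atchley_factors(aa: str, scaled: bool = False) -> np.ndarray:
    """Five physicochemical factor values for a residue.

    ``'X'`` returns five zeros.  With ``scaled=True`` each of the five
    dimensions is min-max rescaled to [0, 1] over the 20 standard residues,
    so the per-dimension extreme residues map to exactly 0 and 1.
    """
    aa = _check_standard(aa)
    if aa == "X":
        return np.zeros(5)
    table = load_table("atchley")
    values = np.array(table.entries[aa], dtype=float)
    if not scaled:
        return values
    all_rows = np.array([table.entries[r] for r in AA_ORDER], dtype=float)
    lo, hi = all_rows.min(axis=0), all_rows.max(axis=0)
    return (values - lo) / (hi - lo)


def _pair_potential(table: LookupTable, a: str, b: str, scaled: bool) -> float:
    a, b = _check_standard(a), _check_standard(b)
    if a == "X" or b == "X":
        value = table.mean_value
    else:
        value = table.pair(a, b)
    if scaled:
        lo, hi = table.value_range
        value = (value - lo) / (hi - lo)
    return float(value)


def interface_contact_potential(a: str, b: str, scaled: bool = False) -> float:
    """Contact potential for an unordered residue pair at an interface.

    Symmetric in its arguments; a pair involving ``'X'`` returns the mean
    over all 210 table entries.  ``scaled=True`` min-max rescales over the
    table's value range.
    """
    return _pair_potential(load_table("interface_contact"), a, b, scaled)


def beta_contact_potential(a: str, b: str, scaled: bool = False) -> float:
    """Cross-strand pairing potential for a residue pair in a beta sheet.

    Same contract as :func:`interface_contact_potential`.
    """
    return _pair_potential(load_table("beta_contact"), a, b, scaled)


def hydrophobicity(aa: str, scaled: bool = False) -> float:
    """Side-chain hydrophobicity of a residue ('X' -> scale mean)."""
    aa = _check_standard(aa)
    table = load_table("hydrophobicity")
    value = table.mean_value if aa == "X" else table.entries[aa]
    if scaled:
        lo, hi = table.value_range
        value = (value - lo) / (hi - lo)
    return float(value)


# ---------------------------------------------------------------------------
# compositions

def aa_composition(seq: str) -> CompositionVector:
    """Fraction of each of the 20 residues in a sequence.

    The denominator counts non-'X' residues only, so unknowns neither
    contribute to nor dilute the composition.
    """
    if not seq:
        raise DomainError("cannot compute composition of an empty sequence")
    seq = "".join(normalize_residue(c, context="composition input") for c in seq)
    counted = [c for c in seq if c != "X"]
    if not counted:
        raise DomainError("sequence contains only unknown residues")
    counts = np.array([counted.count(aa) for aa in AA_ORDER], dtype=float)
    return CompositionVector(space="AA20", fractions=counts / len(counted))


def _annotation_composition(s: AnnotationString, kind: str, order: str) -> CompositionVector:
    if s.kind != kind:
        raise DomainError(f"expected a {kind} annotation, got {s.kind}")
    if len(s) == 0:
        raise DomainError("cannot compute composition of an empty annotation")
    counts = np.array([s.symbols.count(c) for c in order], dtype=float)
    return CompositionVector(space=kind, fractions=counts / len(s))


def ss_composition(ss: AnnotationString) -> CompositionVector:
    """Fraction of helix, strand and coil in a secondary-structure string."""
    return _annotation_composition(ss, "SS3", SS3_ORDER)


def sa_composition(sa: AnnotationString) -> CompositionVector:
    """Fraction of buried and exposed residues in an accessibility string."""
    return _annotation_composition(sa, "SA2", SA2_ORDER)


# ---------------------------------------------------------------------------
# profile columns

def column_profiles(msa: AnchoredMSA) -> list[ColumnProfile]:
    """Per-column residue frequencies and information content of an MSA.

    Frequencies are over non-gap residues of the column ('X' counts as a
    residue but carries no frequency mass of its own — it is dropped from
    the 20-way count); information = log2(20) − H(frequencies) in bits, so
    a perfectly conserved column scores log2(20) ≈ 4.32 and a uniformly
    diverged one 0.
    """
    profiles = []
    n_rows = msa.n_rows
    for j in range(len(msa)):
        column = [row[j] for row in msa.rows]
        gaps = column.count("-")
        residues = [c for c in column if c not in "-X"]
        if not residues:
            raise DomainError(
                f"column {j} has no countable residues (gapless query expected)"
            )
        counts = np.array([residues.count(aa) for aa in AA_ORDER], dtype=float)
        freqs = counts / counts.sum()
        info = _LOG2_20 - calculate_entropy(freqs)
        profiles.append(
            ColumnProfile(
                position=j,
                frequencies=freqs,
                gap_fraction=gaps / n_rows,
                information=max(0.0, info),
            )
        )
    return profiles


def pssm_column_profiles(pssm: PSSMProfile) -> list[ColumnProfile]:
    """Per-position profiles from a PSSM's weighted observed percentages.

    Frequencies are the percentage rows normalized to sum 1 (canonical
    residue order); the information value is taken directly from the file's
    per-position information column rather than recomputed, because
    PSI-BLAST's estimate uses sequence weighting the percentages alone
    cannot reproduce.  An all-zero percentage row falls back to the uniform
    distribution with a warning.
    """
    pct = pssm.percentages_canonical()
    profiles = []
    for j in range(pssm.length):
        row = pct[j]
        total = row.sum()
        if total <= 0:
            warnings.warn(
                f"PSSM position {j}: all-zero percentage row, using uniform frequencies",
                stacklevel=2,
            )
            freqs = np.full(20, 1.0 / 20.0)
        else:
            freqs = row / total
        profiles.append(
            ColumnProfile(
                position=j,
                frequencies=freqs,
                gap_fraction=0.0,
                information=min(float(pssm.information[j]), _LOG2_20),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# vector measures

def calculate_entropy(p: Sequence[float]) -> float:
    """Shannon entropy of a probability vector, in bits (0·log 0 ≡ 0)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise DomainError("entropy of an empty vector is undefined")
    if np.any(arr < 0):
        raise DomainError("probabilities must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-6:
        raise DomainError(f"probabilities must sum to 1 (got {arr.sum():.8f})")
    nz = arr[arr > 0]
    return float(-(nz * np.log2(nz)).sum())


def calculate_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient between two feature vectors.

    A zero-variance input raises :class:`UndefinedCorrelationError` rather
    than silently returning 0 or NaN.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DomainError("correlation needs two equal-length 1-D vectors")
    if xa.size < 2:
        raise DomainError("correlation needs at least two elements")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError(
            "correlation is undefined for a constant vector"
        )
    return float(stats.pearsonr(xa, ya).statistic)


def calculate_cosine(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine similarity dot(x,y)/(|x||y|) between two feature vectors."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size == 0:
        raise DomainError("cosine needs two equal-length non-empty 1-D vectors")
    if np.linalg.norm(xa) == 0 or np.linalg.norm(ya) == 0:
        raise DomainError("cosine is undefined for a zero vector")
    return float(1.0 - _distance.cosine(xa, ya))


def logistic(x):
    """Logistic squash 1/(1+e^{-x}); maps unbounded log-odds into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# ordered (power) mean

def _symbol_values(s: str, scale: str) -> np.ndarray:
    """Scaled-to-[0,1] numeric value per symbol of a string.

    Secondary-structure strings use the fixed class positions H=0, E=1/2,
    C=1; accessibility strings b=0, e=1.  Amino-acid strings use the
    hydrophobicity scale or one Atchley dimension (``"atchley1"`` ..
    ``"atchley5"``), min-max scaled.
    """
    symbols = set(s)
    if symbols <= set(SS3_ORDER):
        lut = {c: SS3_ORDER.index(c) / (len(SS3_ORDER) - 1) for c in SS3_ORDER}
        return np.array([lut[c] for c in s])
    if symbols <= set(SA2_ORDER):
        lut = {c: float(SA2_ORDER.index(c)) for c in SA2_ORDER}
        return np.array([lut[c] for c in s])
    if scale == "hydrophobicity":
        return np.array([hydrophobicity(c, scaled=True) for c in s])
    if scale.startswith("atchley"):
        try:
            dim = int(scale[len("atchley"):]) - 1
        except ValueError:
            raise DomainError(f"unknown scale {scale!r}") from None
        if not 0 <= dim < 5:
            raise DomainError(f"Atchley dimension out of range in {scale!r}")
        return np.array([atchley_factors(c, scaled=True)[dim] for c in s])
    raise DomainError(f"unknown scale {scale!r} for amino-acid strings")


def scaled_ordered_mean(
    s: Union[str, AnnotationString], n: int, scale: str = "hydrophobicity"
) -> float:
    """Generalized (power) mean of order ``n`` over a string's scaled values.

    Each symbol is mapped to a number in [0, 1] (see ``scale``); the result
    is ``(mean(v_i**n))**(1/n)``.  Order 1 is the arithmetic mean and the
    result is non-decreasing in ``n`` (power-mean inequality).
    """
    if isinstance(s, AnnotationString):
        s = s.symbols
    if not s:
        raise DomainError("ordered mean of an empty string is undefined")
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise DomainError("order n must be a positive integer")
    values = _symbol_values(s, scale)
    return float(np.mean(values ** n) ** (1.0 / n))
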