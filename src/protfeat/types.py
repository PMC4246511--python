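"""Domain types shared across the library.

These are plain frozen dataclasses with validation in ``__post_init__``:
a record is either constructed valid or not at all.  Residue indices are
0-based everywhere inside the library; file formats keep their native
1-based indices at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabets import (
    AA_ALPHABET,
    DSSP8_SYMBOLS,
    PSSM_TO_CANONICAL,
    SA2_ORDER,
    SS3_ORDER,
    normalize_sequence,
)
from .errors import AlphabetError, DomainError


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus an amino-acid sequence.

    The sequence is normalized on construction: upper-cased, ambiguous
    codes collapsed to 'X'.  It is the root input of every pipeline.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise DomainError(f"record {self.id!r}: empty sequence")
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, context=f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationString:
    """A per-residue classification string.

    ``kind`` is ``"SS3"`` (symbols over H/E/C) or ``"SA2"`` (symbols over
    b/e).  When paired with a :class:`ProteinRecord` the lengths must match;
    that pairing check belongs to the caller.
    """

    kind: str
    symbols: str

    def __post_init__(self) -> None:
        alphabets = {"SS3": set(SS3_ORDER), "SA2": set(SA2_ORDER)}
        if self.kind not in alphabets:
            raise DomainError(f"unknown annotation kind {self.kind!r}")
        bad = set(self.symbols) - alphabets[self.kind]
        if bad:
            raise AlphabetError(
                f"illegal {self.kind} symbol(s) {sorted(bad)!r} in annotation"
            )

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True, eq=False)
class PSSMProfile:
    """A PSI-BLAST position-specific scoring matrix.

    ``log_odds`` and ``percentages`` keep the source file's column order
    (A R N D C Q E G H I L K M F P S T W Y V); use
    :meth:`log_odds_canonical` / :meth:`percentages_canonical` for the
    library's alphabetical order.  ``information`` is the per-position
    information content column, in bits.
    """

    residues: str
    log_odds: np.ndarray
    percentages: np.ndarray
    information: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        pc = np.asarray(self.percentages, dtype=float)
        info = np.asarray(self.information, dtype=float)
        n = len(self.residues)
        if lo.shape != (n, 20) or pc.shape != (n, 20):
            raise DomainError(
                f"PSSM matrices must be {n}x20; got {lo.shape} and {pc.shape}"
            )
        if info.shape != (n,):
            raise DomainError(f"information vector must have length {n}")
        if np.any(info < 0):
            raise DomainError("per-position information must be >= 0")
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "percentages", pc)
        object.__setattr__(self, "information", info)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PSSMProfile):
            return NotImplemented
        return (
            self.residues == other.residues
            and np.array_equal(self.log_odds, other.log_odds)
            and np.array_equal(self.percentages, other.percentages)
            and np.array_equal(self.information, other.information)
        )

    def log_odds_canonical(self) -> np.ndarray:
        """Log-odds matrix with columns remapped to alphabetical AA order."""
        return self.log_odds[:, PSSM_TO_CANONICAL]

    def percentages_canonical(self) -> np.ndarray:
        """Percentage matrix with columns remapped to alphabetical AA order."""
        return self.percentages[:, PSSM_TO_CANONICAL]


@dataclass(frozen=True)
class AnchoredMSA:
    """A query-anchored alignment: columns map one-to-one to query residues.

    Row 0 is the (gapless) query; every row has exactly the query's length,
    over the residue alphabet plus ``-`` for gaps.
    """

    query: ProteinRecord
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        if not rows:
            raise DomainError("an anchored MSA needs at least the query row")
        n = len(self.query.sequence)
        for i, row in enumerate(rows):
            if len(row) != n:
                raise DomainError(
                    f"MSA row {i} has length {len(row)}, query has {n}"
                )
            bad = set(row) - set(AA_ALPHABET + "-")
            if bad:
                raise AlphabetError(f"illegal symbol(s) {sorted(bad)!r} in MSA row {i}")
        if "-" in rows[0]:
            raise DomainError("query row of an anchored MSA must be gapless")
        object.__setattr__(self, "rows", rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def __len__(self) -> int:
        return len(self.query.sequence)


@dataclass(frozen=True)
class DSSPRecord:
    """One residue line of classic DSSP output."""

    residue_index: int  # 1-based position from the file
    chain: str
    aa: str
    ss8: str  # one of H,G,I,E,B,T,S or ' ' (loop)
    acc: int  # absolute accessibility, Å²

    def __post_init__(self) -> None:
        if self.ss8 not in DSSP8_SYMBOLS:
            raise AlphabetError(f"not a DSSP 8-state symbol: {self.ss8!r}")
        if self.acc < 0:
            raise DomainError("DSSP accessibility must be non-negative")


@dataclass(frozen=True, eq=False)
class SSPrediction:
    """A per-residue prediction read from SSpro/ACCpro or a PSIPRED .ss2 file.

    ``annotation`` is SS3 for secondary-structure predictors and SA2 for
    accessibility predictors.  ``probabilities`` (rows in coil, helix,
    strand order) is present only for PSIPRED-style input.
    """

    residues: str
    annotation: AnnotationString
    probabilities: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.annotation.symbols):
            raise DomainError(
                f"sequence length {len(self.residues)} != "
                f"prediction length {len(self.annotation.symbols)}"
            )
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (len(self.residues), 3):
                raise DomainError("probability matrix must be length x 3")
            object.__setattr__(self, "probabilities", p)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SSPrediction):
            return NotImplemented
        if self.residues != other.residues or self.annotation != other.annotation:
            return False
        if (self.probabilities is None) != (other.probabilities is None):
            return False
        return self.probabilities is None or np.array_equal(
            self.probabilities, other.probabilities
        )

    @property
    def ss3(self) -> AnnotationString:
        """The annotation, provided it is a secondary-structure prediction."""
        if self.annotation.kind != "SS3":
            raise DomainError("prediction is not a secondary-structure prediction")
        return self.annotation

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CompositionVector:
    """Fractional content of a string over one feature space.

    ``fractions`` follows the canonical order of the space (AA20
    alphabetical, SS3 = H,E,C, SA2 = b,e) and sums to 1 for legal input.
    """

    space: str
    fractions: np.ndarray

    _WIDTHS = {"AA20": 20, "SS3": 3, "SA2": 2}

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if self.space not in self._WIDTHS:
            raise DomainError(f"unknown composition space {self.space!r}")
        if f.shape != (self._WIDTHS[self.space],):
            raise DomainError(
                f"{self.space} composition must have {self._WIDTHS[self.space]} entries"
            )
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise DomainError("composition fractions must be >= 0 and sum to 1")
        object.__setattr__(self, "fractions", f)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue-frequency profile of one alignment (or PSSM) column.

    ``frequencies`` is over the 20 residues in alphabetical order and sums
    to 1 over non-gap residues; ``information`` = log2(20) minus the
    Shannon entropy of the frequencies, in bits, so conserved columns score
    high.
    """

    position: int  # 0-based
    frequencies: np.ndarray
    gap_fraction: float
    information: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (20,):
            raise DomainError("column frequencies must have 20 entries")
        if abs(f.sum() - 1.0) > 1e-9:
            raise DomainError("column frequencies must sum to 1")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise DomainError("gap fraction must lie in [0, 1]")
        if not -1e-9 <= self.information <= np.log2(20) + 1e-9:
            raise DomainError("column information must lie in [0, log2(20)] bits")
        object.__setattr__(self, "frequencies", f)


@dataclass(frozen=True)
class FeatureExample:
    """A label/target plus an ordered feature vector: one ML example."""

    label: float
    features: tuple[float, ...]
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        feats = tuple(float(v) for v in self.features)
        if not feats:
            raise DomainError("a feature example needs at least one feature")
        if not np.isfinite(self.label):
            raise DomainError("label must be finite")
        bad = [i for i, v in enumerate(feats) if not np.isfinite(v)]
        if bad:
            raise DomainError(f"non-finite feature value at index {bad[0]}")
        object.__setattr__(self, "features", feats)
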