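"""Parsers for the six input dialects the library understands.

FASTA, query-anchored plain-text MSAs, PSI-BLAST ASCII PSSMs
(the ``-out_ascii_pssm`` dialect), classic DSSP output, SSpro/ACCpro flat
predictions and PSIPRED ``.ss2`` files are each read into the domain types
of :mod:`protfeat.types`.  Parsers are pure functions of file content and
raise :class:`~protfeat.errors.FileFormatError` with a line number when the
text does not match its dialect.

Notes on dialects
-----------------
* The anchored-MSA dialect is one aligned sequence per line, the gapless
  query first, all lines of equal length, ``-`` for gaps.
* Only PSIPRED's vertical ``.ss2`` form is parsed (it is the
  machine-readable one and carries the class probabilities); the
  human-readable ``.horiz`` form is not.
* SSpro secondary-structure and ACCpro accessibility outputs share one
  two-line layout; the parser tells them apart by the prediction string's
  alphabet, which is unambiguous under case sensitivity.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Union

import numpy as np

from .alphabets import normalize_sequence
from .errors import FileFormatError
from .types import (
    AnchoredMSA,
    AnnotationString,
    DSSPRecord,
    ProteinRecord,
    PSSMProfile,
    SSPrediction,
)

PathLike = Union[str, os.PathLike]

__all__ = [
    "parse_fasta_sequences",
    "parse_ascii_pssm",
    "parse_anchored_msa",
    "parse_dssp_output",
    "parse_sspro_output",
    "parse_psipred_output",
]


def _read_text(path_or_text: Union[PathLike, str], *, literal_ok: bool = False) -> str:
    """Return file content, or the argument itself for raw FASTA text.

    A plain string is taken as raw text when it starts with '>' or spans
    several lines; otherwise it is tried as a path, falling back to raw
    text (which the FASTA parser will then reject with a format error).
    """
    if isinstance(path_or_text, os.PathLike):
        return Path(path_or_text).read_text()
    if literal_ok:
        looks_like_text = path_or_text.lstrip().startswith(">") or "\n" in path_or_text
        if not looks_like_text:
            try:
                return Path(path_or_text).read_text()
            except (OSError, ValueError):
                return path_or_text
        return path_or_text
    return Path(path_or_text).read_text()


def parse_fasta_sequences(path_or_text: Union[PathLike, str]) -> list[ProteinRecord]:
    """Parse FASTA text (a path, or the raw text itself) into records.

    One :class:`ProteinRecord` per ``>`` header, in file order.  Multi-line
    sequences are concatenated, whitespace inside sequence lines stripped,
    lower-case residues upper-cased.  The id is the header text up to the
    first whitespace.
    """
    text = _read_text(path_or_text, literal_ok=True)
    records: list[ProteinRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FileFormatError(f"record {current_id!r} has no sequence")
        records.append(ProteinRecord(id=current_id, sequence=seq))

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            current_id = header.split()[0] if header else ""
            chunks = []
        else:
            if current_id is None:
                raise FileFormatError("sequence data before first FASTA header")
            chunks.append("".join(line.split()))
    flush()
    if not records:
        raise FileFormatError("no FASTA records found (empty input?)")
    return records


def parse_ascii_pssm(path: PathLike) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file.

    The file carries, per query position, 20 log-odds integers, 20 weighted
    observed percentages, the per-position information (bits) and a relative
    weight; both 20-column blocks and the information column are retained.
    Footer statistics lines (lambda/K) are ignored.
    """
    lines = Path(path).read_text().splitlines()

    header_idx = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) == 40 and all(len(t) == 1 and t.isalpha() for t in tokens):
            header_idx = i
            break
    if header_idx is None:
        raise FileFormatError("no PSSM column-label line with 40 residue letters found")

    residues: list[str] = []
    log_odds: list[list[int]] = []
    percentages: list[list[int]] = []
    information: list[float] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        fields = line.split()
        if not fields:
            break  # blank line ends the data block; footer follows
        if not fields[0].isdigit():
            break  # footer statistics reached without a blank separator
        if len(fields) < 42:
            raise FileFormatError(
                f"line {lineno}: PSSM row has {len(fields)} fields, expected >= 42"
            )
        pos = int(fields[0])
        if pos != expected_pos:
            raise FileFormatError(
                f"line {lineno}: non-contiguous position index {pos} "
                f"(expected {expected_pos})"
            )
        expected_pos += 1
        residues.append(fields[1])
        try:
            row = [int(v) for v in fields[2:42]]
            info = float(fields[42]) if len(fields) > 42 else 0.0
        except ValueError as exc:
            raise FileFormatError(f"line {lineno}: unparsable PSSM field ({exc})") from None
        log_odds.append(row[:20])
        percentages.append(row[20:40])
        information.append(info)

    if not residues:
        raise FileFormatError("PSSM file contains no data rows")
    return PSSMProfile(
        residues=normalize_sequence("".join(residues), context="PSSM"),
        log_odds=np.array(log_odds, dtype=float),
        percentages=np.array(percentages, dtype=float),
        information=np.array(information, dtype=float),
    )


def parse_anchored_msa(path: PathLike) -> AnchoredMSA:
    """Parse a query-anchored MSA: query first, equal-length rows, '-' gaps."""
    rows = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if not rows:
        raise FileFormatError("empty MSA file")
    rows = [row.upper() for row in rows]
    n = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != n:
            raise FileFormatError(
                f"MSA line {i + 1} has length {len(row)}, expected {n}"
            )
    if "-" in rows[0]:
        raise FileFormatError("query (first) line of an anchored MSA may not contain gaps")
    query = ProteinRecord(id="query", sequence=rows[0])
    # rebuild row 0 from the normalized query so ambiguity codes stay in sync
    normalized = (query.sequence,) + tuple(
        "".join("-" if c == "-" else normalize_sequence(c, context=f"MSA row {i}")
                for c in row)
        for i, row in enumerate(rows[1:], start=1)
    )
    return AnchoredMSA(query=query, rows=normalized)


_DSSP_SENTINEL = "  #  RESIDUE"


def parse_dssp_output(path: PathLike) -> list[DSSPRecord]:
    """Parse classic DSSP text output into per-residue records.

    Data start after the ``  #  RESIDUE`` header; chain-break lines
    (residue letter ``!``) are skipped.  Extraction is fixed-column:
    AA at column 14, SS at column 17, ACC at columns 35-38 (1-based).
    """
    lines = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith(_DSSP_SENTINEL):
            start = i + 1
            break
    if start is None:
        raise FileFormatError("missing DSSP header line starting with '  #  RESIDUE'")

    records: list[DSSPRecord] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        padded = line.ljust(38)
        aa = padded[13]
        if aa == "!":
            continue  # chain break
        try:
            residue_index = int(padded[5:10])
            acc = int(padded[34:38])
        except ValueError:
            raise FileFormatError(
                f"line {lineno}: unparsable residue-number/ACC field in DSSP row"
            ) from None
        records.append(
            DSSPRecord(
                residue_index=residue_index,
                chain=padded[11],
                aa=normalize_sequence(aa, context=f"DSSP line {lineno}"),
                ss8=padded[16],
                acc=acc,
            )
        )
    if not records:
        raise FileFormatError("DSSP file contains no residue records")
    return records


_SS3_SET = set("HEC")
_SA_SET = set("eb-")


def parse_sspro_output(path: PathLike, kind: str | None = None) -> SSPrediction:
    """Parse SSpro/ACCpro flat output: comments, sequence line, prediction line.

    The prediction alphabet decides the kind: H/E/C means a
    secondary-structure prediction (SS3), lowercase ``e`` with ``-`` or
    ``b`` means an accessibility prediction (ACCpro's ``-`` maps to buried
    ``b``).  Pass ``kind`` ("SS3"/"SA2") to override the inference.
    """
    lines = [
        line.rstrip("\n")
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if len(lines) < 2:
        raise FileFormatError("expected a sequence line and a prediction line")
    seq_line, pred_line = lines[0].strip(), lines[1].strip()
    if len(seq_line) != len(pred_line):
        raise FileFormatError(
            f"sequence length {len(seq_line)} != prediction length {len(pred_line)}"
        )
    symbols = set(pred_line)
    if kind is None:
        if symbols <= _SS3_SET:
            kind = "SS3"
        elif symbols <= _SA_SET:
            kind = "SA2"
        else:
            raise FileFormatError(
                f"prediction alphabet {sorted(symbols)!r} matches neither "
                "secondary structure (H/E/C) nor accessibility (e/b/-)"
            )
    if kind == "SA2":
        pred_line = pred_line.replace("-", "b")
    annotation = AnnotationString(kind=kind, symbols=pred_line)
    return SSPrediction(
        residues=normalize_sequence(seq_line, context="SSpro sequence line"),
        annotation=annotation,
    )


def parse_psipred_output(path: PathLike) -> SSPrediction:
    """Parse a PSIPRED vertical ``.ss2`` file.

    Rows are ``idx aa ss p_coil p_helix p_strand``; the probability matrix
    is kept in (coil, helix, strand) column order.  A row whose
    probabilities do not sum to 1 within 0.02 triggers a warning but is
    kept (source files print only 3 decimals).
    """
    residues: list[str] = []
    ss: list[str] = []
    probs: list[tuple[float, float, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) != 6:
            raise FileFormatError(
                f"line {lineno}: expected 6 fields 'idx aa ss pC pH pE', got {len(fields)}"
            )
        try:
            p = (float(fields[3]), float(fields[4]), float(fields[5]))
        except ValueError:
            raise FileFormatError(f"line {lineno}: unparsable probability field") from None
        if abs(sum(p) - 1.0) > 0.02:
            warnings.warn(
                f"line {lineno}: class probabilities sum to {sum(p):.3f}, keeping row",
                stacklevel=2,
            )
        residues.append(fields[1])
        ss.append(fields[2])
        probs.append(p)
    if not residues:
        raise FileFormatError(".ss2 file contains no prediction rows")
    return SSPrediction(
        residues=normalize_sequence("".join(residues), context=".ss2"),
        annotation=AnnotationString(kind="SS3", symbols="".join(ss)),
        probabilities=np.array(probs, dtype=float),
    )
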