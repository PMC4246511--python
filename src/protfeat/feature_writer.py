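"""Serialize labeled feature vectors to text files for ML tools.

Two dialects are produced, both one example per line with the target
first:

* numbered — the SVM^light grammar ``<label> <i>:<v> <i>:<v> ...`` with
  1-based strictly ascending indices, optionally sparse (zero-valued
  features omitted) and optionally followed by ``# comment``;
* unnumbered — dense whitespace-delimited values, for tools that expect a
  plain numeric matrix.

The reader :func:`parse_feature_file` understands both, which gives a
round-trip oracle: write → parse → write is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import math

from .errors import DomainError, FileFormatError
from .types import FeatureExample

PathLike = Union[str, os.PathLike]

__all__ = ["WriterConfig", "format_example", "write_features", "parse_feature_file"]


@dataclass(frozen=True)
class WriterConfig:
    """Controls the output dialect.

    ``numbered`` emits ``index:value`` pairs (SVM^light convention,
    1-based); ``sparse`` additionally omits zero-valued features and only
    applies when numbered.  ``precision`` is the number of decimal places
    printed (6 keeps [0,1]-scaled features lossless enough while staying
    diffable).
    """

    numbered: bool = True
    sparse: bool = False
    precision: int = 6
    delimiter: str = " "
    index_base: int = 1

    def __post_init__(self) -> None:
        if self.precision < 0:
            raise DomainError("precision must be >= 0")
        if self.numbered and self.index_base != 1:
            raise DomainError("numbered output uses 1-based indices")


def _format_label(label: float) -> str:
    if float(label).is_integer():
        return str(int(label))
    return f"{label:g}"


def format_example(ex: FeatureExample, cfg: WriterConfig = WriterConfig()) -> str:
    """Format one example as a single output line (no trailing newline)."""
    for i, v in enumerate(ex.features):
        if not math.isfinite(v):
            raise DomainError(f"non-finite feature value at index {i}")
    parts = [_format_label(ex.label)]
    if cfg.numbered:
        for i, v in enumerate(ex.features, start=cfg.index_base):
            if cfg.sparse and v == 0.0:
                continue
            parts.append(f"{i}:{v:.{cfg.precision}f}")
        line = cfg.delimiter.join(parts)
        if ex.comment:
            line += f" # {ex.comment}"
        return line
    parts.extend(f"{v:.{cfg.precision}f}" for v in ex.features)
    return cfg.delimiter.join(parts)


def write_features(
    examples: Iterable[FeatureExample],
    cfg: WriterConfig = WriterConfig(),
    path: PathLike = "features.txt",
) -> int:
    """Write one line per example; returns the number of lines written.

    Overwrites an existing file.  An empty example list is an error — a
    feature file with no examples is almost certainly a pipeline bug.
    """
    examples = list(examples)
    if not examples:
        raise DomainError("refusing to write an empty feature file")
    lines = [format_example(ex, cfg) for ex in examples]
    Path(path).write_text("\n".join(lines) + "\n")
    return len(lines)


def _parse_number(token: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FileFormatError(f"line {lineno}: unparsable number {token!r}") from None


def parse_feature_file(path: PathLike) -> list[FeatureExample]:
    """Read a feature file in either dialect back into examples.

    In sparse numbered lines, indices missing below the line's maximum
    index are filled with 0.  Duplicate or decreasing indices are format
    errors.
    """
    examples: list[FeatureExample] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        comment = raw.split("#", 1)[1].strip() if "#" in raw else None
        if not line:
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise FileFormatError(f"line {lineno}: expected a label and features")
        label = _parse_number(tokens[0], lineno)
        if ":" in tokens[1]:
            pairs: list[tuple[int, float]] = []
            last = 0
            for tok in tokens[1:]:
                if ":" not in tok:
                    raise FileFormatError(
                        f"line {lineno}: mixed numbered/bare feature tokens"
                    )
                idx_s, val_s = tok.split(":", 1)
                idx = int(idx_s)
                if idx <= last:
                    raise FileFormatError(
                        f"line {lineno}: feature indices must be strictly increasing "
                        f"(saw {idx} after {last})"
                    )
                last = idx
                pairs.append((idx, _parse_number(val_s, lineno)))
            dense = [0.0] * pairs[-1][0]
            for idx, val in pairs:
                dense[idx - 1] = val
            features: Sequence[float] = dense
        else:
            features = [_parse_number(t, lineno) for t in tokens[1:]]
        examples.append(FeatureExample(label=label, features=tuple(features), comment=comment))
    if not examples:
        raise FileFormatError("feature file contains no examples")
    return examples
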