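"""Numeric lookup tables (Atchley factors, hydrophobicity, pair potentials).

Tables ship as plain tab-separated files under ``protfeat/data`` so they
can be audited or replaced.  Each file carries a comment header with its
provenance and a ``# sha256:`` line over the data body; the loader verifies
the checksum, so a silently edited table fails loudly at import.

The two contact-potential tables are synthetic stand-ins (their filenames
and headers say so): deterministic constructions with the structure of
knowledge-based potentials, not transcriptions of published digits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .alphabets import AA_ORDER
from .errors import FileFormatError

__all__ = ["LookupTable", "load_table", "TABLE_FILES"]

TABLE_FILES = {
    "atchley": "atchley_factors.tsv",
    "hydrophobicity": "hydrophobicity.tsv",
    "interface_contact": "interface_contact_potentials.synthetic.tsv",
    "beta_contact": "beta_contact_potentials.synthetic.tsv",
}


@dataclass(frozen=True)
class LookupTable:
    """A residue (or residue-pair) to value(s) mapping with its value range.

    ``entries`` maps a residue letter to a float or tuple of floats for
    scalar/vector tables, or a sorted two-letter pair key (e.g. ``"AC"``)
    to a float for pair tables.  Pair lookups are symmetric by key
    construction.
    """

    name: str
    entries: dict
    value_range: tuple[float, float]
    is_pair: bool

    def pair(self, a: str, b: str) -> float:
        """Symmetric pair lookup (keys are stored with a <= b)."""
        return self.entries["".join(sorted((a, b)))]

    @property
    def mean_value(self) -> float:
        vals = np.array([v for v in self.entries.values()], dtype=float)
        return float(vals.mean())


def _read_data_file(filename: str) -> tuple[list[str], str]:
    text = resources.files("protfeat.data").joinpath(filename).read_text()
    header, data = [], []
    checksum = None
    for line in text.splitlines():
        if line.startswith("#"):
            header.append(line)
            if line.startswith("# sha256:"):
                checksum = line.split(":", 1)[1].strip()
        elif line.strip():
            data.append(line)
    if checksum is None:
        raise FileFormatError(f"{filename}: missing checksum header")
    body = "\n".join(data) + "\n"
    actual = hashlib.sha256(body.encode()).hexdigest()
    if actual != checksum:
        raise FileFormatError(
            f"{filename}: data checksum {actual} does not match header {checksum}"
        )
    return data, checksum


@lru_cache(maxsize=None)
def load_table(name: str) -> LookupTable:
    """Load and checksum-verify one of the shipped tables by short name."""
    if name not in TABLE_FILES:
        raise KeyError(f"unknown table {name!r}; available: {sorted(TABLE_FILES)}")
    data, _ = _read_data_file(TABLE_FILES[name])

    entries: dict = {}
    values: list[float] = []
    is_pair = name.endswith("_contact")
    for line in data:
        fields = line.split("\t")
        if is_pair:
            a, b, v = fields[0], fields[1], float(fields[2])
            entries["".join(sorted((a, b)))] = v
            values.append(v)
        elif len(fields) == 2:
            entries[fields[0]] = float(fields[1])
            values.append(float(fields[1]))
        else:
            vec = tuple(float(v) for v in fields[1:])
            entries[fields[0]] = vec
            values.extend(vec)

    if is_pair and len(entries) != 210:
        raise FileFormatError(f"{name}: expected 210 unordered pairs, got {len(entries)}")
    if not is_pair and set(k for k in entries) != set(AA_ORDER):
        raise FileFormatError(f"{name}: expected one row per standard residue")
    return LookupTable(
        name=name,
        entries=entries,
        value_range=(min(values), max(values)),
        is_pair=is_pair,
    )
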