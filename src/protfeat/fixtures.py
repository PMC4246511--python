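"""Deterministic generator of synthetic input files in every supported dialect.

``make_fixture`` draws a random protein, derives a mutually consistent
anchored MSA, PSSM, DSSP file, PSIPRED ``.ss2`` and SSpro/ACCpro
predictions from it, writes each in its file dialect, and returns the
in-memory ground truth alongside the paths.  Every parser (and the CLI)
can therefore be tested end-to-end with zero downloads: parse the file,
compare with the bundle, field for field.

The generator is not a biophysically realistic simulator; its realism is
limited to internal consistency (the PSSM's percentages are the MSA's
column frequencies, the ``.ss2`` class probabilities argmax to the DSSP
3-state string, etc.).  All randomness flows from one integer seed and
regenerating with the same seed yields byte-identical files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .alphabets import AA_ORDER, MAX_ACC, PSSM_FILE_ORDER, dssp8_to_ss3, sa_two_class
from .errors import DomainError
from .types import (
    AnchoredMSA,
    AnnotationString,
    DSSPRecord,
    ProteinRecord,
    PSSMProfile,
    SSPrediction,
)

PathLike = Union[str, os.PathLike]

__all__ = ["FixtureConfig", "FixtureBundle", "make_fixture"]

_LOG2_20 = math.log2(20)

#: Log-odds written when a residue's weighted percentage rounds to zero
#: (log2 of a zero frequency is undefined; −9 sits at the bottom of the
#: usual PSI-BLAST score range).
ZERO_FREQ_LOG_ODDS = -9


@dataclass(frozen=True)
class FixtureConfig:
    """Rates used when deriving the MSA from the query.

    ``substitution_rate`` is the per-position probability that a non-query
    row redraws the residue uniformly from the 20 standard types (so about
    19/20 of draws actually change it); ``gap_rate`` the probability of a
    gap instead.
    """

    substitution_rate: float = 0.2
    gap_rate: float = 0.05


@dataclass(frozen=True)
class FixtureBundle:
    """Ground truth plus written file paths for one synthetic protein."""

    seed: int
    protein: ProteinRecord
    msa: AnchoredMSA
    pssm: PSSMProfile
    dssp: tuple[DSSPRecord, ...]
    ss_pred: SSPrediction
    sa_pred: SSPrediction
    file_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def ss3(self) -> AnnotationString:
        """The DSSP-derived 3-state secondary-structure string."""
        return AnnotationString(
            kind="SS3", symbols="".join(dssp8_to_ss3(r.ss8) for r in self.dssp)
        )

    @property
    def sa2(self) -> AnnotationString:
        """The DSSP-derived buried/exposed string (25% RSA threshold)."""
        return AnnotationString(
            kind="SA2", symbols="".join(sa_two_class(r.aa, r.acc) for r in self.dssp)
        )


def _largest_remainder_percent(freqs: np.ndarray) -> np.ndarray:
    """Round frequencies to integer percentages that sum to exactly 100."""
    raw = freqs * 100.0
    floors = np.floor(raw).astype(int)
    short = 100 - floors.sum()
    order = np.argsort(-(raw - floors))  # largest fractional parts first
    floors[order[:short]] += 1
    return floors


def _ss8_pattern(length: int, rng: np.random.Generator) -> str:
    """Alternating helix/strand/loop segments with jittered lengths."""
    states = ["H", "E", " "]
    out: list[str] = []
    i = 0
    while len(out) < length:
        seg = int(rng.integers(3, 7))
        out.extend(states[i % 3] * seg)
        i += 1
    return "".join(out[:length])


def make_fixture(
    seed: int,
    length: int = 60,
    msa_rows: int = 20,
    out_dir: PathLike = ".",
    config: FixtureConfig = FixtureConfig(),
) -> FixtureBundle:
    """Generate one consistent synthetic protein and write all input files.

    Writes ``fasta``, ``msa``, ``pssm``, ``dssp``, ``ss2``, ``sspro`` and
    ``accpro`` files under ``out_dir`` (keys of ``file_paths``).  The
    in-memory ground truth stores exactly the values printed to the files
    (integers, 2- or 3-decimal floats), so parsed structures compare equal
    to the bundle bit-for-bit.
    """
    if length < 1 or msa_rows < 1:
        raise DomainError("fixture needs length >= 1 and msa_rows >= 1")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = f"synth{seed}"

    aa_list = list(AA_ORDER)
    sequence = "".join(rng.choice(aa_list, size=length))
    protein = ProteinRecord(id=name, sequence=sequence)

    # --- anchored MSA -----------------------------------------------------
    rows = [sequence]
    for _ in range(msa_rows - 1):
        chars = []
        for c in sequence:
            u = rng.random()
            if u < config.gap_rate:
                chars.append("-")
            elif u < config.gap_rate + config.substitution_rate:
                chars.append(str(rng.choice(aa_list)))
            else:
                chars.append(c)
        rows.append("".join(chars))
    # the MSA file dialect carries no identifier, so its ground truth uses
    # the same placeholder id the parser assigns
    msa = AnchoredMSA(query=ProteinRecord(id="query", sequence=sequence), rows=tuple(rows))

    # --- PSSM consistent with the MSA columns ------------------------------
    log_odds = np.zeros((length, 20), dtype=int)
    percentages = np.zeros((length, 20), dtype=int)
    information = np.zeros(length)
    for j in range(length):
        column = [row[j] for row in rows if row[j] != "-"]
        counts = np.array([column.count(aa) for aa in AA_ORDER], dtype=float)
        pct = _largest_remainder_percent(counts / counts.sum())
        freqs = pct / 100.0
        lo = np.where(
            pct > 0,
            np.round(np.log2(np.where(pct > 0, freqs, 1.0) / 0.05)),
            ZERO_FREQ_LOG_ODDS,
        ).astype(int)
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info = round(max(0.0, _LOG2_20 - entropy), 2)
        # store in PSSM file column order
        file_idx = [AA_ORDER.index(aa) for aa in PSSM_FILE_ORDER]
        percentages[j] = pct[file_idx]
        log_odds[j] = lo[file_idx]
        information[j] = info
    pssm = PSSMProfile(
        residues=sequence,
        log_odds=log_odds.astype(float),
        percentages=percentages.astype(float),
        information=information,
    )

    # --- DSSP with an alternating H/E/loop pattern --------------------------
    ss8 = _ss8_pattern(length, rng)
    dssp_records = tuple(
        DSSPRecord(
            residue_index=i + 1,
            chain="A",
            aa=sequence[i],
            ss8=ss8[i],
            acc=int(rng.integers(0, int(MAX_ACC[sequence[i]]) + 1)),
        )
        for i in range(length)
    )

    # --- PSIPRED .ss2 consistent with the DSSP 3-state string ---------------
    ss3 = "".join(dssp8_to_ss3(s) for s in ss8)
    probs = np.zeros((length, 3))
    for i, state in enumerate(ss3):
        top = round(float(rng.uniform(0.70, 0.95)), 3)
        split = float(rng.uniform(0.2, 0.8))
        second = round((1.0 - top) * split, 3)
        third = round(1.0 - top - second, 3)
        row = {"C": 0, "H": 1, "E": 2}[state]
        others = [k for k in range(3) if k != row]
        probs[i, row] = top
        probs[i, others[0]] = second
        probs[i, others[1]] = third
    ss_pred = SSPrediction(
        residues=sequence,
        annotation=AnnotationString(kind="SS3", symbols=ss3),
        probabilities=probs,
    )
    sa2 = "".join(sa_two_class(r.aa, r.acc) for r in dssp_records)
    sa_pred = SSPrediction(
        residues=sequence, annotation=AnnotationString(kind="SA2", symbols=sa2)
    )

    paths = {
        "fasta": out / f"{name}.fasta",
        "msa": out / f"{name}.msa",
        "pssm": out / f"{name}.pssm",
        "dssp": out / f"{name}.dssp",
        "ss2": out / f"{name}.ss2",
        "sspro": out / f"{name}.sspro",
        "accpro": out / f"{name}.accpro",
    }
    _write_fasta(paths["fasta"], protein)
    _write_msa(paths["msa"], msa)
    _write_pssm(paths["pssm"], pssm)
    _write_dssp(paths["dssp"], dssp_records)
    _write_ss2(paths["ss2"], ss_pred)
    _write_sspro(paths["sspro"], sequence, ss3, banner="SSpro")
    _write_sspro(paths["accpro"], sequence, sa2.replace("b", "-"), banner="ACCpro")

    return FixtureBundle(
        seed=seed,
        protein=protein,
        msa=msa,
        pssm=pssm,
        dssp=dssp_records,
        ss_pred=ss_pred,
        sa_pred=sa_pred,
        file_paths=paths,
    )


# ---------------------------------------------------------------------------
# dialect writers

def _write_fasta(path: Path, protein: ProteinRecord, width: int = 60) -> None:
    seq = protein.sequence
    lines = [f">{protein.id} synthetic fixture"]
    lines += [seq[i:i + width] for i in range(0, len(seq), width)]
    path.write_text("\n".join(lines) + "\n")


def _write_msa(path: Path, msa: AnchoredMSA) -> None:
    path.write_text("\n".join(msa.rows) + "\n")


def _write_pssm(path: Path, pssm: PSSMProfile) -> None:
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
    ]
    letters = "  ".join(PSSM_FILE_ORDER)
    lines.append("            " + letters + "   " + letters)
    for i in range(pssm.length):
        lo = " ".join(f"{int(v):3d}" for v in pssm.log_odds[i])
        pc = " ".join(f"{int(v):3d}" for v in pssm.percentages[i])
        lines.append(
            f"{i + 1:5d} {pssm.residues[i]}  {lo}  {pc}  {pssm.information[i]:.2f} 1.00"
        )
    lines += ["", "                      K         Lambda",
              "Standard Ungapped    0.1337     0.3157"]
    path.write_text("\n".join(lines) + "\n")


def _write_dssp(path: Path, records: tuple[DSSPRecord, ...]) -> None:
    lines = [
        "==== Secondary Structure Definition (synthetic fixture) ====",
        f"  {len(records)}  1  0  0  0   TOTAL NUMBER OF RESIDUES",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N",
    ]
    serial = 0
    for k, rec in enumerate(records):
        serial += 1
        lines.append(
            f"{serial:5d}{rec.residue_index:5d} {rec.chain} {rec.aa}  {rec.ss8}"
            + " " * 17
            + f"{rec.acc:4d}"
        )
        if k == 4 and len(records) > 10:  # exercise chain-break skipping
            serial += 1
            lines.append(f"{serial:5d}" + " " * 8 + "!")  # '!' in the AA column
    path.write_text("\n".join(lines) + "\n")


def _write_ss2(path: Path, pred: SSPrediction) -> None:
    lines = ["# PSF format file (synthetic fixture)", ""]
    for i, (aa, ss) in enumerate(zip(pred.residues, pred.annotation.symbols)):
        c, h, e = pred.probabilities[i]
        lines.append(f"{i + 1:4d} {aa} {ss}   {c:.3f}  {h:.3f}  {e:.3f}")
    path.write_text("\n".join(lines) + "\n")


def _write_sspro(path: Path, sequence: str, prediction: str, banner: str) -> None:
    lines = [f"# {banner} prediction (synthetic fixture)", sequence, prediction]
    path.write_text("\n".join(lines) + "\n")
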