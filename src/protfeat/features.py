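"""Windowed feature assembly: recipes turn parsed inputs into ML examples.

A :class:`FeatureRecipe` names an ordered list of per-residue blocks
(one-hot encodings, Atchley factors, hydrophobicity, PSSM/MSA profile
columns, information content) evaluated over a sliding window centered on
each residue, plus optional global blocks (compositions, power means,
sequence entropy) repeated on every example.

Window slots that fall outside the sequence contribute a zero block plus a
boundary indicator bit set to 1 (in-sequence slots carry the bit as 0);
this keeps the feature length constant across residues, the standard
treatment in secondary-structure prediction.  For a per-residue block of
width ``w`` and window size ``W``, the block contributes ``W * (w + 1)``
features, so the total per-residue width is ``W * Σ(w_block + 1)`` plus
the widths of the global blocks.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import characterizers as ch
from .encoders import hot_encode_aa, hot_encode_sa, hot_encode_ss
from .errors import RecipeError
from .types import (
    AnchoredMSA,
    AnnotationString,
    ColumnProfile,
    FeatureExample,
    ProteinRecord,
    PSSMProfile,
)

__all__ = [
    "FeatureInputs",
    "FeatureRecipe",
    "parse_recipe",
    "build_residue_features",
    "build_examples",
    "PER_RESIDUE_BLOCKS",
    "GLOBAL_BLOCKS",
]

_LOG2_20 = math.log2(20)

PER_RESIDUE_BLOCKS = {
    "hot_aa": 20,
    "hot_ss": 3,
    "hot_sa": 2,
    "atchley": 5,
    "hydrophobicity": 1,
    "pssm_logodds": 20,
    "pssm_freq": 20,
    "msa_freq": 20,
    "information": 1,
}

GLOBAL_BLOCKS = {
    "aa_composition": 20,
    "ss_composition": 3,
    "sa_composition": 2,
    "ordered_mean": 1,
    "entropy": 1,
}

_REQUIRES = {
    "hot_ss": "ss3",
    "hot_sa": "sa2",
    "ss_composition": "ss3",
    "sa_composition": "sa2",
    "pssm_logodds": "pssm",
    "pssm_freq": "pssm",
    "msa_freq": "msa",
}


@dataclass(frozen=True)
class FeatureInputs:
    """Parsed structures a recipe may draw on (only the protein is required)."""

    protein: ProteinRecord
    pssm: Optional[PSSMProfile] = None
    msa: Optional[AnchoredMSA] = None
    ss3: Optional[AnnotationString] = None
    sa2: Optional[AnnotationString] = None

    def __post_init__(self) -> None:
        n = len(self.protein)
        for name in ("pssm", "msa", "ss3", "sa2"):
            obj = getattr(self, name)
            if obj is not None and len(obj) != n:
                raise RecipeError(
                    f"{name} length {len(obj)} does not match sequence length {n}"
                )


@dataclass(frozen=True)
class FeatureRecipe:
    """Which blocks to compute and how wide the residue window is."""

    per_residue_blocks: tuple[str, ...] = ()
    global_blocks: tuple[tuple[str, dict], ...] = ()
    window: int = 1
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise RecipeError("window must be an odd positive integer")
        if not self.per_residue_blocks and not self.global_blocks:
            raise RecipeError("recipe selects no feature blocks")
        for name in self.per_residue_blocks:
            if name not in PER_RESIDUE_BLOCKS:
                raise RecipeError(f"unknown per-residue block {name!r}")
        for name, _ in self.global_blocks:
            if name not in GLOBAL_BLOCKS:
                raise RecipeError(f"unknown global block {name!r}")

    def width(self) -> int:
        """Total feature-vector length the recipe produces."""
        per = sum(PER_RESIDUE_BLOCKS[b] + 1 for b in self.per_residue_blocks)
        glob = sum(GLOBAL_BLOCKS[b] for b, _ in self.global_blocks)
        return self.window * per + glob

    def required_inputs(self) -> set[str]:
        names = [b for b in self.per_residue_blocks] + [b for b, _ in self.global_blocks]
        required = {_REQUIRES[b] for b in names if b in _REQUIRES}
        if any(b == "information" for b in names):
            required.add("msa|pssm")
        return required


_ORDERED_MEAN_RE = re.compile(r"ordered_mean\((\d+)(?:;([a-z0-9_]+))?\)")


def parse_recipe(text: str, window: int = 1, scaled: bool = False) -> FeatureRecipe:
    """Parse a recipe string like ``"hot_aa+pssm_logodds+aa_composition"``.

    Blocks are separated by ``+`` or ``,``; the power-mean block takes its
    order and scale in parentheses, e.g. ``ordered_mean(2;hydrophobicity)``.
    """
    per: list[str] = []
    glob: list[tuple[str, dict]] = []
    for token in re.split(r"[+,]", text):
        token = token.strip()
        if not token:
            continue
        m = _ORDERED_MEAN_RE.fullmatch(token)
        if m:
            glob.append(
                ("ordered_mean", {"n": int(m.group(1)), "scale": m.group(2) or "hydrophobicity"})
            )
        elif token in PER_RESIDUE_BLOCKS:
            per.append(token)
        elif token in GLOBAL_BLOCKS:
            glob.append((token, {}))
        else:
            raise RecipeError(f"unknown feature block {token!r}")
    return FeatureRecipe(
        per_residue_blocks=tuple(per),
        global_blocks=tuple(glob),
        window=window,
        scaled=scaled,
    )


def _check_inputs(inputs: FeatureInputs, recipe: FeatureRecipe) -> None:
    missing = []
    for req in recipe.required_inputs():
        if req == "msa|pssm":
            if inputs.msa is None and inputs.pssm is None:
                missing.append("msa or pssm (for the information block)")
        elif getattr(inputs, req) is None:
            missing.append(req)
    if missing:
        raise RecipeError("recipe needs missing input(s): " + ", ".join(missing))


def _profiles(inputs: FeatureInputs) -> list[ColumnProfile]:
    if inputs.msa is not None:
        return ch.column_profiles(inputs.msa)
    return ch.pssm_column_profiles(inputs.pssm)


def _block_values(
    block: str, inputs: FeatureInputs, pos: int, scaled: bool,
    profiles: Optional[list[ColumnProfile]],
) -> np.ndarray:
    seq = inputs.protein.sequence
    if block == "hot_aa":
        return hot_encode_aa(seq[pos])
    if block == "hot_ss":
        return hot_encode_ss(inputs.ss3.symbols[pos])
    if block == "hot_sa":
        return hot_encode_sa(inputs.sa2.symbols[pos])
    if block == "atchley":
        return ch.atchley_factors(seq[pos], scaled=scaled)
    if block == "hydrophobicity":
        return np.array([ch.hydrophobicity(seq[pos], scaled=scaled)])
    if block == "pssm_logodds":
        row = inputs.pssm.log_odds_canonical()[pos]
        return ch.logistic(row) if scaled else row.astype(float)
    if block == "pssm_freq":
        return ch.pssm_column_profiles(inputs.pssm)[pos].frequencies
    if block == "msa_freq":
        return ch.column_profiles(inputs.msa)[pos].frequencies
    if block == "information":
        info = profiles[pos].information
        return np.array([info / _LOG2_20 if scaled else info])
    raise RecipeError(f"unknown per-residue block {block!r}")


def build_residue_features(
    inputs: FeatureInputs, recipe: FeatureRecipe, position: int
) -> np.ndarray:
    """Feature vector for one residue: windowed blocks then global blocks."""
    _check_inputs(inputs, recipe)
    n = len(inputs.protein)
    if not 0 <= position < n:
        raise RecipeError(f"position {position} outside sequence of length {n}")
    return _assemble(inputs, recipe, position, _precompute(inputs, recipe))


def _precompute(inputs: FeatureInputs, recipe: FeatureRecipe) -> dict:
    cache: dict = {"profiles": None, "globals": None}
    names = list(recipe.per_residue_blocks)
    if "information" in names:
        cache["profiles"] = _profiles(inputs)
    if "msa_freq" in names and inputs.msa is not None:
        cache["msa_profiles"] = ch.column_profiles(inputs.msa)
    if "pssm_freq" in names and inputs.pssm is not None:
        cache["pssm_profiles"] = ch.pssm_column_profiles(inputs.pssm)
    cache["globals"] = _global_values(inputs, recipe)
    return cache


def _global_values(inputs: FeatureInputs, recipe: FeatureRecipe) -> np.ndarray:
    parts: list[np.ndarray] = []
    seq = inputs.protein.sequence
    for name, kwargs in recipe.global_blocks:
        if name == "aa_composition":
            parts.append(ch.aa_composition(seq).fractions)
        elif name == "ss_composition":
            parts.append(ch.ss_composition(inputs.ss3).fractions)
        elif name == "sa_composition":
            parts.append(ch.sa_composition(inputs.sa2).fractions)
        elif name == "ordered_mean":
            parts.append(
                np.array([ch.scaled_ordered_mean(seq, kwargs.get("n", 1),
                                                 kwargs.get("scale", "hydrophobicity"))])
            )
        elif name == "entropy":
            # Shannon entropy of the residue composition, scaled to [0,1]
            # by log2(20) when the recipe asks for scaled output
            h = ch.calculate_entropy(ch.aa_composition(seq).fractions)
            parts.append(np.array([h / _LOG2_20 if recipe.scaled else h]))
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


def _assemble(
    inputs: FeatureInputs, recipe: FeatureRecipe, position: int, cache: dict
) -> np.ndarray:
    n = len(inputs.protein)
    half = recipe.window // 2
    parts: list[np.ndarray] = []
    for block in recipe.per_residue_blocks:
        width = PER_RESIDUE_BLOCKS[block]
        for offset in range(-half, half + 1):
            pos = position + offset
            if 0 <= pos < n:
                if block == "msa_freq":
                    values = cache["msa_profiles"][pos].frequencies
                elif block == "pssm_freq":
                    values = cache["pssm_profiles"][pos].frequencies
                else:
                    values = _block_values(block, inputs, pos, recipe.scaled,
                                           cache["profiles"])
                parts.append(np.asarray(values, dtype=float))
                parts.append(np.zeros(1))  # in-sequence: boundary bit 0
            else:
                parts.append(np.zeros(width))
                parts.append(np.ones(1))  # outside: boundary bit 1
    parts.append(cache["globals"])
    return np.concatenate(parts)


def build_examples(
    inputs: FeatureInputs,
    recipe: FeatureRecipe,
    labels: Optional[Sequence[float]] = None,
) -> list[FeatureExample]:
    """One :class:`FeatureExample` per residue, in sequence order.

    ``labels`` supplies one target per residue; without it a placeholder
    label 0 is written.
    """
    _check_inputs(inputs, recipe)
    n = len(inputs.protein)
    if labels is not None and len(labels) != n:
        raise RecipeError(f"{len(labels)} labels for {n} residues")
    cache = _precompute(inputs, recipe)
    examples = []
    for pos in range(n):
        vec = _assemble(inputs, recipe, pos, cache)
        label = float(labels[pos]) if labels is not None else 0.0
        examples.append(FeatureExample(label=label, features=tuple(vec)))
    return examples
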