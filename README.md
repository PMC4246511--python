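# protfeat

Protein sequence data in, machine-learning-ready feature files out.

Most sequence-based protein prediction tasks — secondary structure,
solvent accessibility, residue contacts, disorder, model quality — start
from the same raw materials: the sequence itself (FASTA), its
evolutionary profile (a query-anchored MSA or a PSI-BLAST PSSM), and
per-residue structure annotations (DSSP output, SSpro/ACCpro or PSIPRED
predictions). Machine-learning tools, however, consume numbers.
`protfeat` is the bridge: a small library that parses those standard
formats, characterizes them numerically, and serializes labeled feature
vectors in the text formats ML packages expect (SVM^light-style sparse
lines or dense matrices), plus a thin CLI for stand-alone feature
generation.

## What it computes

**Encoders.** Orthogonal ("one-hot") encodings: a residue *a* maps to
`e_a ∈ {0,1}^20` with a single 1 (alphabetical residue order; unknown `X`
maps to the zero vector), secondary structure to `{0,1}^3` in (H, E, C)
order — helix is `100`, coil `001` — and buried/exposed to `{0,1}^2`.

**Characterizers.**

- Per-residue lookups: the five Atchley physicochemical factors,
  a side-chain hydrophobicity scale, and two symmetric residue-pair
  contact potentials (interface contacts and cross-strand β-sheet
  pairing). Every lookup takes `scaled=True` to min-max map values into
  [0, 1].
- Content: composition vectors `f` over residues, SS states or SA
  states, with `Σ f_i = 1`.
- Profiles: per-column residue frequencies `p_j` and information content
  `I_j = log₂20 − H(p_j)` (bits), from an anchored MSA or from a PSSM's
  weighted observed percentages, where `H(p) = −Σ p_i log₂ p_i`.
- Vector measures: Shannon entropy, Pearson `r`, cosine similarity, and
  the power (generalized) mean `M_n = (1/L Σ v_i^n)^{1/n}` over a
  string's scaled per-symbol values.

**Feature writers.** `FeatureExample` (label + vector) lists are written
one example per line, numbered (`label 1:v1 2:v2 …`, ascending 1-based
indices, optionally sparse) or unnumbered dense; a reader round-trips
both dialects byte-identically.

**Fixture generator.** `make_fixture(seed, length, msa_rows, out_dir)`
writes a synthetic, mutually consistent set of all supported input files
(the PSSM's percentages are the MSA's column frequencies, the `.ss2`
probabilities argmax to the DSSP-derived 3-state string, …) together
with the in-memory ground truth, so pipelines are testable offline.

Deliberately out of scope: PDB parsing and any model training or
prediction — the package stops at the feature file.

## A worked example

```bash
protfeat fixture --seed 3 --length 100 --msa-rows 15 --out-dir demo
protfeat features --fasta demo/synth3.fasta --pssm demo/synth3.pssm \
    --recipe hot_aa+pssm_logodds --window 15 --out demo/o.feat
```

prints

```
synth3: 100 residues, recipe width 630, 100 examples -> demo/o.feat
```

One line per residue: each of the two blocks (20-dim one-hot residue,
20-dim PSSM log-odds row) is evaluated at all 15 window positions
centered on the residue, each slot carrying one extra boundary bit
(zero-filled slots past the termini get bit 1), giving
15 × (21 + 21) = 630 features. `demo/o.feat` is directly consumable by
SVM^light-style tools; add `--labels ss3 --dssp ...` to label each
residue with its 3-state secondary-structure class, `--scaled` to squash
log-odds through the logistic `1/(1+e^{−x})`.

The same pipeline from Python:

```python
import protfeat as pf

bundle = pf.make_fixture(seed=3, length=100, msa_rows=15, out_dir="demo")
inputs = pf.FeatureInputs(protein=bundle.protein, pssm=bundle.pssm)
recipe = pf.parse_recipe("hot_aa+pssm_logodds", window=15)
examples = pf.build_examples(inputs, recipe)
pf.write_features(examples, pf.WriterConfig(), "demo/o.feat")
```

The `examples/` directory holds short narrative scripts, one per
capability: parsing (`01`), sequence characterization (`02`), profile
conservation (`03`), windowed feature assembly (`04`).

## Data tables

The lookup tables live as audited, checksummed TSVs in
`src/protfeat/data/`. Atchley factors and the hydrophobicity scale are
transcriptions of published values (citations in the file headers). The
two contact-potential tables are **synthetic stand-ins** — deterministic
constructions with the structure of knowledge-based potentials
(symmetric, hydrophobicity/charge-driven), clearly labelled in filename
and header; replace them with your preferred published table (matching
the documented TSV format and refreshing the checksum line) for
production feature sets. See `docs/methods.md` for details.
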