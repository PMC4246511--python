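# Methods

## Scope and data model

`protfeat` converts the standard inputs of sequence-based protein
prediction into numerical feature vectors. The pipeline has three
layers: **parsers** (FASTA, query-anchored MSA, PSI-BLAST ASCII PSSM,
classic DSSP output, SSpro/ACCpro flat predictions, PSIPRED `.ss2`),
**characterizers and encoders** (the numbers), and **feature writers**
(the ML text formats). Residue indices are 0-based inside the library;
file formats keep their native 1-based indices at the I/O boundary.
PDB parsing and model training/prediction are out of scope by design:
the package serves the feature-generation phase only.

## Alphabets and symbol conventions

- Canonical residue order is alphabetical one-letter
  (`ACDEFGHIKLMNPQRSTVWY`) for every encoding, composition and frequency
  vector. PSSM files keep their own column order
  (`ARNDCQEGHILKMFPSTWYV`) inside `PSSMProfile` and are remapped at the
  boundary; keeping both avoids silent column permutation bugs in either
  direction.
- Non-standard codes B, Z, U, O, J normalize to the unknown residue `X`.
  `X` conventions are library-wide: all-zero one-hot and Atchley
  vectors, table mean for scalar/pair lookups, excluded from composition
  denominators. Rationale: zero vectors keep fixed dimensionality
  without inventing a 21st class; table means keep pair features finite
  and unbiased.
- DSSP 8→3 collapse: H, G, I → H; E, B → E; T, S, blank → C (the
  dominant convention in the secondary-structure prediction
  literature). Two-class solvent accessibility calls a residue exposed
  when relative accessibility `acc / max_acc(aa) ≥ 0.25`, with
  `max_acc` a fixed table of theoretical per-residue maxima (Å²); 25%
  is the threshold used by the ACCpro family of predictors.
- SS3 one-hot order (H, E, C) is fixed by the convention that helix
  encodes as `100` and coil as `001`; the SA2 order is (b, e).

## Lookup tables

Tables are plain TSVs under `src/protfeat/data/`, loaded at first use
and verified against a `# sha256:` header over the data body; the test
suite additionally freezes the four checksums, so any change to the
digits is deliberate and visible.

- **Atchley factors** (20×5): transcription of the published
  multivariate factor scores (citation in the file header). Scaling is
  min-max per factor dimension over the 20 residues.
- **Hydrophobicity** (20×1): transcription of a published side-chain
  hydrophobicity scale measured at pH 7 relative to glycine = 0, from a
  study of hydrophobicity and helical propensity (citation in the
  header). Min-max scaling maps Asp (−55) to 0 and Phe (+100) to 1.
- **Interface and β-pairing contact potentials** (210 unordered pairs
  each): these are **synthetic stand-ins**, and both the filenames
  (`*.synthetic.tsv`) and headers say so. The published tables this
  interface was designed around could not be transcribed with
  confidence, and inventing digits under a citation would be worse than
  an honest stand-in. The construction is deterministic (seeded):
  `e(a,b) = −w_h·h'_a·h'_b + w_q·q_a·q_b + ε`, with `h'` the
  hydrophobicity scale on [−0.55, 1], `q` side-chain charges
  (K, R = +1; H = +0.5; D, E = −1) and a small seeded Gaussian
  perturbation — symmetric by construction, hydrophobic pairs
  favorable (negative), like charges unfavorable. Every contract the
  library makes (symmetry over all 210 pairs, `X` → table mean, exact
  [0, 1] min-max scaling) is tested against these tables, and any
  published table in the same three-column TSV format drops in by
  replacing the file and its checksum line.

Pair tables are stored as unordered pairs (`a ≤ b`); a source table in
asymmetric form would be symmetrized by averaging at embedding time,
since contacts are unordered.

## Characterizers

- Compositions divide counts by the number of counted symbols;
  amino-acid composition excludes `X` from the denominator, so
  `Σf = 1` always holds on legal input (enforced at 1e-9).
- MSA column profiles count non-gap residues per column (the anchored
  layout guarantees a gapless query, so no column is empty);
  `gap_fraction = gaps/rows`. Information is `log₂20 − H(p)` bits with
  `0·log 0 ≡ 0` — the information-content convention of sequence-logo
  analysis; base 2 everywhere.
- PSSM profiles use the file's weighted-percentage block renormalized
  to sum 1, but take the per-position information directly from the
  file's information column rather than recomputing it: PSI-BLAST's
  estimate involves sequence weighting and pseudocounts the percentages
  alone cannot reproduce. An all-zero percentage row (possible in
  degenerate files) falls back to uniform 1/20 with a warning.
- `calculate_r` refuses zero-variance input with a dedicated
  `UndefinedCorrelationError` instead of returning 0 or NaN: a silent
  placeholder value would flow into feature files undetected.
- **Ordered mean.** The "nth ordered mean" of a string is implemented
  as the generalized power mean `M_n = (mean(v_i^n))^{1/n}` over
  per-symbol values scaled to [0, 1] (amino acids via the
  hydrophobicity scale or a chosen Atchley dimension, `atchley1` …
  `atchley5`; SS3 via class positions H = 0, E = ½, C = 1; SA2 via
  b = 0, e = 1). The phrase is ambiguous between a power mean and an
  order statistic (the nth-smallest value); the power mean was chosen
  because it is a single smooth summary that is monotone in `n`
  (power-mean inequality, property-tested) and reduces to the
  arithmetic mean at `n = 1`. The order-statistic reading would be a
  different, non-smooth feature; it is not provided.

## Scaling conventions

`scaled=True` means min-max over the table's own entries for finite
lookups (exact 0 and 1 at the extremes), division by `log₂20` for
information values, and the logistic squash `1/(1+e^{−x})` for PSSM
log-odds — the standard treatment of unbounded log-odds scores in
secondary-structure prediction pipelines. One-hot encodings and
frequencies are already in [0, 1].

## Window assembly

Per-residue feature vectors concatenate, block by block in recipe
order, the block's value at every position of an odd window centered on
the residue. A window slot outside the sequence contributes a zero
block plus a boundary-indicator bit of 1 (0 in-sequence), so feature
length is constant across residues:
`width = W · Σ(w_block + 1) + Σ w_global`. Zero-fill with an explicit
boundary bit was chosen over truncation because constant-width examples
are what fixed-input ML tools require, and the bit lets a model
distinguish "zero because absent" from "zero because terminal". Global
blocks (compositions, power means, the entropy of the residue
composition) are computed once and appended to every example.

Per-residue class labels, when requested from the CLI, are class
indices in canonical order (H/E/C → 0/1/2, b/e → 0/1); a placeholder 0
is written otherwise.

## Feature-file dialects

The numbered dialect follows the SVM^light grammar — target, then
space-separated `index:value` tokens with strictly ascending 1-based
indices — optionally sparse (zeros omitted; the reader refills them up
to the line's maximum index). The unnumbered dialect is dense
whitespace-delimited values. Values print with 6 decimal places by
default: lossless enough for [0, 1]-scaled features and stable under
write → parse → write (byte-identical, tested). Accommodating every ML
package's format is not feasible; these two canonical dialects cover
the SVM^light/NNrank-style families, and labels/numbering are
controlled by `WriterConfig`.

## Synthetic fixture generator

`make_fixture` emulates one protein's complete input set:

- sequence drawn uniformly over the 20 residues (default length 60);
- MSA rows derived from the query at substitution rate 0.2 and gap
  rate 0.05 per position (a mid-depth homolog set: enough divergence
  that column frequencies are informative, anchored so columns map 1:1
  to query residues);
- PSSM percentages are the MSA column frequencies rounded by largest
  remainder so every row sums to exactly 100 (naive per-cell rounding
  can miss 100 by several points across 20 cells); log-odds are
  `round(log₂(f/0.05))` with zero-frequency cells clamped to −9 (the
  bottom of the usual score range, since `log₂ 0` is undefined);
  information is `log₂20 − H` rounded to the file's 2 decimals;
- DSSP states follow alternating helix/strand/loop segments of length
  3–6 with accessibilities uniform in `[0, max_acc(aa)]`, and one
  chain-break line is planted in longer fixtures to exercise skipping;
- `.ss2` probabilities give the DSSP-derived state 0.70–0.95 of the
  mass, rounded to the file's 3 decimals with the remainder assigned so
  each row sums to exactly 1.000.

The ground truth stores exactly the printed (quantized) values, so
parsers must recover files bit-exactly — a stricter check than
approximate agreement. All randomness flows from one integer seed;
identical seeds yield byte-identical files. The generator is **not**
biophysically realistic: residues are i.i.d., structure states ignore
the sequence, and the MSA has no phylogenetic correlation. Passing
round-trip tests therefore demonstrates parser/writer fidelity and
pipeline correctness, not predictive value of the features on real
proteins.

### Default problem sizes

Tests use fixtures of length 12–100 with 5–20 MSA rows and 20 seeds for
round-trip sweeps; the brute-force Pearson/cosine comparison uses 1,000
random vector pairs. These sizes fully exercise every code path
(multi-segment structures, chain breaks, window boundary handling) while
keeping the suite fast.

## Known limitations and open choices

- Only PSIPRED's vertical `.ss2` dialect is parsed; `.horiz` is
  human-oriented and carries no probabilities.
- The SSpro family has had several output layouts; the two-line
  (sequence, prediction) dialect implemented here is a defined
  stand-in for the flat form, with the prediction alphabet
  ({H,E,C} vs {e,b,-}) selecting secondary structure vs accessibility —
  disjoint under case sensitivity, with an explicit `kind` override.
- Both percentage and log-odds blocks of the PSSM are retained;
  characterizers that need frequencies use the percentage block, and
  log-odds feed the `pssm_logodds` feature block directly.
- The contact-potential digits are synthetic (see above); feature
  *pipelines* built on them are fully functional, but absolute values
  carry no knowledge-based meaning until a published table is dropped
  in.
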