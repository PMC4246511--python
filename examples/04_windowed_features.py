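"""Build a windowed per-residue feature file ready for an ML tool.

The recipe concatenates, for every residue, each block evaluated across a
15-residue window (out-of-sequence slots are zero plus a boundary bit),
and writes one SVM^light line per residue labeled with the DSSP-derived
secondary-structure class (H=0, E=1, C=2).
"""

import tempfile
from pathlib import Path

import protfeat as pf

tmp = Path(tempfile.mkdtemp())
bundle = pf.make_fixture(seed=21, length=80, msa_rows=15, out_dir=tmp)

inputs = pf.FeatureInputs(protein=bundle.protein, pssm=bundle.pssm,
                          ss3=bundle.ss3)
recipe = pf.parse_recipe("hot_aa+pssm_logodds", window=15, scaled=True)
labels = [pf.SS3_ORDER.index(c) for c in bundle.ss3.symbols]

examples = pf.build_examples(inputs, recipe, labels=labels)
out = tmp / "train.feat"
n = pf.write_features(examples, pf.WriterConfig(numbered=True), out)

print(f"recipe width: {recipe.width()} features per residue")
print(f"wrote {n} examples to {out}")
print("first line starts:", out.read_text().splitlines()[0][:60], "...")
# Every line has the same token count, so the file drops straight into
# SVM^light-style tools; the label is the residue's 3-state class.
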