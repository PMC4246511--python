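"""Column frequencies and information content from an anchored MSA.

Information = log2(20) - Shannon entropy of the column's residue
frequencies, in bits: ~4.32 for a perfectly conserved column, 0 for a
uniformly diverged one.
"""

import tempfile

import protfeat as pf

bundle = pf.make_fixture(seed=4, length=40, msa_rows=30, out_dir=tempfile.mkdtemp())
msa = pf.parse_anchored_msa(bundle.file_paths["msa"])

profiles = pf.column_profiles(msa)
most = max(profiles, key=lambda p: p.information)
least = min(profiles, key=lambda p: p.information)
print(f"{len(profiles)} columns from {msa.n_rows} aligned sequences")
print(f"most conserved column {most.position}: "
      f"{most.information:.2f} bits, top frequency {most.frequencies.max():.2f}")
print(f"least conserved column {least.position}: "
      f"{least.information:.2f} bits, gap fraction {least.gap_fraction:.2f}")

# the same per-position view from a PSSM instead of an MSA
pssm_profiles = pf.pssm_column_profiles(bundle.pssm)
print(f"PSSM column 0 information: {pssm_profiles[0].information:.2f} bits "
      f"(taken from the file's information column)")
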