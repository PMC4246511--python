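"""Parse every supported input dialect and summarize what was read.

Generates a synthetic but mutually consistent set of files first, so the
example runs with no downloads; point the parsers at real PSI-BLAST,
DSSP, SSpro or PSIPRED output in the same way.
"""

import tempfile

import protfeat as pf

tmp = tempfile.mkdtemp()
bundle = pf.make_fixture(seed=11, length=50, msa_rows=12, out_dir=tmp)

protein = pf.parse_fasta_sequences(bundle.file_paths["fasta"])[0]
msa = pf.parse_anchored_msa(bundle.file_paths["msa"])
pssm = pf.parse_ascii_pssm(bundle.file_paths["pssm"])
dssp = pf.parse_dssp_output(bundle.file_paths["dssp"])
ss2 = pf.parse_psipred_output(bundle.file_paths["ss2"])

print(f"sequence   {protein.id}: {len(protein)} residues")
print(f"MSA        {msa.n_rows} rows x {len(msa)} columns")
print(f"PSSM       {pssm.length} positions, mean information "
      f"{pssm.information.mean():.2f} bits")
ss3 = "".join(pf.dssp8_to_ss3(r.ss8) for r in dssp)
print(f"DSSP       {len(dssp)} residues, 3-state: "
      f"H={ss3.count('H')} E={ss3.count('E')} C={ss3.count('C')}")
c, h, e = ss2.probabilities[0]
print(f"PSIPRED    {len(ss2)} residues, first row probabilities "
      f"(coil,helix,strand) = ({c:.3f}, {h:.3f}, {e:.3f})")
# High mean PSSM information means the synthetic alignment is shallow:
# most columns are dominated by the query residue.
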