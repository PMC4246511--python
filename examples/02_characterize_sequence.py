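"""Characterize one sequence numerically: lookups, compositions, means.

Each characterizer turns symbols into real numbers suitable as ML
features; `scaled=True` maps everything into [0, 1].
"""

import numpy as np

import protfeat as pf

seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"

comp = pf.aa_composition(seq)
top = max(zip(comp.fractions, pf.AA_ORDER))
print(f"composition: most frequent residue {top[1]} at {top[0]:.3f}")
print(f"composition entropy: {pf.calculate_entropy(comp.fractions):.3f} bits "
      f"(log2(20) = {np.log2(20):.3f} would be a perfectly uniform sequence)")

print(f"Atchley factors of K: {pf.atchley_factors('K')}")
print(f"hydrophobicity F vs D (scaled): "
      f"{pf.hydrophobicity('F', scaled=True):.2f} vs "
      f"{pf.hydrophobicity('D', scaled=True):.2f}")
print(f"interface contact potential (L, V): "
      f"{pf.interface_contact_potential('L', 'V'):.3f} "
      f"(negative = favorable in this table's convention)")

# power means: order 1 is the plain mean; higher orders emphasize the
# hydrophobic extreme of the [0,1]-scaled values
for n in (1, 2, 4):
    print(f"ordered mean n={n}: {pf.scaled_ordered_mean(seq, n):.4f}")
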