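"""Featurise a backbone: from atom coordinates to the 180-value encoding.

Builds an ideal 30-residue alpha-helix, computes each residue's local frame
and neighbourhood encoding, and prints what one feature vector contains.
"""

import numpy as np

from seqdesign import synthetic
from seqdesign.featurise import chain_dihedrals, featurise_chain

chain = synthetic.build_backbone(30, synthetic.HELIX)
features = featurise_chain(chain)

print(f"chain of {len(chain)} residues -> feature matrix {features.matrix.shape}")
pairs = chain_dihedrals(chain)
mid = 15
print(f"residue {mid}: phi = {np.rad2deg(pairs[mid].phi):.1f} deg, "
      f"psi = {np.rad2deg(pairs[mid].psi):.1f} deg")

vec = features.matrix[mid]
print(f"self dihedral encoding (sin/cos phi, sin/cos psi): {np.round(vec[:4], 3)}")
row = vec[4:15]
print(f"nearest neighbour row: translation {np.round(row[:3], 2)} Angstrom,")
print(f"  rotation quaternion {np.round(row[3:7], 3)} (unit norm),")
print(f"  neighbour dihedral encoding {np.round(row[7:], 3)}")

# The first 3 values are the neighbour's Calpha position in residue 15's own
# frame, so they are identical for every interior residue of an ideal helix
# and unchanged if the whole structure is rotated or translated.
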