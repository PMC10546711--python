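"""Train the residue classifier on a learnable synthetic dataset.

Fifty synthetic chains alternate between ideal helix and strand geometry;
each residue is labelled by a deterministic rule on its own torsions
(helical -> Ala, extended -> Val), so a working model must reach
near-perfect recovery.
"""

import numpy as np

from seqdesign import synthetic
from seqdesign.model import ModelConfig, forward, train

fsets = synthetic.standard_dataset(n_chains=50, chain_length=30, seed=0)
X, y = synthetic.pool_features(fsets)
rng = np.random.default_rng(0)
perm = rng.permutation(len(y))
n_val = len(y) // 10
val, tr = perm[:n_val], perm[n_val:]

config = ModelConfig(max_epochs=50, seed=0)
params = train(X[tr], y[tr], X[val], y[val], config)

print(f"trained on {len(tr)} residues, validated on {n_val}")
for epoch in (0, 9, 49):
    print(f"epoch {epoch:3d}: train loss {params.history['train_loss'][epoch]:.4f}  "
          f"val loss {params.history['val_loss'][epoch]:.4f}  "
          f"val recovery {params.history['val_recovery'][epoch]:.3f}")

train_recovery = float(np.mean(forward(params, X[tr]).argmax(axis=1) == y[tr]))
print(f"final training recovery: {train_recovery:.3f}")
# Recovery ~1.0 confirms the rule is exactly expressible in the features;
# on real structures the ceiling is far lower because many sequences fit
# one backbone.
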