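#!/usr/bin/env bash
# The shell workflow: fixtures -> features -> model -> designed sequences.
# Swap the fixture directory for a directory of real PDB files plus a chain
# list (one PDBID_CHAIN per line) to run on experimental structures.
set -euo pipefail

seqdesign make-fixtures --out fixtures --n-chains 12 --length 45 \
    --jitter 0.02 --seed 0

seqdesign featurise --chains fixtures/chains.txt --pdb-dir fixtures \
    --out features --seed 0

seqdesign train --features features --out run \
    --epochs 30 --hidden 64,64,64 --dropout 0.5 --seed 0

seqdesign predict --features features --params run/model.npz --out predictions

echo "designed sequences: predictions/designed.fasta"
echo "metrics: predictions/confusion.csv, predictions/per_class.csv"
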