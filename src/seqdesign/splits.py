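"""Dataset partitioning: chain-level test split and residue-level validation split.

Whole chains go to the held-out test set (so no structural context leaks
across the boundary); validation residues are then sampled from the pooled
residues of the training chains and are only used to monitor training. Both
draws are exact-fraction sampling without replacement from a seeded
generator, so a (ids, fraction, seed) triple always reproduces the same
partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import UNKNOWN
from .featurise import FeatureSet

#: Minimum chain length accepted when culling enforcement is on; mirrors the
#: "length greater than 40 residues" criterion of typical nonredundant sets.
MIN_CHAIN_LENGTH = 41


class SplitError(ValueError):
    """Not enough chains or residues to produce the requested split."""


@dataclass
class DatasetSplit:
    """Membership record of one train/test/validation partition."""

    train_chain_ids: list[str]
    test_chain_ids: list[str]
    val_residue_index: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed\t{self.seed}\n")
            for cid in self.train_chain_ids:
                fh.write(f"train\t{cid}\n")
            for cid in self.test_chain_ids:
                fh.write(f"test\t{cid}\n")
            for cid, pos in self.val_residue_index:
                fh.write(f"val\t{cid}\t{pos}\n")


def split_chains(
    chain_ids: list[str], test_fraction: float = 0.10, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Assign chains to train/test sets by exact-fraction random sampling.

    ``floor(N · test_fraction)`` chains (at least 1) are drawn uniformly
    without replacement. Deterministic given the seed.
    """
    if len(chain_ids) < 2:
        raise SplitError("cannot split: need at least 2 chains")
    if not 0.0 < test_fraction < 1.0:
        raise SplitError("cannot split: test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(len(chain_ids) * test_fraction))
    perm = rng.permutation(len(chain_ids))
    test_idx = set(perm[:n_test].tolist())
    train = [cid for i, cid in enumerate(chain_ids) if i not in test_idx]
    test = [cid for i, cid in enumerate(chain_ids) if i in test_idx]
    return train, test


def split_residues(
    train_features: list[FeatureSet], val_fraction: float = 0.10, seed: int = 0
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Sample validation residues uniformly from the pooled training residues.

    Residues with UNKNOWN labels are excluded from both sides. Returns
    (train_index, validation_index) as (chain_id, residue_position) pairs;
    their union is exactly the labelled training residues.
    """
    pooled = [
        (fs.chain_id, i)
        for fs in train_features
        for i in range(len(fs))
        if fs.labels[i] != UNKNOWN
    ]
    if len(pooled) < 10:
        raise SplitError("cannot split: need at least 10 labelled residues")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(len(pooled) * val_fraction))
    perm = rng.permutation(len(pooled))
    val_set = set(perm[:n_val].tolist())
    train_index = [pooled[i] for i in range(len(pooled)) if i not in val_set]
    val_index = [pooled[i] for i in sorted(val_set)]
    return train_index, val_index


def enforce_length_filter(chains: dict[str, int], minimum: int = MIN_CHAIN_LENGTH):
    """Drop chains shorter than ``minimum`` residues; returns surviving ids."""
    kept = [cid for cid, length in chains.items() if length >= minimum]
    return kept
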