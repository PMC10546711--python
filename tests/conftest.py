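import numpy as np
import pytest

from seqdesign import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def helix_chain():
    return synthetic.build_backbone(30, synthetic.HELIX, chain_id="H")


@pytest.fixture
def strand_chain():
    return synthetic.build_backbone(30, synthetic.STRAND, chain_id="S")


@pytest.fixture
def jittered_chain():
    """A helix with small coordinate noise so every residue is distinguishable."""
    specs = [(30, synthetic.HELIX)]
    # build directly to keep the BackboneChain (not the FeatureSet)
    chain = synthetic.build_backbone(30, synthetic.HELIX, chain_id="J")
    noise = np.random.default_rng(7)
    for arr in (chain.coords_N, chain.coords_CA, chain.coords_C):
        arr += noise.normal(0, 0.05, arr.shape)
    return chain


def random_rigid_motion(rng):
    """A sampled proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 20, 3)
    return R, t


def apply_rigid(chain, R, t):
    from seqdesign.structure_io import BackboneChain

    return BackboneChain(
        chain_id=chain.chain_id,
        residue_ids=list(chain.residue_ids),
        residue_labels=chain.residue_labels.copy(),
        coords_N=chain.coords_N @ R.T + t,
        coords_CA=chain.coords_CA @ R.T + t,
        coords_C=chain.coords_C @ R.T + t,
    )
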