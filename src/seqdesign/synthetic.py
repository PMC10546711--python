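"""Synthetic backbone fixtures with exactly known geometry.

Chains are grown atom-by-atom from internal coordinates (bond lengths, bond
angles, torsions) by the natural-extension reference-frame construction, so
the phi/psi requested for each residue are reproduced *exactly* by the
geometry module — the central cross-module oracle of the test suite. Labels
are assigned by a deterministic rule on quantities present in the features
(helical torsions → alanine's class, extended torsions → valine's class),
making the Bayes-optimal sequence recovery 1.0 by construction: a classifier
that cannot learn the rule is broken, and chance-level recovery on shuffled
labels bounds the leakage.

Internal-coordinate defaults are standard peptide values (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å; N–Cα–C 111.2°, Cα–C–N 116.6°, C–N–Cα 121.9°;
ω = 180°, trans). They are frozen constants of the fixture: any chemically
reasonable values would do, and fixing them makes tests exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featurise import DEFAULT_K, FeatureSet, chain_dihedrals, featurise_chain
from .structure_io import AA1, BackboneChain


@dataclass(frozen=True)
class SecondaryParams:
    """Internal coordinates of an idealised secondary-structure element.

    Angles in degrees, lengths in Å; ``omega`` is the peptide-bond torsion
    (180° for the trans conformation).
    """

    phi: float
    psi: float
    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.6
    angle_c_n_ca: float = 121.9
    omega: float = 180.0

    def __post_init__(self):
        for length in (self.bond_n_ca, self.bond_ca_c, self.bond_c_n):
            if not 1.0 < length < 2.0:
                raise ValueError("bond lengths must lie in (1, 2) Å")
        for angle in (self.angle_n_ca_c, self.angle_ca_c_n, self.angle_c_n_ca):
            if not 90.0 < angle < 150.0:
                raise ValueError("bond angles must lie in (90°, 150°)")


HELIX = SecondaryParams(phi=-57.0, psi=-47.0)
STRAND = SecondaryParams(phi=-120.0, psi=120.0)

#: Class labels assigned by the geometry rule.
HELIX_CLASS = 0  # 'A'
STRAND_CLASS = AA1.index("V")  # 17


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position D with |CD| = bond, ∠BCD = angle, dihedral(A,B,C,D) = torsion.

    Angle and torsion in radians; torsion follows the same sign convention as
    :func:`seqdesign.geometry.dihedral`.
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone_from_torsions(
    phis: np.ndarray,
    psis: np.ndarray,
    params: SecondaryParams = HELIX,
    chain_id: str = "A",
    labels: np.ndarray | None = None,
) -> BackboneChain:
    """Grow a backbone whose residue *i* has the requested φᵢ, ψᵢ (degrees).

    ``phis[0]`` and ``psis[-1]`` are ignored (those torsions do not exist).
    Bond lengths/angles and ω come from ``params``.
    """
    phis = np.deg2rad(np.asarray(phis, dtype=np.float64))
    psis = np.deg2rad(np.asarray(psis, dtype=np.float64))
    L = len(phis)
    if L < 1 or len(psis) != L:
        raise ValueError("phis and psis must share a length >= 1")
    ang_n_ca_c = np.deg2rad(params.angle_n_ca_c)
    ang_ca_c_n = np.deg2rad(params.angle_ca_c_n)
    ang_c_n_ca = np.deg2rad(params.angle_c_n_ca)
    omega = np.deg2rad(params.omega)

    n_xyz = np.zeros((L, 3))
    ca_xyz = np.zeros((L, 3))
    c_xyz = np.zeros((L, 3))

    # Seed the first residue in the xy-plane.
    n_xyz[0] = (0.0, 0.0, 0.0)
    ca_xyz[0] = (params.bond_n_ca, 0.0, 0.0)
    c_xyz[0] = ca_xyz[0] + params.bond_ca_c * np.array(
        [-np.cos(ang_n_ca_c), np.sin(ang_n_ca_c), 0.0]
    )
    for i in range(1, L):
        # psi of residue i-1 places N_i; omega places CA_i; phi of residue i
        # places C_i.
        n_xyz[i] = _place_atom(
            n_xyz[i - 1], ca_xyz[i - 1], c_xyz[i - 1],
            params.bond_c_n, ang_ca_c_n, psis[i - 1],
        )
        ca_xyz[i] = _place_atom(
            ca_xyz[i - 1], c_xyz[i - 1], n_xyz[i],
            params.bond_n_ca, ang_c_n_ca, omega,
        )
        c_xyz[i] = _place_atom(
            c_xyz[i - 1], n_xyz[i], ca_xyz[i],
            params.bond_ca_c, ang_n_ca_c, phis[i],
        )
    if labels is None:
        labels = np.zeros(L, dtype=np.int64)
    return BackboneChain(
        chain_id=chain_id,
        residue_ids=[str(i + 1) for i in range(L)],
        residue_labels=labels,
        coords_N=n_xyz,
        coords_CA=ca_xyz,
        coords_C=c_xyz,
    )


def build_backbone(
    residue_count: int, params: SecondaryParams, chain_id: str = "A"
) -> BackboneChain:
    """Ideal uniform secondary-structure chain with φ/ψ from ``params``."""
    if residue_count < 1:
        raise ValueError("residue_count must be >= 1")
    phis = np.full(residue_count, params.phi)
    psis = np.full(residue_count, params.psi)
    return build_backbone_from_torsions(phis, psis, params, chain_id=chain_id)


def dihedral_class_rule(chain: BackboneChain) -> np.ndarray:
    """Deterministic geometry → label rule used by the learnability fixtures.

    Helical torsions map to class ``HELIX_CLASS`` and extended torsions to
    ``STRAND_CLASS``, decided from the residue's own ψ (falling back to φ at
    the chain ends, where one torsion is undefined). Every quantity used is
    present in the feature encoding, so the rule is exactly learnable.
    """
    pairs = chain_dihedrals(chain)
    labels = np.empty(len(chain), dtype=np.int64)
    for i, pair in enumerate(pairs):
        if pair.psi is not None:
            helical = pair.psi < np.deg2rad(30.0)
        elif pair.phi is not None:
            helical = pair.phi > np.deg2rad(-90.0)
        else:
            helical = True
        labels[i] = HELIX_CLASS if helical else STRAND_CLASS
    return labels


def random_label_rule(seed: int = 0):
    """A 20-class uniform random labeller — the chance-level control.

    Labels carry no information about the geometry, so validation recovery of
    any classifier trained on them is pinned at chance (1/20).
    """
    rng = np.random.default_rng(seed)

    def rule(chain: BackboneChain) -> np.ndarray:
        return rng.integers(0, len(AA1), size=len(chain), dtype=np.int64)

    return rule


def make_labeled_dataset(
    chain_specs: list[tuple[int, SecondaryParams]],
    label_rule=dihedral_class_rule,
    seed: int = 0,
    jitter_sigma: float = 0.0,
    k: int = DEFAULT_K,
) -> list[FeatureSet]:
    """Build, optionally jitter, label and featurise a set of chains.

    ``chain_specs`` is a list of (residue_count, SecondaryParams); labels are
    assigned by ``label_rule`` on the *jittered* geometry so that the rule
    stays a deterministic function of the features (Bayes recovery 1.0).
    ``jitter_sigma`` (Å, ≤ ~0.1 to stay realistic) adds seeded isotropic
    Gaussian noise to every atom.
    """
    rng = np.random.default_rng(seed)
    feature_sets = []
    for index, (count, params) in enumerate(chain_specs):
        chain = build_backbone(count, params, chain_id=f"SYN{index:04d}")
        if jitter_sigma > 0.0:
            chain = BackboneChain(
                chain_id=chain.chain_id,
                residue_ids=chain.residue_ids,
                residue_labels=chain.residue_labels,
                coords_N=chain.coords_N + rng.normal(0, jitter_sigma, (count, 3)),
                coords_CA=chain.coords_CA + rng.normal(0, jitter_sigma, (count, 3)),
                coords_C=chain.coords_C + rng.normal(0, jitter_sigma, (count, 3)),
            )
        chain.residue_labels[:] = label_rule(chain)
        feature_sets.append(featurise_chain(chain, k=k))
    return feature_sets


def standard_dataset(
    n_chains: int = 50,
    chain_length: int = 30,
    seed: int = 0,
    jitter_sigma: float = 0.0,
    k: int = DEFAULT_K,
) -> list[FeatureSet]:
    """The default learnability fixture: alternating helix/strand chains."""
    specs = [
        (chain_length, HELIX if i % 2 == 0 else STRAND) for i in range(n_chains)
    ]
    return make_labeled_dataset(specs, seed=seed, jitter_sigma=jitter_sigma, k=k)


def pool_features(feature_sets: list[FeatureSet]) -> tuple[np.ndarray, np.ndarray]:
    """Stack all residues of a FeatureSet collection into (X, y) arrays."""
    X = np.concatenate([fs.matrix for fs in feature_sets])
    y = np.concatenate([fs.labels for fs in feature_sets])
    return X, y
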