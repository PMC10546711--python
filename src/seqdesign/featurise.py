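"""Per-residue structural features from backbone geometry.

For each residue the encoding concatenates

* its own phi/psi dihedrals as ``(sin φ, cos φ, sin ψ, cos ψ)`` — 4 values,
* one 11-value row per nearest neighbour, in ascending Cα–Cα distance order:
  relative translation (3) ⊕ relative-rotation quaternion (4) ⊕ neighbour
  dihedral encoding (4),

for a flattened length of ``4 + 11·k`` (180 at the default k=16). Undefined
dihedrals — chain termini and residues flanking a chain break — encode as
``(0, 0)`` per angle, a point outside the unit circle traced by real angles,
so the classifier can tell "missing" from any true torsion. Chains shorter
than k+1 residues are zero-padded with a boolean mask marking real rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    LocalFrame,
    dihedral,
    local_frame,
    relative_rotation,
    relative_translation,
)
from .structure_io import UNKNOWN, BackboneChain

logger = logging.getLogger(__name__)

#: Sentinel for an undefined dihedral angle (terminus or chain break).
UNDEFINED = None

#: Values per neighbour row: translation 3 + quaternion 4 + dihedral enc 4.
NEIGHBOR_ROW = 11

#: Default neighbourhood size.
DEFAULT_K = 16

FEATURE_LAYOUT_VERSION = 1
QUATERNION_CONVENTION = "scalar-first, canonical a>=0, R = Oj Oi^T, rows-as-basis"


@dataclass(frozen=True)
class DihedralPair:
    """phi/psi of one residue; ``None`` marks an undefined angle."""

    phi: float | None
    psi: float | None


@dataclass
class ResidueFeatures:
    """The fixed-length encoding of one residue's structural neighbourhood."""

    target_index: int
    label: int  # 0–19 or UNKNOWN
    self_dihedrals: np.ndarray  # (4,)
    neighbor_block: np.ndarray  # (k, 11)
    neighbor_mask: np.ndarray  # (k,) bool

    @property
    def vector(self) -> np.ndarray:
        """Flattened feature vector of length 4 + 11·k."""
        return np.concatenate([self.self_dihedrals, self.neighbor_block.ravel()])


def chain_dihedrals(chain: BackboneChain) -> list[DihedralPair]:
    """Backbone phi/psi for every residue of a chain.

    ``φ_i`` uses atoms C_{i−1}, N_i, Cα_i, C_i and ``ψ_i`` uses N_i, Cα_i,
    C_i, N_{i+1}; hence φ of the first and ψ of the last residue are
    undefined, as is any dihedral spanning a flagged chain break.
    """
    L = len(chain)
    pairs = []
    for i in range(L):
        phi = psi = UNDEFINED
        if i > 0 and not chain.breaks[i - 1]:
            try:
                phi = dihedral(
                    chain.coords_C[i - 1],
                    chain.coords_N[i],
                    chain.coords_CA[i],
                    chain.coords_C[i],
                )
            except DegenerateGeometryError:
                pass
        if i < L - 1 and not chain.breaks[i]:
            try:
                psi = dihedral(
                    chain.coords_N[i],
                    chain.coords_CA[i],
                    chain.coords_C[i],
                    chain.coords_N[i + 1],
                )
            except DegenerateGeometryError:
                pass
        pairs.append(DihedralPair(phi, psi))
    return pairs


def encode_dihedrals(d: DihedralPair) -> np.ndarray:
    """(sin φ, cos φ, sin ψ, cos ψ); an undefined angle contributes (0, 0)."""
    out = np.zeros(4)
    if d.phi is not UNDEFINED:
        out[0], out[1] = np.sin(d.phi), np.cos(d.phi)
    if d.psi is not UNDEFINED:
        out[2], out[3] = np.sin(d.psi), np.cos(d.psi)
    return out


def nearest_neighbors(chain: BackboneChain, i: int, k: int = DEFAULT_K) -> list[int]:
    """Indices of the k nearest residues to residue i by Cα–Cα distance.

    Sorted by ascending distance; exact ties broken by ascending sequence
    index (numpy's stable sort). The residue itself is excluded. Returns all
    other residues when fewer than k exist.
    """
    d = np.linalg.norm(chain.coords_CA - chain.coords_CA[i], axis=1)
    order = [int(j) for j in np.argsort(d, kind="stable") if j != i]
    return order[:k]


def featurise_residue(
    chain: BackboneChain,
    frames: list[LocalFrame | None],
    dihedrals: list[DihedralPair],
    i: int,
    k: int = DEFAULT_K,
) -> ResidueFeatures:
    """Assemble the feature encoding of residue ``i``.

    ``frames`` and ``dihedrals`` are the precomputed per-residue values for
    the whole chain (a frame may be ``None`` if degenerate; such residues are
    skipped as neighbours). Raises :class:`DegenerateGeometryError` when the
    target residue's own frame is missing.
    """
    if frames[i] is None:
        raise DegenerateGeometryError(f"degenerate frame at residue {i}")
    block = np.zeros((k, NEIGHBOR_ROW))
    mask = np.zeros(k, dtype=bool)
    neighbors = [j for j in nearest_neighbors(chain, i, k=len(chain)) if frames[j] is not None]
    for row, j in enumerate(neighbors[:k]):
        block[row, 0:3] = relative_translation(frames[i], chain.coords_CA[j])
        block[row, 3:7] = relative_rotation(frames[i], frames[j])
        block[row, 7:11] = encode_dihedrals(dihedrals[j])
        mask[row] = True
    return ResidueFeatures(
        target_index=i,
        label=int(chain.residue_labels[i]),
        self_dihedrals=encode_dihedrals(dihedrals[i]),
        neighbor_block=block,
        neighbor_mask=mask,
    )


@dataclass
class FeatureSet:
    """All residue features of one chain plus provenance.

    ``matrix`` stacks the flattened per-residue vectors, shape (L, 4+11k).
    """

    chain_id: str
    matrix: np.ndarray  # (L, 4 + 11k)
    labels: np.ndarray  # (L,) int
    mask: np.ndarray  # (L, k) bool
    residue_ids: list[str]
    k: int = DEFAULT_K
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.meta.setdefault("layout_version", FEATURE_LAYOUT_VERSION)
        self.meta.setdefault("quaternion_convention", QUATERNION_CONVENTION)
        self.meta.setdefault("k", self.k)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def save(self, path) -> None:
        """Write to an .npz container with a JSON provenance header."""
        np.savez(
            path,
            matrix=self.matrix,
            labels=self.labels,
            mask=self.mask,
            residue_ids=np.array(self.residue_ids, dtype="U16"),
            header=np.array(
                json.dumps({"chain_id": self.chain_id, **self.meta}), dtype="U4096"
            ),
        )

    @classmethod
    def load(cls, path) -> "FeatureSet":
        with np.load(path) as data:
            header = json.loads(str(data["header"]))
            k = int(header.pop("k"))
            return cls(
                chain_id=header.pop("chain_id"),
                matrix=data["matrix"],
                labels=data["labels"],
                mask=data["mask"],
                residue_ids=[str(r) for r in data["residue_ids"]],
                k=k,
                meta=header | {"k": k},
            )


def featurise_chain(chain: BackboneChain, k: int = DEFAULT_K) -> FeatureSet:
    """Featurise every residue of a chain, in chain order.

    Residues whose own frame is degenerate (collinear backbone atoms, which
    essentially never happens in real structures) are dropped with a warning.
    """
    dihedrals = chain_dihedrals(chain)
    frames: list[LocalFrame | None] = []
    for i in range(len(chain)):
        try:
            frames.append(
                local_frame(chain.coords_N[i], chain.coords_CA[i], chain.coords_C[i])
            )
        except DegenerateGeometryError:
            logger.warning("chain %s residue %d: degenerate frame, dropped",
                           chain.chain_id, i)
            frames.append(None)

    vectors, labels, masks, ids = [], [], [], []
    for i in range(len(chain)):
        if frames[i] is None:
            continue
        rf = featurise_residue(chain, frames, dihedrals, i, k=k)
        vectors.append(rf.vector)
        labels.append(rf.label)
        masks.append(rf.neighbor_mask)
        ids.append(chain.residue_ids[i])
    if not vectors:
        raise DegenerateGeometryError(f"no featurisable residues in {chain.chain_id}")
    return FeatureSet(
        chain_id=chain.chain_id,
        matrix=np.stack(vectors),
        labels=np.array(labels),
        mask=np.stack(masks),
        residue_ids=ids,
        k=k,
    )
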