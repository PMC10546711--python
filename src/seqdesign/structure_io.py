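"""Reading protein backbones from PDB files.

Extracts one chain's N/Cα/C backbone coordinates and maps residue names onto
the 20-class amino-acid alphabet used by the classifier. Only the first MODEL
of a file is read; for alternate locations the highest-occupancy conformer is
kept (ties broken by altloc identifier, so 'A' wins). Residues missing any of
the three backbone atoms are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel class index for residues that are not one of the 20 standard
#: amino acids. Such residues still contribute geometry as neighbours but are
#: never used as prediction targets.
UNKNOWN: int = -1

#: One-letter codes in alphabetical order; index in this string is the class
#: index used throughout the package.
AA1 = "ACDEFGHIKLMNPQRSTVWY"

#: Three-letter code for each class index, aligned with AA1.
AA3 = (
    "ALA CYS ASP GLU PHE GLY HIS ILE LYS LEU "
    "MET ASN PRO GLN ARG SER THR VAL TRP TYR"
).split()

_THREE_TO_INDEX = {code: i for i, code in enumerate(AA3)}
# Selenomethionine is chemically methionine with Se for S; the convention in
# sequence work is to treat it as MET.
_THREE_TO_INDEX["MSE"] = AA1.index("M")

#: Consecutive residues whose Cα–Cα distance exceeds this are flagged as a
#: chain break; no bonded Cα–Cα pair exceeds it (trans peptide ≈ 3.8 Å,
#: cis ≈ 2.9 Å).
CHAIN_BREAK_CUTOFF = 4.5


class ChainNotFoundError(KeyError):
    """Requested chain identifier is absent from the file."""


class EmptyChainError(ValueError):
    """No residue in the chain retained all three backbone atoms."""


def standardize_residue(name3: str) -> int:
    """Map a 3-letter residue code to a class index 0–19, or ``UNKNOWN``.

    The 20 standard codes map to fixed indices in alphabetical one-letter
    order (A=0 … Y=19); MSE maps to MET; everything else (waters, ligands,
    nonstandard residues) maps to ``UNKNOWN``. Total function: never raises.
    """
    return _THREE_TO_INDEX.get(name3.strip().upper(), UNKNOWN)


@dataclass
class BackboneChain:
    """Ordered backbone coordinates and residue identities for one chain.

    Coordinates are in Å. ``residue_ids`` keeps the author numbering (with
    insertion code) purely for reporting; all internal indexing is 0-based
    positional. ``breaks[i]`` is True when the Cα–Cα step from residue ``i``
    to ``i+1`` exceeds :data:`CHAIN_BREAK_CUTOFF`.
    """

    chain_id: str
    residue_ids: list[str]
    residue_labels: np.ndarray  # (L,) int, 0–19 or UNKNOWN
    coords_N: np.ndarray  # (L, 3) float
    coords_CA: np.ndarray
    coords_C: np.ndarray
    breaks: np.ndarray = field(default=None)  # (L-1,) bool

    def __post_init__(self):
        self.residue_labels = np.asarray(self.residue_labels, dtype=np.int64)
        self.coords_N = np.asarray(self.coords_N, dtype=np.float64).reshape(-1, 3)
        self.coords_CA = np.asarray(self.coords_CA, dtype=np.float64).reshape(-1, 3)
        self.coords_C = np.asarray(self.coords_C, dtype=np.float64).reshape(-1, 3)
        L = len(self.residue_ids)
        if not (
            L >= 1
            and len(self.residue_labels) == L
            and self.coords_N.shape[0] == L
            and self.coords_CA.shape[0] == L
            and self.coords_C.shape[0] == L
        ):
            raise ValueError("backbone arrays must share one length L >= 1")
        for arr in (self.coords_N, self.coords_CA, self.coords_C):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite backbone coordinates")
        if self.breaks is None:
            step = np.linalg.norm(np.diff(self.coords_CA, axis=0), axis=1)
            self.breaks = step > CHAIN_BREAK_CUTOFF
        self.breaks = np.asarray(self.breaks, dtype=bool).reshape(-1)

    def __len__(self) -> int:
        return len(self.residue_ids)

    @property
    def sequence(self) -> str:
        """One-letter sequence; UNKNOWN residues render as 'X'."""
        return "".join(
            AA1[lab] if lab != UNKNOWN else "X" for lab in self.residue_labels
        )


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties resolved by altloc character so 'A' beats
    # 'B'. A blank altloc sorts before 'A' and is fine to keep.
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def parse_backbone(pdb_text: str, chain_id: str) -> BackboneChain:
    """Extract the backbone of one chain from PDB-format text.

    Parameters
    ----------
    pdb_text:
        The full text of a PDB file.
    chain_id:
        The author chain identifier to extract.

    Returns
    -------
    BackboneChain
        Residues in order of appearance in the file. Residues missing any of
        N/Cα/C are dropped with a logged warning.

    Raises
    ------
    ChainNotFoundError
        If the chain is not present in the first model.
    EmptyChainError
        If no residue retains all three backbone atoms.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} (no models)")
    model = structure[0]  # first MODEL only
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")

    ids, labels, n_xyz, ca_xyz, c_xyz = [], [], [], [], []
    for residue in chain:
        per_name: dict[str, list[gemmi.Atom]] = {}
        for atom in residue:
            if atom.name in ("N", "CA", "C"):
                per_name.setdefault(atom.name, []).append(atom)
        if set(per_name) != {"N", "CA", "C"}:
            if standardize_residue(residue.name) != UNKNOWN:
                logger.warning(
                    "dropping %s %s%s: incomplete backbone",
                    residue.name,
                    residue.seqid.num,
                    residue.seqid.icode.strip(),
                )
            continue
        picked = {name: _pick_altloc(atoms) for name, atoms in per_name.items()}
        ids.append(f"{residue.seqid.num}{residue.seqid.icode.strip()}")
        labels.append(standardize_residue(residue.name))
        n_xyz.append(picked["N"].pos.tolist())
        ca_xyz.append(picked["CA"].pos.tolist())
        c_xyz.append(picked["C"].pos.tolist())

    if not ids:
        raise EmptyChainError(f"empty chain: {chain_id!r}")
    return BackboneChain(chain_id, ids, labels, n_xyz, ca_xyz, c_xyz)


_PDB_ATOM = (
    "ATOM  {serial:>5d}  {name:<3s} {res:>3s} {chain:1s}{num:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}\n"
)


def write_pdb(chain: BackboneChain, path=None) -> str:
    """Render a BackboneChain as minimal PDB text (N, CA, C records only).

    Used to emit synthetic fixtures and for round-trip testing. Returns the
    text; also writes it to ``path`` when given.
    """
    lines = []
    serial = 1
    for i in range(len(chain)):
        lab = chain.residue_labels[i]
        res3 = AA3[lab] if lab != UNKNOWN else "UNK"
        num = i + 1
        for name, elem, xyz in (
            ("N", "N", chain.coords_N[i]),
            ("CA", "C", chain.coords_CA[i]),
            ("C", "C", chain.coords_C[i]),
        ):
            lines.append(
                _PDB_ATOM.format(
                    serial=serial,
                    name=name,
                    res=res3,
                    chain=chain.chain_id[:1] or "A",
                    num=num,
                    x=xyz[0],
                    y=xyz[1],
                    z=xyz[2],
                    elem=elem,
                )
            )
            serial += 1
    lines.append("TER\nEND\n")
    text = "".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
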