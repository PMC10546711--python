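"""Local coordinate frames and the geometric primitives built on them.

Every residue gets an orthonormal right-handed frame derived from its N, Cα
and C atoms:

* ``u`` — unit vector from the amide nitrogen to the carbonyl carbon,
* ``v`` — unit component of ``a = n − cα`` orthogonal to ``u``
  (``v = normalize(a − (a·u)u)``),
* ``w = u × v``.

Expressing neighbour positions and orientations in this frame makes the
features invariant to any global rotation + translation of the structure
while remaining sensitive to mirror images (the cross product fixes the
handedness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

_EPS = 1e-8


class DegenerateGeometryError(ValueError):
    """Atoms are collinear or coincident, so a frame/dihedral is undefined."""


@dataclass(frozen=True)
class LocalFrame:
    """Residue-attached orthonormal basis with the Cα as origin.

    ``basis`` rows are the unit vectors (u, v, w); right-handed by
    construction, so ``det(basis) = +1``.
    """

    origin: np.ndarray  # (3,)
    basis: np.ndarray  # (3, 3), rows u, v, w


def local_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> LocalFrame:
    """Build the local frame of a residue from its N, Cα and C positions.

    Raises
    ------
    DegenerateGeometryError
        If the three atoms are collinear or coincident (``‖c − n‖`` or the
        rejection of ``a`` from ``u`` below 1e-8 Å).
    """
    n = np.asarray(n, dtype=np.float64)
    ca = np.asarray(ca, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    cn = c - n
    norm_cn = np.linalg.norm(cn)
    if norm_cn <= _EPS:
        raise DegenerateGeometryError("degenerate frame: C and N coincide")
    u = cn / norm_cn
    a = n - ca
    rej = a - (a @ u) * u
    norm_rej = np.linalg.norm(rej)
    if norm_rej <= _EPS:
        raise DegenerateGeometryError("degenerate frame: N, CA, C collinear")
    v = rej / norm_rej
    w = np.cross(u, v)
    return LocalFrame(origin=ca.copy(), basis=np.stack([u, v, w]))


def relative_translation(frame_i: LocalFrame, ca_j: np.ndarray) -> np.ndarray:
    """Neighbour Cα displacement expressed in frame i: ``O_i · (cα_j − cα_i)``."""
    return frame_i.basis @ (np.asarray(ca_j, dtype=np.float64) - frame_i.origin)


def _canonical_sign(q: np.ndarray) -> np.ndarray:
    """Fix the q/−q ambiguity: scalar part ≥ 0; if it is (numerically) zero,
    the first clearly nonzero component decides.

    A component is treated as zero below 1e-6 so that a half-turn rotation —
    whose scalar part is a roundoff-level number of arbitrary sign — gets a
    stable sign from the axis components instead.
    """
    for component in q:
        if abs(component) > 1e-6:
            return q if component > 0 else -q
    return q


def relative_rotation(frame_i: LocalFrame, frame_j: LocalFrame) -> np.ndarray:
    """Unit quaternion (scalar-first) of the rotation taking frame i to frame j.

    The rotation matrix is ``R = O_j · O_iᵀ`` with rows-as-basis-vectors
    frames, so ``O_j = R · O_i``; its entries are the direction cosines
    between the two bases, which makes the quaternion invariant to any global
    rotation of the structure (both bases transform identically and the
    transform cancels). Returned as ``(a, b, c, d)`` for ``a + bî + cĵ + dk̂``
    with the canonical sign ``a ≥ 0``.
    """
    R = frame_j.basis @ frame_i.basis.T
    xyzw = Rotation.from_matrix(R).as_quat()  # scipy is scalar-last
    q = np.array([xyzw[3], xyzw[0], xyzw[1], xyzw[2]])
    return _canonical_sign(q)


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a scalar-first unit quaternion (inverse of above)."""
    a, b, c, d = q
    return Rotation.from_quat([b, c, d, a]).as_matrix()


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, in (−π, π].

    IUPAC sign convention: looking from ``p2`` towards ``p3``, a clockwise
    rotation of the far bond relative to the near bond is positive.

    Raises
    ------
    DegenerateGeometryError
        If either bonded triple is collinear, leaving a plane undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if (
        norm_b2 <= _EPS
        or np.linalg.norm(n1) <= _EPS * norm_b2 * np.linalg.norm(b1)
        or np.linalg.norm(n2) <= _EPS * norm_b2 * np.linalg.norm(b3)
        or np.linalg.norm(n1) <= _EPS
        or np.linalg.norm(n2) <= _EPS
    ):
        raise DegenerateGeometryError("degenerate dihedral: collinear points")
    # atan2 form is numerically stable near 0 and π
    angle = np.arctan2(np.cross(n1, n2) @ (b2 / norm_b2), n1 @ n2)
    if angle <= -np.pi:  # fold −π onto +π so the range is (−π, π]
        angle = np.pi
    return float(angle)
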