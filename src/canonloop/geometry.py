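"""Rigid-body superposition, loop distances and CDR3 torso geometry.

Distances between loops of different lengths are computed by dynamic
time warping (DTW) over per-residue backbone atom sets after the two
loops have been superposed on the backbone atoms of their ten anchor
residues.  The DTW score is normalised by path length, so it behaves
like a length-independent RMSD in Å.

The CDR3 "torso" (base) metrics follow the pseudo bond angle τ and
pseudo dihedral angle α at IMGT position 116, the 6-DOF loop anchor
transform (LAT) between local frames at positions 105 and 117, and the
backbone φ/ψ of the first three (T1–T3) and last four (T4–T7) loop
residues.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .records import BACKBONE_ATOMS, LoopRecord, ResidueRecord

#: Peptide-bond continuity cutoff (Å): a C–N distance at or above this
#: breaks the chain.
BOND_CUTOFF = 1.37


class DegenerateGeometryError(ValueError):
    """Raised when point sets are too degenerate for the requested operation."""


@dataclass
class RigidTransform:
    """Proper rigid transform y = R @ x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def validate(self, tol: float = 1e-9) -> None:
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=tol):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > tol:
            raise ValueError("rotation is not proper (det != +1)")


def kabsch(moving: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``moving`` onto ``reference``.

    Returns the proper rigid transform (no reflection) and the RMSD after
    applying it.  Point sets must be in correspondence with N >= 3 and
    must not be collinear.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    cm = moving.mean(axis=0)
    cr = reference.mean(axis=0)
    mc = moving - cm
    rc = reference - cr
    for pts, name in ((mc, "moving"), (rc, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(1.0, s[0]):
            raise DegenerateGeometryError(f"{name} points are collinear")
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cr - rot @ cm
    transform = RigidTransform(rot, t)
    moved = transform.apply(moving)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return transform, rmsd


def anchor_superpose(loop_a: LoopRecord, loop_b: LoopRecord) -> LoopRecord:
    """Return ``loop_b`` expressed in ``loop_a``'s frame.

    The fit uses the 40 backbone atoms (N, CA, C, O of the ten anchors).
    """
    transform, _ = kabsch(loop_b.anchor_backbone(), loop_a.anchor_backbone())
    return loop_b.transformed(transform.rotation, transform.translation)


def _residue_cost_matrix(loop_a: LoopRecord, loop_b: LoopRecord) -> np.ndarray:
    """Local DTW cost: RMS of the 4 backbone-atom distances per residue pair."""
    a = loop_a.cdr_backbone_by_residue()  # (La, 4, 3)
    b = loop_b.cdr_backbone_by_residue()  # (Lb, 4, 3)
    diff = a[:, None, :, :] - b[None, :, :, :]
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=-1), axis=-1))


def _dtw_on_costs(cost: np.ndarray) -> tuple[float, int]:
    """Boundary-to-boundary DTW with {diagonal, horizontal, vertical} steps.

    Minimises (total path cost, path length) lexicographically; returns both.
    """
    n, m = cost.shape
    total = np.full((n, m), np.inf)
    steps = np.zeros((n, m), dtype=int)
    total[0, 0] = cost[0, 0]
    steps[0, 0] = 1
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = (np.inf, 0)
            for pi, pj in ((i - 1, j - 1), (i - 1, j), (i, j - 1)):
                if pi < 0 or pj < 0:
                    continue
                cand = (total[pi, pj] + cost[i, j], steps[pi, pj] + 1)
                if cand < best:
                    best = cand
            total[i, j], steps[i, j] = best
    return float(total[n - 1, m - 1]), int(steps[n - 1, m - 1])


def dtw_distance(loop_a: LoopRecord, loop_b: LoopRecord) -> float:
    """Length-independent loop distance in Å.

    Anchor-superposes ``loop_b`` onto ``loop_a``, aligns the CDR residue
    series by DTW and returns total path cost divided by path length.
    """
    if loop_a.length == 0 or loop_b.length == 0:
        raise ValueError("empty CDR")
    moved_b = anchor_superpose(loop_a, loop_b)
    cost = _residue_cost_matrix(loop_a, moved_b)
    total, length = _dtw_on_costs(cost)
    return total / length


def backbone_rmsd(loop_a: LoopRecord, loop_b: LoopRecord, fit_on: str = "loop") -> float:
    """Backbone RMSD over CDR atoms of two equal-length loops.

    fit_on="loop" superposes on the CDR backbone itself; fit_on="anchors"
    superposes on the ten anchor residues and measures the CDR deviation
    in that frame.
    """
    if loop_a.length != loop_b.length:
        raise ValueError("CDR length mismatch")
    a = loop_a.cdr_backbone()
    b = loop_b.cdr_backbone()
    if fit_on == "loop":
        _, rmsd = kabsch(b, a)
        return rmsd
    if fit_on == "anchors":
        transform, _ = kabsch(loop_b.anchor_backbone(), loop_a.anchor_backbone())
        moved = transform.apply(b)
        return float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    raise ValueError(f"unknown fit_on: {fit_on!r}")


# ---------------------------------------------------------------------------
# angles

def pseudo_bond_angle(ca_prev, ca_116, ca_next) -> float:
    """Interior angle (degrees) at the middle point, in (0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (ca_prev, ca_116, ca_next))
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise DegenerateGeometryError("coincident points")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def pseudo_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees) in (-180, 180], IUPAC convention (cis = 0)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("three consecutive points are collinear")
    b2n = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2n)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def residue_frame(residue: ResidueRecord) -> tuple[np.ndarray, np.ndarray]:
    """Local frame at a residue: (origin, rotation matrix with columns x, y, z).

    Origin is CA; z points toward the carbonyl C; y is perpendicular to z
    within the N–CA–C plane (toward N); x = y × z (right-handed).
    """
    ca = residue.atom("CA")
    c = residue.atom("C")
    n = residue.atom("N")
    z = c - ca
    nz = np.linalg.norm(z)
    if nz < 1e-10:
        raise DegenerateGeometryError("CA and C coincide")
    z = z / nz
    u = n - ca
    y = u - np.dot(u, z) * z
    ny = np.linalg.norm(y)
    if ny < 1e-10:
        raise DegenerateGeometryError("N, CA, C are collinear")
    y = y / ny
    x = np.cross(y, z)
    return ca, np.column_stack([x, y, z])


#: Euler convention used for the LAT rotation (intrinsic z-y-z).
LAT_EULER_CONVENTION = "ZYZ"


def lat(loop: LoopRecord) -> tuple[float, float, float, float, float, float]:
    """Loop anchor transform: 6-DOF Euler transform frame(105) -> frame(117).

    Returns (X, Y, Z, phi, psi, theta): the translation of the 117 frame
    origin expressed in the 105 frame, and the intrinsic z-y-z Euler angles
    of the relative rotation, in degrees.  Invariant to global rigid motion.
    """
    res105 = loop.find_residue(105)
    res117 = loop.find_residue(117)
    if res105 is None or res117 is None:
        raise ValueError("loop lacks residues at IMGT positions 105/117")
    o1, r1 = residue_frame(res105)
    o2, r2 = residue_frame(res117)
    trans = r1.T @ (o2 - o1)
    rel = r1.T @ r2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # gimbal lock for near-identity rotations
        phi, psi, theta = Rotation.from_matrix(rel).as_euler(LAT_EULER_CONVENTION, degrees=True)
    return (float(trans[0]), float(trans[1]), float(trans[2]),
            float(phi), float(psi), float(theta))


def phi_psi(residues: list[ResidueRecord],
            bond_cutoff: float = BOND_CUTOFF) -> list[tuple[Optional[float], Optional[float]]]:
    """Backbone (φ, ψ) per residue; None at termini and across chain breaks."""
    n = len(residues)
    out: list[list[Optional[float]]] = [[None, None] for _ in range(n)]
    for i in range(n - 1):
        c_i = residues[i].atom("C")
        n_next = residues[i + 1].atom("N")
        if np.linalg.norm(n_next - c_i) >= bond_cutoff:
            continue  # broken junction: leave psi(i) and phi(i+1) undefined
        out[i][1] = pseudo_dihedral(
            residues[i].atom("N"), residues[i].atom("CA"), c_i, n_next)
        out[i + 1][0] = pseudo_dihedral(
            c_i, n_next, residues[i + 1].atom("CA"), residues[i + 1].atom("C"))
    return [tuple(pair) for pair in out]


def torso_class(tau116: float, alpha116: float) -> str:
    """Kinked iff α116 > 0; the α = 0 boundary is assigned to extended."""
    return "kinked" if alpha116 > 0 else "extended"


@dataclass
class TorsoGeometry:
    """Torso (base) metrics of one CDR3 loop."""

    tau116: float
    alpha116: float
    lat: tuple[float, float, float, float, float, float]
    torso_phi_psi: dict[str, tuple[Optional[float], Optional[float]]]
    torso_class: str


def torso_geometry(loop: LoopRecord) -> TorsoGeometry:
    """Compute τ116, α116, LAT and T1–T7 φ/ψ for a CDR3 loop.

    The residue at IMGT position 116 is located by number; its neighbours
    are taken by chain order so insertion codes are handled naturally.
    T1–T3 are the first three and T4–T7 the last four CDR residues.
    """
    if loop.cdr_type not in {"a3", "b3", "L3", "H3"}:
        raise ValueError("torso geometry is defined for CDR3 loops")
    residues = loop.residues
    idx116 = next(
        (i for i, r in enumerate(residues)
         if r.imgt_position == 116 and r.insertion_code == ""), None)
    if idx116 is None:
        raise ValueError("loop lacks a residue at IMGT position 116")
    if idx116 < 1 or idx116 + 2 >= len(residues):
        raise ValueError("not enough residues around position 116")
    cas = [residues[i].atom("CA") for i in range(idx116 - 1, idx116 + 3)]
    tau = pseudo_bond_angle(cas[0], cas[1], cas[2])
    alpha = pseudo_dihedral(*cas)

    torsions = phi_psi(residues)
    n_anch = len(loop.anchors_n)
    first = [torsions[n_anch + i] for i in range(3)]
    last = [torsions[n_anch + loop.length - 4 + i] for i in range(4)]
    labels = {f"T{i + 1}": v for i, v in enumerate([*first, *last])}

    return TorsoGeometry(
        tau116=tau,
        alpha116=alpha,
        lat=lat(loop),
        torso_phi_psi=labels,
        torso_class=torso_class(tau, alpha),
    )
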