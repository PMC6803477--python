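"""Synthetic CDR loop fixtures with planted structure.

Idealised loop backbones are built from per-residue (φ, ψ, ω) torsion
profiles by sequential internal-coordinate (NeRF-style) construction with
standard bond lengths and angles, so every generated loop is chemically
continuous and passes the structural quality filters unless a defect is
injected deliberately.  Generators plant ground truth — cluster
membership, torso class, sequence classes, exact pairwise RMSDs — and
emit it alongside the data.  All generators are seed-deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import geometry
from .imgt import imgt_positions
from .records import CDR_WINDOWS, LoopRecord, N_ANCHORS, ResidueRecord
from .imgt import cdr_of_type

#: Idealised backbone geometry (Engh–Huber-like averages): bond lengths in Å,
#: bond angles in degrees.
GEOMETRY_CONSTANTS: dict[str, float] = {
    "bond_n_ca": 1.458,
    "bond_ca_c": 1.525,
    "bond_c_n": 1.329,
    "bond_c_o": 1.231,
    "angle_n_ca_c": 111.0,
    "angle_ca_c_n": 116.2,
    "angle_c_n_ca": 121.7,
    "angle_ca_c_o": 120.8,
}

#: Default anchor-region torsions (β-strand-like).
ANCHOR_PHI_PSI: tuple[float, float] = (-139.0, 135.0)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D from A-B-C so that |CD| = bond, angle(BCD) = angle
    and torsion(A, B, C, D) = torsion (IUPAC sign)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(torsions: Sequence[tuple[float, float, float]],
                   constants: Optional[dict[str, float]] = None) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O coordinates for a chain from (φ, ψ, ω) per residue.

    φ of the first residue and ω of the first residue are unused; ψ of the
    last residue only places its carbonyl oxygen.
    """
    g = constants or GEOMETRY_CONSTANTS
    n_res = len(torsions)
    if n_res < 1:
        raise ValueError("need at least one residue")
    for phi, psi, omega in torsions:
        for v in (phi, psi, omega):
            if not np.isfinite(v):
                raise ValueError("torsions must be finite")
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([g["bond_n_ca"], 0.0, 0.0])
    a = math.radians(180.0 - g["angle_n_ca_c"])
    c0 = ca0 + g["bond_ca_c"] * np.array([math.cos(a), math.sin(a), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[i - 1]
        psi_prev = torsions[i - 1][1]
        phi_i, _, omega_i = torsions[i]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         g["bond_c_n"], g["angle_ca_c_n"], psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          g["bond_n_ca"], g["angle_c_n_ca"], omega_i)
        c_i = place_atom(prev["C"], n_i, ca_i,
                         g["bond_ca_c"], g["angle_n_ca_c"], phi_i)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(residues):
        psi_i = torsions[i][1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              g["bond_c_o"], g["angle_ca_c_o"], psi_i + 180.0)
    return residues


@dataclass
class LoopTemplate:
    """Torsion-space description of one idealised CDR loop."""

    cdr_type: str
    cdr_phi_psi: list[tuple[float, float]]
    anchor_phi_psi: tuple[float, float] = ANCHOR_PHI_PSI
    omega: float = 180.0
    geometry_constants: dict[str, float] = field(default_factory=lambda: dict(GEOMETRY_CONSTANTS))

    @property
    def length(self) -> int:
        return len(self.cdr_phi_psi)

    def full_torsions(self) -> list[tuple[float, float, float]]:
        aph, aps = self.anchor_phi_psi
        anchors = [(aph, aps, self.omega)] * N_ANCHORS
        cdr = [(phi, psi, self.omega) for phi, psi in self.cdr_phi_psi]
        return anchors + cdr + anchors


def _default_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_loop(template: LoopTemplate,
              noise_sd: float = 0.0,
              seed: int = 0,
              sequence: Optional[str] = None,
              source: Optional[str] = None,
              torsion_noise_deg: float = 0.0,
              bound_state: Optional[bool] = None,
              resolution: float = 2.0,
              bfactor: float = 30.0) -> LoopRecord:
    """Build one LoopRecord from a template.

    Gaussian Cartesian noise of ``noise_sd`` (Å per coordinate) is added to
    CDR atoms only; ``torsion_noise_deg`` perturbs CDR φ/ψ before chain
    construction, which changes the conformation without distorting bonds.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    torsions = template.full_torsions()
    if torsion_noise_deg > 0:
        torsions = list(torsions)
        for i in range(N_ANCHORS, N_ANCHORS + template.length):
            phi, psi, omega = torsions[i]
            dphi, dpsi = rng.normal(0.0, torsion_noise_deg, size=2)
            torsions[i] = (phi + dphi, psi + dpsi, omega)
    atoms = build_backbone(torsions, template.geometry_constants)

    length = template.length
    if sequence is None:
        sequence = _default_sequence(length, rng)
    if len(sequence) != length:
        raise ValueError("sequence length must match template length")
    if source is None:
        source = f"sy{seed % 100:02d}:A"

    start, end = CDR_WINDOWS[cdr_of_type(template.cdr_type)]
    cdr_labels = imgt_positions(template.cdr_type, length)
    positions = (
        [(p, "") for p in range(start - N_ANCHORS, start)]
        + cdr_labels
        + [(p, "") for p in range(end + 1, end + 1 + N_ANCHORS)]
    )
    anchor_seq_n = "G" * N_ANCHORS
    anchor_seq_c = "G" * N_ANCHORS
    full_seq = anchor_seq_n + sequence.upper() + anchor_seq_c

    residues: list[ResidueRecord] = []
    for i, ((pos, icode), aa) in enumerate(zip(positions, full_seq)):
        coords = {role: np.array(atoms[i][role], dtype=float) for role in ("N", "CA", "C", "O")}
        if noise_sd > 0 and N_ANCHORS <= i < N_ANCHORS + length:
            for role in coords:
                coords[role] = coords[role] + rng.normal(0.0, noise_sd, size=3)
        residues.append(ResidueRecord(pos, icode, aa, coords,
                                      {role: bfactor for role in ("N", "CA", "C", "O")}))
    return LoopRecord(
        cdr_type=template.cdr_type,
        sequence=sequence.upper(),
        cdr_residues=residues[N_ANCHORS:N_ANCHORS + length],
        anchors_n=residues[:N_ANCHORS],
        anchors_c=residues[N_ANCHORS + length:],
        source=source,
        resolution=resolution,
        bound_state=bound_state,
    )


#: Distinct CDR φ/ψ profiles used for planted cluster families.
FAMILY_PROFILES: list[tuple[float, float]] = [
    (-139.0, 135.0),   # extended β
    (-57.0, -47.0),    # α-helical
    (57.0, 47.0),      # left-handed helical
    (75.0, -60.0),
    (-80.0, 60.0),
]


def default_templates(k: int, cdr_type: str = "a1", length: int = 6) -> list[LoopTemplate]:
    if k > len(FAMILY_PROFILES):
        raise ValueError(f"at most {len(FAMILY_PROFILES)} default families")
    return [
        LoopTemplate(cdr_type, [FAMILY_PROFILES[f]] * length)
        for f in range(k)
    ]


@dataclass
class PlantedDataset:
    """Loops plus the ground truth they were generated from."""

    loops: list[LoopRecord]
    truth: list[int]  # planted family index per loop
    seed: int
    templates: list[LoopTemplate] = field(default_factory=list)
    sequences_by_family: list[list[str]] = field(default_factory=list)


def make_cluster_set(k: int = 3,
                     per_family: int = 7,
                     base_templates: Optional[list[LoopTemplate]] = None,
                     noise_sd: float = 0.005,
                     torsion_noise_deg: float = 0.3,
                     seed: int = 0,
                     eps: float = 1.0,
                     unique_sequences_per_family: int = 3,
                     plant_shared_sequence: bool = False,
                     cdr_type: str = "a1",
                     length: int = 6,
                     calibrate: bool = True) -> PlantedDataset:
    """Generate ``k`` loop families with planted cluster structure.

    Calibration is asserted at generation time: template pairwise DTW
    distances must exceed 3×eps and intra-family DTW must stay below
    eps/2, so DBSCAN at ``eps`` recovers the planted partition.
    """
    templates = base_templates or default_templates(k, cdr_type, length)
    if len(templates) != k:
        raise ValueError("need one template per family")
    rng = np.random.default_rng(seed)

    # family sequences mimic canonical-class motifs: a per-family consensus
    # over a family-private alphabet, varied by single point mutations
    per = len(AMINO_ACIDS) // k
    if per < 2:
        raise ValueError("too many families for disjoint sequence alphabets")
    sequences_by_family: list[list[str]] = []
    for fam in range(k):
        alphabet = AMINO_ACIDS[fam * per:(fam + 1) * per]
        loop_len = templates[fam].length
        consensus = [str(rng.choice(list(alphabet))) for _ in range(loop_len)]
        seqs: set[str] = set()
        while len(seqs) < unique_sequences_per_family:
            pos = int(rng.integers(loop_len))
            sub = str(rng.choice([a for a in alphabet if a != consensus[pos]]))
            mutant = consensus.copy()
            mutant[pos] = sub
            seqs.add("".join(mutant))
        sequences_by_family.append(sorted(seqs))
    if plant_shared_sequence and k >= 2:
        sequences_by_family[1][0] = sequences_by_family[0][0]

    loops: list[LoopRecord] = []
    truth: list[int] = []
    child_seeds = np.random.SeedSequence(seed).spawn(k * per_family)
    for fam in range(k):
        for m in range(per_family):
            child = int(child_seeds[fam * per_family + m].generate_state(1)[0] % (2 ** 31))
            seq = sequences_by_family[fam][m % unique_sequences_per_family]
            loops.append(make_loop(
                templates[fam],
                noise_sd=noise_sd,
                torsion_noise_deg=torsion_noise_deg,
                seed=child,
                sequence=seq,
                source=f"c{fam}{m:02d}:A",
            ))
            truth.append(fam)

    if calibrate:
        refs = [make_loop(t, noise_sd=0.0, torsion_noise_deg=0.0, seed=0,
                          sequence="A" * t.length, source=f"t{f:03d}:A")
                for f, t in enumerate(templates)]
        for i in range(k):
            for j in range(i + 1, k):
                d = geometry.dtw_distance(refs[i], refs[j])
                if d <= 3.0 * eps:
                    raise ValueError(
                        f"templates {i} and {j} too close: DTW {d:.2f} <= {3 * eps:.2f} Å")
        for fam in range(k):
            members = [lp for lp, t in zip(loops, truth) if t == fam]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    d = geometry.dtw_distance(members[a], members[b])
                    if d >= eps / 2:
                        raise ValueError(
                            f"family {fam} too noisy: intra DTW {d:.2f} >= {eps / 2:.2f} Å")

    return PlantedDataset(loops, truth, seed, templates, sequences_by_family)


def make_displaced_loops(template: LoopTemplate,
                         offsets: Sequence[float],
                         seed: int = 0,
                         direction: Optional[np.ndarray] = None,
                         sequence: Optional[str] = None) -> list[LoopRecord]:
    """Loops whose pairwise anchor-frame backbone RMSDs are exact by construction.

    Each loop is the template loop with every CDR atom displaced by
    ``offset`` along one shared unit direction, anchors untouched.  With
    identical anchors the anchor fit is the identity, so the backbone RMSD
    between loops i and j (fit_on="anchors") equals |offset_i - offset_j|.
    """
    rng = np.random.default_rng(seed)
    if direction is None:
        direction = rng.normal(size=3)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    if sequence is None:
        sequence = _default_sequence(template.length, rng)
    base = make_loop(template, noise_sd=0.0, seed=seed, sequence=sequence,
                     source="d000:A")
    loops = []
    for k, offset in enumerate(offsets):
        shift = float(offset) * direction
        moved = LoopRecord(
            base.cdr_type,
            base.sequence,
            [ResidueRecord(r.imgt_position, r.insertion_code, r.amino_acid,
                           {role: np.asarray(xyz, dtype=float) + shift
                            for role, xyz in r.backbone_atoms.items()},
                           dict(r.bfactors))
             for r in base.cdr_residues],
            [ResidueRecord(r.imgt_position, r.insertion_code, r.amino_acid,
                           {role: np.asarray(xyz, dtype=float).copy()
                            for role, xyz in r.backbone_atoms.items()},
                           dict(r.bfactors))
             for r in base.anchors_n],
            [ResidueRecord(r.imgt_position, r.insertion_code, r.amino_acid,
                           {role: np.asarray(xyz, dtype=float).copy()
                            for role, xyz in r.backbone_atoms.items()},
                           dict(r.bfactors))
             for r in base.anchors_c],
            source=f"d{k:03d}:A",
            resolution=base.resolution,
        )
        loops.append(moved)
    return loops


#: CDR3 torso torsion profiles giving a robustly negative (extended) or
#: positive (kinked) pseudo dihedral α116.  The profile is β-strand-like
#: except around the penultimate residue, whose torsions set the sign of
#: the Cα pseudo dihedral at position 116.
TORSO_PROFILES: dict[str, list[tuple[float, float]]] = {
    "extended": [(-139.0, 135.0)] * 6 + [(60.0, 120.0), (90.0, -120.0), (150.0, 90.0)],
    "kinked": [(-139.0, 135.0)] * 6 + [(-150.0, 60.0), (90.0, -120.0), (30.0, -30.0)],
}


def make_torso(kind: str, seed: int = 0, torsion_noise_deg: float = 3.0) -> LoopRecord:
    """CDR3-like loop whose α116 sign matches the requested torso kind."""
    if kind not in TORSO_PROFILES:
        raise ValueError("kind must be 'kinked' or 'extended'")
    template = LoopTemplate("b3", list(TORSO_PROFILES[kind]))
    return make_loop(template, noise_sd=0.0, torsion_noise_deg=torsion_noise_deg,
                     seed=seed, source=f"tr{seed % 100:02d}:B")


@dataclass
class SequenceClassSet:
    """Planted, separable sequence classes for PSSM validation."""

    classes: dict[str, list[str]]
    decoys: list[str]
    cdr_type: str
    length: int
    seed: int


def make_sequence_classes(n_classes: int = 2,
                          seqs_per_class: int = 10,
                          length: int = 6,
                          cdr_type: str = "a1",
                          n_decoys: int = 0,
                          seed: int = 0) -> SequenceClassSet:
    """Sequence classes over disjoint residue alphabets (plus decoys).

    Each class is built as single-point mutants of a class consensus drawn
    from its own alphabet, mimicking the conserved motifs of real
    canonical classes.  Disjoint alphabets make the classes separable by
    construction: a residue from one class's alphabet is never observed in
    another class, so cross-class scores collapse to the unseen-residue
    penalty, while within-class scores stay high through the conserved
    consensus positions.
    """
    n_groups = n_classes + (1 if n_decoys > 0 else 0)
    per = len(AMINO_ACIDS) // n_groups
    if per < 2:
        raise ValueError("too many classes for disjoint alphabets")
    rng = np.random.default_rng(seed)
    alphabets = [AMINO_ACIDS[g * per:(g + 1) * per] for g in range(n_groups)]

    def draw_class(alphabet: str, n: int) -> list[str]:
        if n > length * (len(alphabet) - 1):
            raise ValueError("too many sequences for single-mutant construction")
        consensus = [str(rng.choice(list(alphabet))) for _ in range(length)]
        mutants: set[str] = set()
        while len(mutants) < n:
            pos = int(rng.integers(length))
            sub = str(rng.choice([a for a in alphabet if a != consensus[pos]]))
            seq = consensus.copy()
            seq[pos] = sub
            mutants.add("".join(seq))
        return sorted(mutants)

    def draw_random(alphabet: str, n: int) -> list[str]:
        seqs: set[str] = set()
        while len(seqs) < n:
            seqs.add("".join(rng.choice(list(alphabet), size=length)))
        return sorted(seqs)

    classes = {f"class_{i}": draw_class(alphabets[i], seqs_per_class)
               for i in range(n_classes)}
    decoys = draw_random(alphabets[-1], n_decoys) if n_decoys > 0 else []
    return SequenceClassSet(classes, decoys, cdr_type, length, seed)
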