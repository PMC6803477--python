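"""Geometry: superposition, DTW, RMSD, torso angles and frames."""
import itertools
import math

import numpy as np
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from canonloop import geometry as ge
from canonloop.records import LoopRecord, ResidueRecord
from canonloop.synthetic import LoopTemplate, make_displaced_loops, make_loop
from conftest import random_rigid_motion


# ---------------------------------------------------------------------------
# Kabsch

class TestKabsch:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        tf, rmsd = ge.kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)

    def test_recovers_planted_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        rot, trans = random_rigid_motion(rng)
        moved = pts @ rot.T + trans
        tf, rmsd = ge.kabsch(pts, moved)
        assert rmsd < 1e-9
        assert np.allclose(tf.rotation, rot, atol=1e-6)
        tf.validate()

    def test_reflection_gives_proper_rotation_and_positive_rmsd(self):
        # a chiral 4-point set and its mirror image: no proper rotation can
        # superpose them, so rmsd > 0, yet det(R) must stay +1
        pts = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.0, 0], [0.3, 0.4, 2.0]])
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        tf, rmsd = ge.kabsch(mirrored, pts)
        assert rmsd > 0.1
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        # brute-force over random proper rotations: none beats the Kabsch fit
        rng = np.random.default_rng(2)
        centred_m = mirrored - mirrored.mean(axis=0)
        centred_p = pts - pts.mean(axis=0)
        for _ in range(500):
            rot, _ = random_rigid_motion(rng)
            cand = np.sqrt(np.mean(np.sum((centred_m @ rot.T - centred_p) ** 2, axis=1)))
            assert cand >= rmsd - 1e-9

    @pytest.mark.parametrize("pts", [
        np.zeros((2, 3)),
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
    ])
    def test_degenerate_input_raises(self, pts):
        with pytest.raises(ge.DegenerateGeometryError):
            ge.kabsch(pts, pts + 1.0)


# ---------------------------------------------------------------------------
# anchor superposition

class TestAnchorSuperpose:
    def test_rigid_copy_coincides(self, helix_loop):
        rng = np.random.default_rng(3)
        rot, trans = random_rigid_motion(rng)
        moved = helix_loop.transformed(rot, trans)
        back = ge.anchor_superpose(helix_loop, moved)
        assert np.allclose(back.cdr_backbone(), helix_loop.cdr_backbone(), atol=1e-9)

    def test_cdr_perturbation_preserved(self, helix_template):
        base = make_loop(helix_template, seed=4, sequence="ACDEFG", source="p000:A")
        shifted = make_displaced_loops(helix_template, [0.0, 0.7], seed=4,
                                       sequence="ACDEFG")
        fitted = ge.anchor_superpose(shifted[0], shifted[1])
        assert np.allclose(fitted.anchor_backbone(), shifted[0].anchor_backbone(),
                           atol=1e-9)
        dev = np.linalg.norm(fitted.cdr_backbone() - shifted[0].cdr_backbone(), axis=1)
        assert np.allclose(dev, 0.7, atol=1e-9)
        del base

    def test_invariant_to_rigid_premotion(self, helix_loop, cdr3_loop):
        rng = np.random.default_rng(5)
        other = make_loop(LoopTemplate("a1", [(-75.0, 150.0)] * 6),
                          seed=9, sequence="GGGGGG", source="q000:A")
        d0 = ge.dtw_distance(helix_loop, other)
        for _ in range(5):
            rot, trans = random_rigid_motion(rng)
            assert ge.dtw_distance(helix_loop, other.transformed(rot, trans)) == \
                pytest.approx(d0, abs=1e-6)


# ---------------------------------------------------------------------------
# DTW

def brute_force_dtw(cost: np.ndarray) -> float:
    """Enumerate every monotone boundary-to-boundary warping path."""
    n, m = cost.shape
    best = (math.inf, 0)

    def walk(i, j, total, length):
        nonlocal best
        total += cost[i, j]
        length += 1
        if (i, j) == (n - 1, m - 1):
            best = min(best, (total, length))
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, total, length)

    walk(0, 0, 0.0, 0)
    return best[0] / best[1]


class TestDTW:
    def test_identical_loops_score_zero(self, helix_loop):
        assert ge.dtw_distance(helix_loop, helix_loop) == pytest.approx(0.0, abs=1e-9)

    def test_forced_diagonal_equals_mean_residue_rmsd(self, helix_template):
        # uniform CDR displacement with identical anchors: the cost matrix
        # diagonal is the offset and off-diagonals are larger, so the optimal
        # path is the diagonal and the score is the mean per-residue RMSD
        a, b = make_displaced_loops(helix_template, [0.0, 0.4], seed=6)
        fitted = ge.anchor_superpose(a, b)
        cost = ge._residue_cost_matrix(a, fitted)
        per_residue = np.diag(cost)
        score = ge.dtw_distance(a, b)
        assert score == pytest.approx(float(per_residue.mean()), abs=1e-9)
        # sanity relation: the anchor-frame backbone RMSD cannot exceed the
        # worst matched-residue cost on the diagonal path
        assert ge.backbone_rmsd(a, b, fit_on="anchors") <= per_residue.max() + 1e-9

    @pytest.mark.parametrize("la,lb", [(4, 5), (3, 5), (5, 5), (1, 4)])
    def test_matches_path_enumeration(self, la, lb):
        rng = np.random.default_rng(100 * la + lb)
        for _ in range(25):
            cost = rng.uniform(0.0, 3.0, size=(la, lb))
            total, length = ge._dtw_on_costs(cost)
            assert total / length == pytest.approx(brute_force_dtw(cost), abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(arrays(np.float64, (4, 5), elements=st.floats(0.0, 5.0)))
    def test_dp_equals_enumeration_for_arbitrary_costs(self, cost):
        total, length = ge._dtw_on_costs(cost)
        assert total / length == pytest.approx(brute_force_dtw(cost), abs=1e-12)

    def test_symmetry_and_nonnegativity(self):
        t1 = LoopTemplate("a3", [(-139.0, 135.0)] * 10)
        t2 = LoopTemplate("a3", [(-57.0, -47.0)] * 12)
        a = make_loop(t1, seed=1, source="a000:A")
        b = make_loop(t2, seed=2, source="b000:A")
        dab = ge.dtw_distance(a, b)
        assert dab >= 0
        assert dab == pytest.approx(ge.dtw_distance(b, a), abs=1e-9)

    def test_empty_cdr_rejected(self, helix_loop):
        empty = LoopRecord("a1", "", [], helix_loop.anchors_n, helix_loop.anchors_c,
                           "e000:A")
        with pytest.raises(ValueError):
            ge.dtw_distance(helix_loop, empty)


# ---------------------------------------------------------------------------
# backbone RMSD

class TestBackboneRMSD:
    def test_self_is_zero(self, helix_loop):
        assert ge.backbone_rmsd(helix_loop, helix_loop) == pytest.approx(0.0, abs=1e-9)

    def test_single_atom_displacement_closed_form(self, helix_loop):
        import copy
        other = LoopRecord.from_dict(helix_loop.to_dict())
        d = 0.9
        other.cdr_residues[2].backbone_atoms["CA"] = \
            other.cdr_residues[2].backbone_atoms["CA"] + np.array([0.0, 0.0, d])
        L = helix_loop.length
        expected = d / math.sqrt(4 * L)
        assert ge.backbone_rmsd(helix_loop, other, fit_on="anchors") == \
            pytest.approx(expected, abs=1e-9)
        del copy

    def test_symmetric(self, helix_template):
        a, b = make_displaced_loops(helix_template, [0.0, 0.5], seed=8)
        assert ge.backbone_rmsd(a, b) == pytest.approx(ge.backbone_rmsd(b, a), abs=1e-12)

    def test_length_mismatch_rejected(self, helix_loop, cdr3_loop):
        with pytest.raises(ValueError):
            ge.backbone_rmsd(helix_loop, cdr3_loop)


# ---------------------------------------------------------------------------
# pseudo bond / dihedral angles

class TestAngles:
    def test_collinear_is_180(self):
        assert ge.pseudo_bond_angle((0, 0, 0), (1, 0, 0), (2, 0, 0)) == \
            pytest.approx(180.0)

    def test_orthogonal_is_90(self):
        assert ge.pseudo_bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == \
            pytest.approx(90.0)

    def test_bond_angle_matches_vector_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p1, p2, p3 = rng.normal(scale=5.0, size=(3, 3))
            v1, v2 = p1 - p2, p3 - p2
            expected = math.degrees(math.acos(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
            assert ge.pseudo_bond_angle(p1, p2, p3) == pytest.approx(expected, abs=1e-9)

    def test_cis_is_zero_trans_is_180(self):
        p = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]
        assert ge.pseudo_dihedral(*p) == pytest.approx(0.0, abs=1e-9)
        q = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]
        assert abs(ge.pseudo_dihedral(*q)) == pytest.approx(180.0, abs=1e-9)

    def test_dihedral_matches_biopython(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            pts = rng.normal(scale=5.0, size=(4, 3))
            expected = math.degrees(calc_dihedral(*(Vector(*p) for p in pts)))
            assert ge.pseudo_dihedral(*pts) == pytest.approx(expected, abs=1e-9)

    def test_mirror_negates_dihedral(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            ang = ge.pseudo_dihedral(*pts)
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert ge.pseudo_dihedral(*mirrored) == pytest.approx(-ang, abs=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(ge.DegenerateGeometryError):
            ge.pseudo_bond_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))
        with pytest.raises(ge.DegenerateGeometryError):
            ge.pseudo_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


# ---------------------------------------------------------------------------
# LAT

class TestLAT:
    def test_pure_translation_along_frame_axis(self, cdr3_loop):
        res105 = cdr3_loop.find_residue(105)
        origin, frame = ge.residue_frame(res105)
        # synthetic residue 117 = copy of 105 translated along frame x
        shift = frame[:, 0] * 4.2
        res117 = ResidueRecord(117, "", "A", {
            role: res105.backbone_atoms[role] + shift for role in ("N", "CA", "C", "O")})
        hybrid = LoopRecord.from_dict(cdr3_loop.to_dict())
        for i, r in enumerate(hybrid.cdr_residues):
            if r.imgt_position == 117:
                hybrid.cdr_residues[i] = res117
        for i, r in enumerate(hybrid.cdr_residues):
            if r.imgt_position == 105:
                hybrid.cdr_residues[i] = res105
        x, y, z, phi, psi, theta = ge.lat(hybrid)
        assert (x, y, z) == pytest.approx((4.2, 0.0, 0.0), abs=1e-9)
        # rotation is the identity: the z-y-z angles sum to zero net rotation
        assert abs(phi + theta) % 360.0 == pytest.approx(0.0, abs=1e-6)
        assert psi == pytest.approx(0.0, abs=1e-6)
        del origin

    def test_invariant_under_global_rigid_motion(self, cdr3_loop):
        rng = np.random.default_rng(14)
        ref = ge.lat(cdr3_loop)
        for _ in range(10):
            rot, trans = random_rigid_motion(rng)
            moved = cdr3_loop.transformed(rot, trans)
            assert np.allclose(ge.lat(moved), ref, atol=1e-6)

    def test_round_trip_reproduces_frame_117(self, cdr3_loop):
        from scipy.spatial.transform import Rotation
        o1, r1 = ge.residue_frame(cdr3_loop.find_residue(105))
        o2, r2 = ge.residue_frame(cdr3_loop.find_residue(117))
        x, y, z, phi, psi, theta = ge.lat(cdr3_loop)
        rel = Rotation.from_euler(ge.LAT_EULER_CONVENTION, [phi, psi, theta],
                                  degrees=True).as_matrix()
        assert np.allclose(r1 @ rel, r2, atol=1e-9)
        assert np.allclose(o1 + r1 @ np.array([x, y, z]), o2, atol=1e-9)


# ---------------------------------------------------------------------------
# phi/psi

class TestPhiPsi:
    def test_round_trip_of_template_torsions(self):
        template = LoopTemplate("a1", [(-57.0, -47.0)] * 6)
        loop = make_loop(template, seed=0, sequence="AAAAAA", source="r000:A")
        torsions = ge.phi_psi(loop.residues)
        full = template.full_torsions()
        for i in range(1, len(full) - 1):
            assert torsions[i][0] == pytest.approx(full[i][0], abs=1e-6)
            assert torsions[i][1] == pytest.approx(full[i][1], abs=1e-6)
        assert torsions[0][0] is None
        assert torsions[-1][1] is None

    def test_two_residue_chain(self, helix_loop):
        pair = helix_loop.residues[:2]
        torsions = ge.phi_psi(pair)
        assert torsions[0][0] is None and torsions[0][1] is not None
        assert torsions[1][0] is not None and torsions[1][1] is None

    def test_chain_break_undefined_at_junction(self, helix_loop):
        broken = LoopRecord.from_dict(helix_loop.to_dict())
        residues = broken.residues
        k = 6
        for res in residues[k:]:
            for role in res.backbone_atoms:
                res.backbone_atoms[role] = res.backbone_atoms[role] + np.array([9.0, 0, 0])
        torsions = ge.phi_psi(residues)
        assert torsions[k - 1][1] is None
        assert torsions[k][0] is None
        assert torsions[k - 1][0] is not None

    def test_matches_quadruple_torsion_oracle(self, cdr3_loop):
        residues = cdr3_loop.residues
        torsions = ge.phi_psi(residues)
        for i in range(1, len(residues) - 1):
            phi_oracle = math.degrees(calc_dihedral(
                Vector(*residues[i - 1].atom("C")), Vector(*residues[i].atom("N")),
                Vector(*residues[i].atom("CA")), Vector(*residues[i].atom("C"))))
            psi_oracle = math.degrees(calc_dihedral(
                Vector(*residues[i].atom("N")), Vector(*residues[i].atom("CA")),
                Vector(*residues[i].atom("C")), Vector(*residues[i + 1].atom("N"))))
            assert torsions[i][0] == pytest.approx(phi_oracle, abs=1e-9)
            assert torsions[i][1] == pytest.approx(psi_oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# torso classification

class TestTorsoClass:
    @pytest.mark.parametrize("alpha,expected", [
        (-35.0, "extended"),
        (35.0, "kinked"),
        (0.0, "extended"),  # boundary assigned to extended
    ])
    def test_sign_rule(self, alpha, expected):
        assert ge.torso_class(100.0, alpha) == expected

    def test_torso_geometry_fields(self, cdr3_loop):
        tg = ge.torso_geometry(cdr3_loop)
        assert 0.0 < tg.tau116 <= 180.0
        assert -180.0 < tg.alpha116 <= 180.0
        assert set(tg.torso_phi_psi) == {f"T{i}" for i in range(1, 8)}
        assert tg.torso_class in {"kinked", "extended"}
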