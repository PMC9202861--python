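"""Superposition, H-bond and tight-turn geometry, and fingerprint assembly."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import helixprime as hp
from helixprime.geometry import GeometryError, REFERENCE_ROLES
from helixprime.structure_io import extract_backbone

from conftest import WINDOW
from oracles import brute_force_superposition_rmsd

RNG = np.random.default_rng(2024)


def random_rigid_motion(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


class TestKabsch:
    def test_self_superposition_is_identity(self, ideal_segment):
        res = hp.kabsch_superpose(ideal_segment.coords(), ideal_segment.coords())
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_gives_zero_rmsd(self, ideal_segment):
        pts = ideal_segment.coords()
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([5.0, -3.0, 2.0])
        res = hp.kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_always_proper(self):
        for _ in range(20):
            a = RNG.normal(size=(8, 3))
            b = RNG.normal(size=(8, 3))
            res = hp.kabsch_superpose(a, b)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_not_used_for_mirror_images(self):
        pts = RNG.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        res = hp.kabsch_superpose(pts, mirrored)
        # a chiral set cannot be superposed onto its mirror by proper rotation
        assert res.rmsd > 0.1

    def test_tetrahedron_matches_brute_force_oracle(self):
        tet = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.5, np.sqrt(3) / 2, 0.0],
                [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
            ]
        )
        displaced = tet.copy()
        displaced[3, 0] += 0.5
        res = hp.kabsch_superpose(tet, displaced)
        oracle = brute_force_superposition_rmsd(tet, displaced)
        assert res.rmsd == pytest.approx(oracle, abs=1e-3)

    def test_agrees_with_oracle_on_random_instances(self):
        # 50 random 10-point instances vs quaternion-search oracle
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(scale=3.0, size=(10, 3))
            b = a + rng.normal(scale=0.5, size=(10, 3))
            R, t = random_rigid_motion(rng)
            b = b @ R.T + t
            assert hp.kabsch_superpose(a, b).rmsd == pytest.approx(
                brute_force_superposition_rmsd(a, b), abs=1e-3
            )

    def test_size_mismatch_and_too_few_points(self):
        with pytest.raises(GeometryError, match="mismatch"):
            hp.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(GeometryError, match="at least 3"):
            hp.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_reported_as_degenerate(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(GeometryError, match="degenerate"):
            hp.kabsch_superpose(line, line)


class TestHelixOverlapRmsd:
    def test_self_is_zero_and_symmetric(self, ideal_segment, kinked_segment):
        assert hp.helix_overlap_rmsd(ideal_segment, ideal_segment) == pytest.approx(0.0, abs=1e-12)
        ab = hp.helix_overlap_rmsd(ideal_segment, kinked_segment)
        ba = hp.helix_overlap_rmsd(kinked_segment, ideal_segment)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_noise_band_and_oracle_agreement(self, ideal_helix, ideal_segment):
        rmsds = []
        for seed in range(100):
            noisy = hp.perturb(ideal_helix, 0.1, seed)
            seg = extract_backbone(noisy, WINDOW, reference_positions=WINDOW,
                                   check_continuity=False)
            rmsds.append(hp.helix_overlap_rmsd(seg, ideal_segment))
        assert all(0.05 <= r <= 0.2 for r in rmsds)
        # per-instance oracle agreement (first few instances)
        for seed in range(3):
            noisy = hp.perturb(ideal_helix, 0.1, seed)
            seg = extract_backbone(noisy, WINDOW, reference_positions=WINDOW,
                                   check_continuity=False)
            assert hp.helix_overlap_rmsd(seg, ideal_segment) == pytest.approx(
                brute_force_superposition_rmsd(seg.coords(), ideal_segment.coords()),
                abs=1e-3,
            )

    def test_kink_separates_from_noise(self, ideal_helix, ideal_segment, kinked_segment):
        noisy = hp.perturb(ideal_helix, 0.1, 0)
        seg = extract_backbone(noisy, WINDOW, reference_positions=WINDOW,
                               check_continuity=False)
        noise_rmsd = hp.helix_overlap_rmsd(seg, ideal_segment)
        kink_rmsd = hp.helix_overlap_rmsd(kinked_segment, ideal_segment)
        assert kink_rmsd > noise_rmsd
        assert kink_rmsd == pytest.approx(
            brute_force_superposition_rmsd(
                kinked_segment.coords(), ideal_segment.coords()
            ),
            abs=1e-3,
        )

    def test_window_mismatch_lists_positions(self, ideal_segment):
        sub = ideal_segment.subset(range(60, 73))
        with pytest.raises(GeometryError, match="73"):
            hp.helix_overlap_rmsd(ideal_segment, sub)

    def test_triangle_like_inequality(self, ideal_segment, kinked_segment, ideal_helix):
        noisy = hp.perturb(ideal_helix, 0.3, 5)
        seg = extract_backbone(noisy, WINDOW, reference_positions=WINDOW,
                               check_continuity=False)
        ac = hp.helix_overlap_rmsd(ideal_segment, kinked_segment)
        ab = hp.helix_overlap_rmsd(ideal_segment, seg)
        bc = hp.helix_overlap_rmsd(seg, kinked_segment)
        assert ac <= ab + bc + 1e-6


class TestHbondDistances:
    def test_ideal_helix_all_near_3A(self, ideal_segment):
        hd = hp.hbond_distances(ideal_segment)
        assert set(hd) == {f"HD{k}" for k in range(1, 12)}
        assert all(2.7 <= v <= 3.3 for v in hd.values())

    def test_extended_strand_all_far(self):
        profile = hp.TorsionProfile((180.0,) * 15, (180.0,) * 15, (180.0,) * 15)
        st = hp.build_backbone(profile)
        seg = extract_backbone(st, WINDOW, reference_positions=WINDOW,
                               check_continuity=False)
        assert all(v > 10 for v in hp.hbond_distances(seg).values())

    def test_kink_breaks_hbonds_in_block(self, kinked_segment):
        hd = hp.hbond_distances(kinked_segment)
        # bonds crossing the 64-67 kink open far beyond helical range
        assert max(hd[f"HD{k}"] for k in range(3, 8)) > 4.5
        # bonds away from the kink stay helical
        assert hd["HD1"] == pytest.approx(3.09, abs=0.05)
        assert hd["HD11"] == pytest.approx(3.09, abs=0.05)

    def test_incomplete_window_raises(self, ideal_segment):
        short = hp.BackboneSegment(ideal_segment.residues[:14])
        with pytest.raises(GeometryError, match="incomplete"):
            hp.hbond_distances(short)


class TestTightTurn:
    def test_constructed_distance_recovered(self, ideal_helix, identity_map):
        d = hp.tight_turn_distance(ideal_helix, identity_map)
        n67 = ideal_helix.atom(67, "N").position
        c65 = ideal_helix.atom(65, "C").position
        assert d == pytest.approx(float(np.linalg.norm(n67 - c65)), abs=1e-6)

    def test_kinked_turn_is_tighter_than_ideal(self, ideal_helix, kinked_helix, identity_map):
        d_ideal = hp.tight_turn_distance(ideal_helix, identity_map)
        d_kink = hp.tight_turn_distance(kinked_helix, identity_map)
        assert d_ideal > d_kink

    def test_missing_anchor_raises(self, ideal_helix):
        rmap = hp.ResidueMap("x", [(p, p) for p in WINDOW], anchors={65: 65})
        with pytest.raises(GeometryError, match="67"):
            hp.tight_turn_distance(ideal_helix, rmap)

    def test_alternative_atom_pair_definition(self, ideal_helix, identity_map):
        alt = hp.TightTurnDefinition(donor_position=67, donor_atom="N",
                                     acceptor_position=65, acceptor_atom="CA")
        d = hp.tight_turn_distance(ideal_helix, identity_map, alt)
        ca65 = ideal_helix.atom(65, "CA").position
        n67 = ideal_helix.atom(67, "N").position
        assert d == pytest.approx(float(np.linalg.norm(n67 - ca65)), abs=1e-9)


class TestFingerprint:
    @pytest.fixture
    def references(self, ideal_segment, kinked_segment, ideal_helix):
        mature = hp.build_backbone(
            hp.kinked_helix_profile(15, kink_torsions=(-73.1, -7.1))
        )
        seg = extract_backbone(mature, WINDOW, reference_positions=WINDOW)
        return {"1EMA": seg, "2AWJ": kinked_segment, "1H4U": ideal_segment}

    def test_target_equal_to_reference_has_zero_rmsd(self, ideal_helix, identity_map, references):
        fp = hp.fingerprint(ideal_helix, identity_map, references)
        assert fp.rmsd_vs_1H4U == pytest.approx(0.0, abs=1e-9)
        assert fp.rmsd_vs_2AWJ > 1.0

    def test_schema_completeness(self, kinked_helix, identity_map, references):
        rmap = hp.ResidueMap("kinked", [(p, p) for p in WINDOW],
                             anchors={65: 65, 66: 66, 67: 67})
        fp = hp.fingerprint(kinked_helix, rmap, references, predictor="synthetic",
                            label="can_form")
        row = fp.as_row()
        from helixprime.geometry import FINGERPRINT_COLUMNS
        assert set(row) == set(FINGERPRINT_COLUMNS)
        assert len(fp.hd) == 11
        assert all(np.isfinite(v) and v > 0 for v in fp.hd.values())

    def test_subset_reference_keeps_atom_counts_equal(self, ideal_helix, identity_map, references):
        # the mature reference without the chromophore residues 65-67
        positions = [p for p in WINDOW if p not in (65, 66, 67)]
        refs = dict(references)
        refs["1EMA"] = references["1EMA"].subset(positions)
        fp = hp.fingerprint(ideal_helix, identity_map, refs)
        assert np.isfinite(fp.rmsd_vs_1EMA)

    def test_rigid_motion_invariance_of_all_fields(self, kinked_helix, identity_map, references):
        fp0 = hp.fingerprint(kinked_helix, identity_map, references)
        R, t = random_rigid_motion(np.random.default_rng(3))
        moved = kinked_helix.transformed(R, t)
        fp1 = hp.fingerprint(moved, identity_map, references)
        for name in ("rmsd_vs_1EMA", "rmsd_vs_2AWJ", "rmsd_vs_1H4U", "tight_turn"):
            assert getattr(fp1, name) == pytest.approx(getattr(fp0, name), abs=1e-9)
        for k, v in fp0.hd.items():
            assert fp1.hd[k] == pytest.approx(v, abs=1e-9)

    def test_error_annotated_with_target_id(self, ideal_helix, references):
        rmap = hp.ResidueMap("broken_target", [(p, p + 900) for p in WINDOW],
                             anchors={65: 965, 67: 967})
        with pytest.raises(GeometryError, match="broken_target"):
            hp.fingerprint(ideal_helix, rmap, references)
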