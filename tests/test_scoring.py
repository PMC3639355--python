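import numpy as np
import pytest

from tmrepack.bundle import set_rigid_variables
from tmrepack.fixtures import FixtureSpec, make_ideal_bundle
from tmrepack.scoring import (
    ScoreReport,
    ScoreWeights,
    aromatic_vdw_energy,
    elevation_penalty,
    find_pockets,
    helix_center_distance_score,
    hydrophilic_exposure,
    key_interaction_filter,
    ligand_score,
    loop_span_penalty,
    molecular_volume_area,
    score_model,
    serine_hbond_energy,
    tilt_penalty,
    total_score,
)
from tmrepack.structure import Structure


def _single_atom(element="C"):
    return Structure(np.zeros((1, 3)), ["X1"], [element], [1], ["LIG"])


class TestVolumeArea:
    def test_single_sphere_analytic_oracle(self):
        from tmrepack.forcefield import VDW_RADII

        st = _single_atom("C")
        vol, _ = molecular_volume_area(st, probe=0.0, spacing=0.3)
        expect = 4.0 / 3.0 * np.pi * VDW_RADII["C"] ** 3
        assert vol == pytest.approx(expect, rel=0.02)

    def test_expanded_bundle_has_larger_area(self, ideal_bundle):
        from dataclasses import replace

        expanded = ideal_bundle
        for hid in range(2, 8):
            v = expanded.get_rigid_variables(hid)
            expanded = set_rigid_variables(expanded, hid, replace(v, radial=v.radial + 10.0))
        _, a0 = molecular_volume_area(ideal_bundle.structure, spacing=1.0)
        _, a1 = molecular_volume_area(expanded.structure, spacing=1.0)
        assert a1 > a0

    def test_empty_structure(self):
        st = Structure(np.zeros((0, 3)), [], [], [], [])
        assert molecular_volume_area(st) == (0.0, 0.0)

    def test_duplicate_coordinates_same_as_deduplicated(self):
        # documented behavior: duplicates are harmless for the grid volume
        st1 = _single_atom()
        st2 = Structure(np.zeros((2, 3)), ["X1", "X2"], ["C", "C"], [1, 1], ["LIG", "LIG"])
        v1, _ = molecular_volume_area(st1, probe=0.0, spacing=0.4)
        v2, _ = molecular_volume_area(st2, probe=0.0, spacing=0.4)
        assert v1 == pytest.approx(v2)


class TestPockets:
    def test_ideal_bundle_no_buried_pockets(self, ideal_bundle):
        buried = [p for p in find_pockets(ideal_bundle.structure) if p[1]]
        assert buried == []

    def test_removed_helix_leaves_pocket_at_site(self, ideal_bundle):
        keep = np.ones(len(ideal_bundle.structure), bool)
        keep[ideal_bundle.helix_slices[0]] = False  # central helix
        site = ideal_bundle.helix_center(1)
        pockets = find_pockets(
            ideal_bundle.structure.select(keep), surface_probe=5.5, return_centroids=True
        )
        big = [p for p in pockets if p[0] > 100.0]
        assert big
        assert min(np.linalg.norm(c - site) for _, _, c in big) < 3.0

    def test_empty_structure_empty_list(self):
        st = Structure(np.zeros((0, 3)), [], [], [], [])
        assert find_pockets(st) == []


class TestHelixCenterDistance:
    def test_hexagon_plus_center_is_60(self):
        bundle = make_ideal_bundle(FixtureSpec(ring_radius=10.0))
        assert helix_center_distance_score(bundle) == pytest.approx(60.0, abs=1e-6)

    def test_coincident_centers_zero(self, ideal_bundle):
        collapsed = ideal_bundle.copy()
        for hid in range(1, 8):
            sl = collapsed.helix_slices[hid - 1]
            collapsed.structure.coords[sl] -= collapsed.helix_center(hid)
        assert helix_center_distance_score(collapsed) == pytest.approx(0.0, abs=1e-9)

    def test_axial_slide_increases_score_analytically(self, ideal_bundle):
        from dataclasses import replace

        base = helix_center_distance_score(ideal_bundle)
        v = ideal_bundle.get_rigid_variables(3)
        moved = set_rigid_variables(ideal_bundle, 3, replace(v, z_offset=v.z_offset + 5.0))
        got = helix_center_distance_score(moved)
        # analytic oracle: recompute center displacements directly
        c = moved.bundle_center
        expect = sum(
            np.linalg.norm(moved.helix_center(h) - c) for h in range(1, 8)
        )
        assert got == pytest.approx(expect, abs=1e-9)
        assert got > base

    def test_single_helix_rejected(self):
        bundle = make_ideal_bundle(FixtureSpec(n_helices=1, ring_radius=8.0))
        with pytest.raises(ValueError):
            helix_center_distance_score(bundle)


class TestHydrophilicExposure:
    def test_poly_ala_bundle_zero(self, ideal_bundle):
        assert hydrophilic_exposure(ideal_bundle) == (0.0, 0.0)

    def test_lysine_facing_lipid_exposes_more(self):
        # Lys mid-helix on a ring helix of a filled 7-helix bundle: facing
        # the core (center helix) vs facing the lipid void
        from dataclasses import replace

        from tmrepack.fixtures import _assemble_bundle, orient_residue_inward

        seqs = ["A" * 18] * 7
        seqs[1] = seqs[1][:9] + "K" + seqs[1][10:]
        bundle = _assemble_bundle(seqs, 11.5, include_center=True)
        rid = bundle.spans[1][0] + 9
        inward = orient_residue_inward(bundle, 2, rid)
        v = inward.get_rigid_variables(2)
        outward = set_rigid_variables(inward, 2, replace(v, spin=v.spin + 180.0))
        t1_in, t2_in = hydrophilic_exposure(inward)
        t1_out, t2_out = hydrophilic_exposure(outward)
        assert t2_out > t2_in
        # the core-facing group falls below the 25 % gate, the exposed one passes
        assert t1_in == 0.0
        assert t1_out > 0.0

    def test_lysine_outside_mid_third_contributes_zero(self):
        from tmrepack.fixtures import _assemble_bundle

        seqs = ["A" * 18] * 6
        seqs[0] = "K" + seqs[0][1:]  # at the helix terminus, outside mid-third
        bundle = _assemble_bundle(seqs, 12.0, include_center=False)
        assert hydrophilic_exposure(bundle) == (0.0, 0.0)


class TestTiltPenalty:
    def test_vertical_bundle_zero(self, ideal_bundle):
        assert tilt_penalty(ideal_bundle) == 0.0

    def test_below_threshold_zero(self, ideal_bundle):
        from dataclasses import replace

        v = ideal_bundle.get_rigid_variables(2)
        tilted = set_rigid_variables(ideal_bundle, 2, replace(v, tilt=45.0))
        assert tilt_penalty(tilted) == 0.0

    def test_65_degrees_gives_15(self):
        from dataclasses import replace

        # 10 helices: the 65-degree outlier is excluded from the axis
        # (floor(0.1*10) = 1), so the axis stays vertical and the penalty is
        # exactly 65 - 50 = 15
        bundle = make_ideal_bundle(FixtureSpec(n_helices=10, ring_radius=16.0))
        v = bundle.get_rigid_variables(5)
        tilted = set_rigid_variables(bundle, 5, replace(v, tilt=65.0, tilt_azimuth=20.0))
        assert tilt_penalty(tilted) == pytest.approx(15.0, abs=1e-6)


class TestElevationPenalty:
    def test_ideal_zero(self, ideal_bundle):
        assert elevation_penalty(ideal_bundle) == pytest.approx(0.0, abs=1e-9)

    def test_shift_matches_analytic(self, ideal_bundle):
        from dataclasses import replace
        from tmrepack.bundle import helix_elevations

        v = ideal_bundle.get_rigid_variables(4)
        moved = set_rigid_variables(ideal_bundle, 4, replace(v, z_offset=v.z_offset + 4.0))
        expect = np.sum(np.abs(helix_elevations(moved)))
        assert elevation_penalty(moved) == pytest.approx(expect)
        w = np.array([moved.helix_residue_count(h) for h in range(1, 8)], float)
        shift = 4.0 * w[3] / w.sum()
        analytic = (4.0 - shift) + 6 * shift
        assert elevation_penalty(moved) == pytest.approx(analytic, abs=1e-6)

    def test_global_translation_invariant(self, ideal_bundle):
        moved = ideal_bundle.copy()
        moved.structure.coords = moved.structure.coords + np.array([3.0, 4.0, 5.0])
        assert elevation_penalty(moved) == pytest.approx(elevation_penalty(ideal_bundle), abs=1e-9)


class TestLoopSpanPenalty:
    def test_within_reach_zero(self, ideal_bundle):
        # 10-residue loops can span 32 A; fixture termini are closer
        assert loop_span_penalty(ideal_bundle, [10] * 6) == 0.0

    def test_excess_squared(self):
        # two helices 36 A apart at the junction, 10-residue loop -> (36-32)^2
        from tmrepack.fixtures import build_ideal_helix
        from tmrepack.bundle import BundleState

        h1 = build_ideal_helix("A" * 12, first_resid=1)
        h2 = build_ideal_helix("A" * 12, first_resid=20)
        h2.coords = h2.coords @ np.diag([1.0, -1.0, -1.0])  # antiparallel
        b0 = BundleState(
            Structure.concat([h1, h2]),
            [slice(0, len(h1)), slice(len(h1), len(h1) + len(h2))],
            [(1, 12), (20, 31)],
        )
        # measure the junction distance, then push it to exactly 36 A
        a = b0.helix(1).ca_coords()[-1]
        c = b0.helix(2).ca_coords()[0]
        d0 = np.linalg.norm(a - c)
        shift = (36.0 - d0) * (c - a) / d0
        moved = b0.copy()
        moved.structure.coords[moved.helix_slices[1]] += shift
        assert loop_span_penalty(moved, [10]) == pytest.approx(16.0, abs=1e-6)

    def test_zero_length_loop_penalizes_any_separation(self, ideal_bundle):
        assert loop_span_penalty(ideal_bundle, [0] + [10] * 5) > 0.0

    def test_missing_length_skipped_with_warning(self, ideal_bundle):
        with pytest.warns(UserWarning):
            p = loop_span_penalty(ideal_bundle, [None] * 6)
        assert p == 0.0


class TestLigandScore:
    def test_distant_ligand_zero_contact_terms(self, pocket_bundle, pocket_spec, dopamine):
        pose = dopamine.copy()
        pose.coords = pose.coords + np.array([100.0, 0.0, 0.0])
        score, terms = ligand_score(pocket_bundle, pose, pocket_spec)
        assert terms["serine_hbond"] == 0.0
        assert terms["aromatic_vdw"] == pytest.approx(0.0, abs=1e-4)

    def test_salt_bridge_pose_beats_rotated_pose(self, pocket_bundle, pocket_spec, dopamine):
        st = pocket_bundle.structure
        od = st.coords[
            [st.atom_index(pocket_spec.aspartate_residue, "OD1"),
             st.atom_index(pocket_spec.aspartate_residue, "OD2")]
        ].mean(axis=0)
        good = dopamine.copy()
        n_idx = good.basic_n[0]
        # place the protonated amine 3 A from the carboxylate midpoint
        target = od + np.array([0.0, 0.0, 3.0])
        good.coords = good.coords + (target - good.coords[n_idx])
        bad = good.copy()
        # rotate the amine away: move whole ligand 8 A off
        bad.coords = bad.coords + np.array([0.0, 0.0, 8.0])
        s_good, _ = ligand_score(pocket_bundle, good, pocket_spec)
        s_bad, _ = ligand_score(pocket_bundle, bad, pocket_spec)
        assert s_good < s_bad

    def test_zero_weights_zero_score(self, pocket_bundle, pocket_spec, dopamine):
        w = ScoreWeights()
        w.ligand_terms = {k: 0.0 for k in w.ligand_terms}
        score, _ = ligand_score(pocket_bundle, dopamine, pocket_spec, w)
        assert score == 0.0

    def test_missing_named_residue_errors(self, pocket_bundle, pocket_spec, dopamine):
        import dataclasses

        spec = dataclasses.replace(pocket_spec, aspartate_residue=99999)
        with pytest.raises(KeyError):
            ligand_score(pocket_bundle, dopamine, spec)


class TestKeyInteractionFilter:
    def _posed(self, pocket_bundle, pocket_spec, dopamine, offset):
        st = pocket_bundle.structure
        od = st.coords[
            [st.atom_index(pocket_spec.aspartate_residue, "OD1"),
             st.atom_index(pocket_spec.aspartate_residue, "OD2")]
        ].mean(axis=0)
        pose = dopamine.copy()
        n_idx = pose.basic_n[0]
        pose.coords = pose.coords + (od + offset - pose.coords[n_idx])
        return pose

    def test_no_asp_contact_fails_with_salt_bridge_reason(
        self, pocket_bundle, pocket_spec, dopamine
    ):
        pose = self._posed(pocket_bundle, pocket_spec, dopamine, np.array([50.0, 0, 0]))
        ok, reasons = key_interaction_filter(pocket_bundle, pose, pocket_spec)
        assert not ok
        assert any("salt-bridge" in r for r in reasons)

    def test_boundary_semantics_exact_threshold(self, monkeypatch, pocket_bundle, pocket_spec, dopamine):
        import tmrepack.scoring as scoring

        pose = self._posed(pocket_bundle, pocket_spec, dopamine, np.array([0.0, 0.0, 2.5]))
        # force the aromatic term to exactly the threshold: must PASS
        monkeypatch.setattr(scoring, "aromatic_vdw_energy", lambda *a, **k: -0.3)
        monkeypatch.setattr(
            scoring, "hbond_energy", lambda *a, **k: -1.0
        )
        ok, reasons = scoring.key_interaction_filter(pocket_bundle, pose, pocket_spec)
        assert ok, reasons

    def test_weak_aromatic_contact_fails(self, monkeypatch, pocket_bundle, pocket_spec, dopamine):
        import tmrepack.scoring as scoring

        pose = self._posed(pocket_bundle, pocket_spec, dopamine, np.array([0.0, 0.0, 2.5]))
        monkeypatch.setattr(scoring, "aromatic_vdw_energy", lambda *a, **k: -0.1)
        monkeypatch.setattr(scoring, "hbond_energy", lambda *a, **k: -1.0)
        ok, reasons = scoring.key_interaction_filter(pocket_bundle, pose, pocket_spec)
        assert not ok
        assert any("aromatic" in r for r in reasons)


class TestTotalScore:
    def _report(self):
        rep = ScoreReport(
            packing={"volume": 100.0, "area": 50.0, "buried_pocket_count": 1.0,
                     "buried_pocket_volume": 30.0, "helix_center_distance": 60.0},
            orientation={"hydrophilic_exposure_major": 5.0, "hydrophilic_exposure_all": 8.0,
                         "tilt_penalty": 2.0, "elevation_penalty": 3.0,
                         "loop_span_penalty": 0.0, "anchor_penalty": 1.0},
            ligand={"serine_hbond": -1.0, "aspartate_elec_hbond": -2.0,
                    "restraints": 0.5, "aromatic_vdw": -0.4},
        )
        return rep

    def test_zero_weights(self):
        w = ScoreWeights()
        for group in (w.packing_terms, w.orientation_terms, w.ligand_terms):
            for k in group:
                group[k] = 0.0
        total, _ = total_score(self._report(), w)
        assert total == 0.0

    def test_unit_weights_plain_sum(self):
        w = ScoreWeights()
        for group in (w.packing_terms, w.orientation_terms, w.ligand_terms):
            for k in group:
                group[k] = 1.0
        rep = self._report()
        total, rep = total_score(rep, w)
        expect = sum(rep.packing.values()) + sum(rep.orientation.values()) + sum(rep.ligand.values())
        assert total == pytest.approx(expect, abs=1e-12)

    def test_arithmetic_oracle_recomputation(self):
        w = ScoreWeights()
        rep = self._report()
        total, rep = total_score(rep, w)
        expect = (
            w.top_level["packing"] * sum(w.packing_terms[k] * v for k, v in rep.packing.items())
            + w.top_level["orientation"]
            * sum(w.orientation_terms[k] * v for k, v in rep.orientation.items())
            + w.top_level["ligand"] * sum(w.ligand_terms[k] * v for k, v in rep.ligand.items())
        )
        assert total == pytest.approx(expect, abs=1e-12)
        assert rep.total_score == pytest.approx(
            rep.packing_score + rep.orientation_score + rep.ligand_score, abs=1e-9
        )

    def test_linear_in_weights(self):
        rep = self._report()
        w = ScoreWeights()
        t1, _ = total_score(rep, w)
        w2 = ScoreWeights()
        w2.top_level = {k: 2.0 * v for k, v in w2.top_level.items()}
        t2, _ = total_score(rep, w2)
        assert t2 == pytest.approx(2.0 * t1, abs=1e-9)


def test_all_penalties_zero_on_ideal_fixture(ideal_bundle):
    rep = score_model(ideal_bundle)
    assert rep.orientation["tilt_penalty"] == 0.0
    assert rep.orientation["elevation_penalty"] == pytest.approx(0.0, abs=1e-9)
    assert rep.orientation["hydrophilic_exposure_major"] == 0.0
    assert rep.packing["buried_pocket_count"] == 0.0
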