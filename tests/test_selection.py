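import numpy as np
import pytest

from tmrepack.fixtures import FixtureSpec, make_ideal_bundle
from tmrepack.geometry import rotation_about_axis
from tmrepack.selection import (
    APF_CHANNELS,
    Compound,
    PoseRecord,
    apf_grid,
    best_accepted_pose,
    binding_site_box_transfer,
    binding_site_residues,
    compute_grid_maps,
    dock_ligand,
    evaluate_pose,
    rank_models,
    superpose_and_rmsd,
    write_dx,
)


@pytest.fixture(scope="module")
def asp_maps(pocket_bundle, pocket_spec):
    st = pocket_bundle.structure
    od = st.coords[
        [st.atom_index(pocket_spec.aspartate_residue, "OD1"),
         st.atom_index(pocket_spec.aspartate_residue, "OD2")]
    ].mean(axis=0)
    return od, compute_grid_maps(st, od, box_size=10.0)


class TestDockLigand:
    def test_cation_docks_adjacent_to_carboxylate(self, asp_maps, toy_cation):
        od, maps = asp_maps
        stack = dock_ligand(maps, toy_cation, seed=2, n_poses=5, n_runs=8, n_steps=150)
        assert stack
        n_pos = stack[0].coords[toy_cation.elements == "N"][0]
        d_best = np.linalg.norm(n_pos - od)
        assert d_best < 5.0
        # exhaustive grid-search oracle over the box: the energy-optimal
        # cation position must itself be adjacent to the carboxylate
        grid = maps.origin + maps.spacing * np.stack(
            np.meshgrid(*[np.arange(s) for s in maps.shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        energies = [maps.ligand_energy(toy_cation, toy_cation.coords - toy_cation.coords[0] + g)
                    for g in grid[:: 7]]  # stride for speed; still exhaustive coverage
        best = grid[::7][int(np.argmin(energies))]
        assert np.linalg.norm(best - od) < 5.0

    def test_same_seed_identical_stack(self, asp_maps, toy_cation):
        _, maps = asp_maps
        a = dock_ligand(maps, toy_cation, seed=4, n_poses=4, n_runs=5, n_steps=80)
        b = dock_ligand(maps, toy_cation, seed=4, n_poses=4, n_runs=5, n_steps=80)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert pa.energy == pb.energy
            assert np.array_equal(pa.coords, pb.coords)

    def test_n_poses_one_returns_single_lowest(self, asp_maps, toy_cation):
        _, maps = asp_maps
        full = dock_ligand(maps, toy_cation, seed=5, n_poses=10, n_runs=6, n_steps=80)
        one = dock_ligand(maps, toy_cation, seed=5, n_poses=1, n_runs=6, n_steps=80)
        assert len(one) == 1
        assert one[0].energy == min(p.energy for p in full)


class TestEvaluatePose:
    def _record(self, coords):
        return PoseRecord(compound_id="x", coords=coords, energy=0.0)

    def test_boundary_values_accepted(self, monkeypatch, pocket_bundle, pocket_spec, dopamine):
        import tmrepack.selection as sel

        pose = self._record(dopamine.coords.copy())
        monkeypatch.setattr(sel, "hbond_energy", lambda *a, **k: -0.2)
        import tmrepack.scoring as scoring

        monkeypatch.setattr(scoring, "serine_hbond_energy", lambda *a, **k: -0.2)
        monkeypatch.setattr(scoring, "aromatic_vdw_energy", lambda *a, **k: -0.3)
        out = evaluate_pose(pose, pocket_bundle, dopamine, pocket_spec)
        assert out.accepted, out.reasons

    def test_weak_aromatic_rejected_with_reason(
        self, monkeypatch, pocket_bundle, pocket_spec, dopamine
    ):
        import tmrepack.scoring as scoring
        import tmrepack.selection as sel

        pose = self._record(dopamine.coords.copy())
        monkeypatch.setattr(sel, "hbond_energy", lambda *a, **k: -0.5)
        monkeypatch.setattr(scoring, "serine_hbond_energy", lambda *a, **k: -0.5)
        monkeypatch.setattr(scoring, "aromatic_vdw_energy", lambda *a, **k: -0.1)
        out = evaluate_pose(pose, pocket_bundle, dopamine, pocket_spec)
        assert not out.accepted
        assert any("aromatic" in r for r in out.reasons)

    def test_ligand_without_aromatics_rejected_explicitly(
        self, pocket_bundle, pocket_spec, toy_cation
    ):
        pose = self._record(toy_cation.coords.copy())
        out = evaluate_pose(pose, pocket_bundle, toy_cation, pocket_spec)
        assert not out.accepted
        assert any("no aromatic atoms" in r for r in out.reasons)

    def test_missing_anchor_residue_errors(self, pocket_bundle, pocket_spec, dopamine):
        import dataclasses

        spec = dataclasses.replace(pocket_spec, aspartate_residue=4242)
        with pytest.raises(KeyError):
            evaluate_pose(self._record(dopamine.coords), pocket_bundle, dopamine, spec)

    def test_monotone_under_stricter_criteria(
        self, pocket_bundle, pocket_spec, dopamine, asp_maps
    ):
        import dataclasses

        od, maps = asp_maps
        stack = dock_ligand(maps, dopamine, seed=6, n_poses=8, n_runs=6, n_steps=100)
        loose = dataclasses.replace(
            pocket_spec,
            acceptance=dataclasses.replace(pocket_spec.acceptance, hbond_asp_max=-0.0001),
        )
        strict = dataclasses.replace(
            pocket_spec,
            acceptance=dataclasses.replace(pocket_spec.acceptance, hbond_asp_max=-1.0),
        )
        acc_loose = {p.pose_index for p in
                     (evaluate_pose(PoseRecord("x", p.coords, p.energy, pose_index=p.pose_index),
                                    pocket_bundle, dopamine, loose) for p in stack) if p.accepted}
        acc_strict = {p.pose_index for p in
                      (evaluate_pose(PoseRecord("x", p.coords, p.energy, pose_index=p.pose_index),
                                     pocket_bundle, dopamine, strict) for p in stack) if p.accepted}
        assert acc_strict <= acc_loose


class TestBestAcceptedPose:
    def _pose(self, i, e, accepted):
        return PoseRecord("c", np.zeros((1, 3)), e, accepted=accepted, pose_index=i)

    def test_all_rejected_none(self):
        assert best_accepted_pose([self._pose(0, -1.0, False)]) is None

    def test_single_accepted(self):
        p = self._pose(1, -2.0, True)
        assert best_accepted_pose([self._pose(0, -5.0, False), p]) is p

    def test_tie_breaks_by_pose_index(self):
        a = self._pose(0, -1.0, True)
        b = self._pose(1, -1.0, True)
        assert best_accepted_pose([b, a]) is a


class TestRankModels:
    def _compounds(self):
        return [
            Compound("ag1", True),
            Compound("ag2_R", True, enantiomer_group="ag2"),
            Compound("ag2_S", True, enantiomer_group="ag2"),
            Compound("ag3", True),
            Compound("inact", False),
        ]

    def test_enumeration_oracle_3x5(self):
        accept = {
            "m1": {"ag1": True, "ag2_R": True, "ag2_S": True, "ag3": False, "inact": True},
            "m2": {"ag1": True, "ag2_R": False, "ag2_S": False, "ag3": True, "inact": False},
            "m3": {"ag1": False, "ag2_R": False, "ag2_S": False, "ag3": False, "inact": True},
        }
        # hand-computed: m1 -> {ag1, ag2} = 2, m2 -> {ag1, ag3} = 2, m3 -> 0
        rows = rank_models(accept, self._compounds(), model_scores={"m1": 5.0, "m2": 1.0})
        assert [r[0] for r in rows] == ["m2", "m1", "m3"]
        assert [r[1] for r in rows] == [2, 2, 0]

    def test_enantiomer_pair_counted_once(self):
        accept = {"m": {"ag2_R": True, "ag2_S": True}}
        rows = rank_models(accept, self._compounds())
        assert rows[0][1] == 1

    def test_zero_acceptance_ranks_last(self):
        accept = {"a": {"ag1": True}, "b": {}}
        rows = rank_models(accept, self._compounds())
        assert rows[-1][0] == "b"

    def test_permutation_invariant(self):
        accept = {"m1": {"ag1": True}, "m2": {"ag1": True, "ag3": True}}
        r1 = rank_models(accept, self._compounds())
        r2 = rank_models(dict(reversed(list(accept.items()))), self._compounds())
        assert r1 == r2


def _quaternion_rmsd_oracle(a, b):
    """Independent superposition RMSD via scipy's quaternion-based
    align_vectors (a different algorithm from the package's SVD Kabsch)."""
    from scipy.spatial.transform import Rotation

    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a0, b0)
    moved = rot.apply(b0)
    return float(np.sqrt(np.mean(np.sum((moved - a0) ** 2, axis=1))))


class TestSuperposeRmsd:
    def test_self_zero(self, ideal_bundle):
        st = ideal_bundle.structure
        assert superpose_and_rmsd(st, st) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotated_copy_zero(self, ideal_bundle):
        st = ideal_bundle.structure
        moved = st.copy()
        r = rotation_about_axis([1.0, 2.0, 0.5], 41.0)
        moved.coords = moved.coords @ r.T + np.array([4.0, 0.0, -2.0])
        assert superpose_and_rmsd(st, moved) == pytest.approx(0.0, abs=1e-9)

    def test_against_quaternion_oracle(self, ideal_bundle, rng):
        st = ideal_bundle.structure
        moved = st.copy()
        moved.coords = moved.coords + rng.normal(0, 0.8, moved.coords.shape)
        got = superpose_and_rmsd(st, moved, fit="heavy")
        hm = st.heavy_mask
        expect = _quaternion_rmsd_oracle(st.coords[hm], moved.coords[hm])
        assert got == pytest.approx(expect, abs=1e-8)

    def test_symmetry(self, ideal_bundle, rng):
        st = ideal_bundle.structure
        moved = st.copy()
        moved.coords = moved.coords + rng.normal(0, 0.5, moved.coords.shape)
        assert superpose_and_rmsd(st, moved) == pytest.approx(
            superpose_and_rmsd(moved, st), abs=1e-9
        )

    def test_fit_and_report_sets_may_differ(self, ideal_bundle, rng):
        st = ideal_bundle.structure
        moved = st.copy()
        moved.coords = moved.coords + rng.normal(0, 0.3, moved.coords.shape)
        r = superpose_and_rmsd(st, moved, fit="ca", report="heavy")
        assert r > 0.0

    def test_unmatched_atoms_error(self, ideal_bundle):
        st = ideal_bundle.structure
        with pytest.raises(ValueError, match="unmatched|common"):
            superpose_and_rmsd(st, st, fit=[(99999, "CA")])


class TestBoxTransfer:
    def test_reference_vs_itself_identical_selection(self, pocket_bundle):
        st = pocket_bundle.structure
        center = pocket_bundle.helix_center(1)
        sel = binding_site_box_transfer(st, center, [st])[0]
        inside = np.all(np.abs(st.coords - center) <= 5.0, axis=1)
        assert len(sel) > 0
        assert np.array_equal(sel, np.flatnonzero(inside))

    def test_displaced_distant_helix_does_not_change_selection(self, pocket_bundle):
        from dataclasses import replace
        from tmrepack.bundle import set_rigid_variables

        st = pocket_bundle.structure
        center = pocket_bundle.helix_center(1)
        # displace helix 4 (far from the box) in a model copy
        v = pocket_bundle.get_rigid_variables(4)
        moved = set_rigid_variables(pocket_bundle, 4, replace(v, radial=v.radial + 6.0))
        core = [int(r) for span in pocket_bundle.spans[:3] for r in range(span[0], span[1] + 1)]
        sel_ref = binding_site_box_transfer(st, center, [st], core_residues=core)[0]
        sel_moved = binding_site_box_transfer(st, center, [moved.structure], core_residues=core)[0]
        assert np.array_equal(sel_ref, sel_moved)

    def test_empty_box_warns(self, pocket_bundle):
        st = pocket_bundle.structure
        with pytest.warns(UserWarning):
            sel = binding_site_box_transfer(st, np.array([500.0, 0, 0]), [st])[0]
        assert len(sel) == 0


def test_binding_site_residues_five_angstrom(pocket_bundle, dopamine):
    pose = dopamine.copy()
    pose.coords = pose.coords - pose.coords[pose.heavy_mask].mean(axis=0)
    res = binding_site_residues(pocket_bundle.structure, pose.coords[pose.heavy_mask], cutoff=5.0)
    st = pocket_bundle.structure
    expected = set()
    lig = pose.coords[pose.heavy_mask]
    for i in range(len(st)):
        if st.elements[i] != "H":
            if np.min(np.linalg.norm(lig - st.coords[i], axis=1)) <= 5.0:
                expected.add(int(st.res_seq[i]))
    assert set(res) == expected


class TestApf:
    def test_single_cation_charge_and_donor_peak(self, toy_cation):
        grid = apf_grid(toy_cation, [toy_cation.coords])
        n_pos = toy_cation.coords[toy_cation.elements == "N"][0]
        # Gasteiger spreads the formal charge onto the hydrogens (~1 A from
        # N), so the smoothed peak sits at the amine group, not the N nucleus
        assert np.linalg.norm(grid.peak_position("charge") - n_pos) < 1.6
        assert np.linalg.norm(grid.peak_position("hb_donor") - n_pos) < 1.6

    def test_catechol_donor_peak_near_hydroxyl_hydrogens(self, dopamine):
        grid = apf_grid(dopamine, [dopamine.coords])
        from rdkit import Chem

        mol = dopamine.mol
        oh_h = []
        for a in mol.GetAtoms():
            if a.GetSymbol() == "O":
                for nb in a.GetNeighbors():
                    if nb.GetSymbol() == "H":
                        oh_h.append(dopamine.coords[nb.GetIdx()])
        # kernel-sum oracle: evaluate the donor field directly at candidate points
        sigma = 1.0 / np.sqrt(2 * np.log(2))
        donors = [dopamine.coords[h] for _, h in dopamine.donor_h]
        def field(x):
            return sum(np.exp(-np.sum((x - d) ** 2) / (2 * sigma**2)) for d in donors)
        peak = grid.peak_position("hb_donor")
        assert field(peak) >= 0.95 * max(field(h) for h in donors)

    def test_empty_ensemble_errors(self, dopamine):
        with pytest.raises(ValueError):
            apf_grid(dopamine, [])

    def test_channels_same_shape_and_linear_scaling(self, toy_cation):
        g1 = apf_grid(toy_cation, [toy_cation.coords])
        g2 = apf_grid(toy_cation, [toy_cation.coords, toy_cation.coords])
        shapes = {g1.channels[c].shape for c in APF_CHANNELS}
        assert len(shapes) == 1
        # averaging over identical poses leaves the field unchanged
        np.testing.assert_allclose(g1.channels["charge"], g2.channels["charge"], atol=1e-12)

    def test_nonnegative_channels_for_nonnegative_properties(self, dopamine):
        grid = apf_grid(dopamine, [dopamine.coords])
        for ch in ("hydrophobicity", "hb_acceptor", "hb_donor", "sp2", "size", "electronegativity"):
            assert grid.channels[ch].min() >= 0.0

    def test_write_dx(self, toy_cation, tmp_path):
        grid = apf_grid(toy_cation, [toy_cation.coords])
        path = tmp_path / "charge.dx"
        write_dx(grid, "charge", path)
        text = path.read_text()
        assert "gridpositions" in text and "data follows" in text
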