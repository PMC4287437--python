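import numpy as np
import pytest

from phscreen.errors import ValidationError
from phscreen.pharmacophore import (
    LigandPose,
    PoseAtom,
    ProbeGrid,
    ProteinAtom,
    compute_simplified_field,
    extract_features,
    match_pose,
    _LJ_PARAMS,
)
from phscreen.synthetic_data import gen_probe_field


def grid_with_wells(wells, shape=(25, 25, 25), spacing=0.5, background=0.0,
                    probe="acceptor_O", seed=0):
    return gen_probe_field(wells, origin=(0.0, 0.0, 0.0), spacing=spacing,
                           shape=shape, seed=seed, probe_kind=probe,
                           background_amplitude=background)


class TestExtractFeatures:
    def test_single_planted_well_detected_at_lattice_point(self):
        grid = grid_with_wells([((6.0, 6.0, 6.0), -8.0, 1.0)])
        feats = extract_features(grid, threshold=-6.0)
        assert len(feats) == 1
        assert feats[0].center == (6.0, 6.0, 6.0)
        assert feats[0].depth == pytest.approx(-8.0, abs=1e-6)
        assert feats[0].kind == "acceptor_favored"

    def test_all_zero_field_yields_nothing(self):
        grid = ProbeGrid("acceptor_O", (0, 0, 0), 0.5, np.zeros((5, 5, 5)))
        assert extract_features(grid, threshold=-6.0) == []

    def test_shallow_well_filtered_by_threshold(self):
        grid = grid_with_wells([((3.0, 3.0, 3.0), -5.0, 0.8),
                                ((9.0, 9.0, 9.0), -7.0, 0.8)])
        feats = extract_features(grid, threshold=-6.0)
        assert len(feats) == 1
        assert feats[0].center == (9.0, 9.0, 9.0)

    def test_nearby_minima_merge_to_deepest(self):
        grid = grid_with_wells([((5.0, 5.0, 5.0), -8.0, 0.4),
                                ((6.0, 5.0, 5.0), -7.0, 0.4)])
        feats = extract_features(grid, threshold=-6.0, merge_radius=2.0)
        assert len(feats) == 1
        assert feats[0].center == (5.0, 5.0, 5.0)

    def test_separated_wells_all_recovered(self):
        wells = [((3.0, 3.0, 3.0), -7.0, 0.7), ((9.0, 9.0, 3.0), -8.0, 0.7),
                 ((6.0, 6.0, 9.0), -9.0, 0.7)]
        grid = grid_with_wells(wells, background=0.05, seed=4)
        feats = extract_features(grid, threshold=-6.0, merge_radius=2.0)
        assert len(feats) == 3
        found = {f.center for f in feats}
        assert found == {w[0] for w in wells}

    def test_translation_equivariance(self):
        grid = grid_with_wells([((6.0, 6.0, 6.0), -8.0, 1.0)])
        shifted = ProbeGrid(grid.probe_kind,
                            tuple(np.asarray(grid.origin) + [1.0, -2.0, 3.0]),
                            grid.spacing, grid.energies)
        f0 = extract_features(grid, threshold=-6.0)[0]
        f1 = extract_features(shifted, threshold=-6.0)[0]
        np.testing.assert_allclose(np.asarray(f1.center) - f0.center, [1.0, -2.0, 3.0])

    def test_error_contracts(self):
        grid = grid_with_wells([((6.0, 6.0, 6.0), -8.0, 1.0)])
        with pytest.raises(ValidationError, match="negative"):
            extract_features(grid, threshold=1.0)
        tiny = ProbeGrid("acceptor_O", (0, 0, 0), 0.5, np.zeros((2, 5, 5)))
        with pytest.raises(ValidationError, match="too small"):
            extract_features(tiny, threshold=-1.0)


def feature(kind, center, tolerance=1.5):
    from phscreen.pharmacophore import PharmacophoreFeature

    return PharmacophoreFeature(kind=kind, center=center, depth=-7.0,
                                tolerance=tolerance)


class TestMatchPose:
    acceptor = feature("acceptor_favored", (0.0, 0.0, 0.0))

    def test_atom_at_center_matches_with_zero_distance(self):
        pose = LigandPose("p1", [PoseAtom("O", (0.0, 0.0, 0.0),
                                          frozenset({"acceptor"}))])
        res = match_pose(pose, [self.acceptor])
        assert res.matched and res.distances[0] == 0.0

    def test_boundary_is_inclusive(self):
        pose = LigandPose("p1", [PoseAtom("O", (1.5, 0.0, 0.0),
                                          frozenset({"acceptor"}))])
        assert match_pose(pose, [self.acceptor]).matched

    def test_partial_match_counts_features(self):
        feats = [feature("acceptor_favored", (0.0, 0.0, 0.0)),
                 feature("donor_favored", (5.0, 0.0, 0.0)),
                 feature("hydrophobic_favored", (0.0, 5.0, 0.0))]
        pose = LigandPose("p1", [
            PoseAtom("O", (0.2, 0.0, 0.0), frozenset({"acceptor"})),
            PoseAtom("C", (0.0, 5.2, 0.0), frozenset({"hydrophobe"})),
        ])
        res = match_pose(pose, feats)
        assert not res.matched
        assert res.matched_feature_count == 2

    def test_required_kinds_subset(self):
        feats = [feature("acceptor_favored", (0.0, 0.0, 0.0)),
                 feature("donor_favored", (5.0, 0.0, 0.0))]
        pose = LigandPose("p1", [PoseAtom("O", (0.0, 0.0, 0.0),
                                          frozenset({"acceptor"}))])
        assert match_pose(pose, feats, required_kinds={"acceptor_favored"}).matched

    def test_role_incompatible_atom_never_matches(self):
        pose = LigandPose("p1", [PoseAtom("C", (0.0, 0.0, 0.0),
                                          frozenset({"hydrophobe"}))])
        res = match_pose(pose, [self.acceptor])
        assert not res.matched and res.distances[0] == np.inf

    def test_unflagged_pose_warns_and_fails(self):
        pose = LigandPose("p1", [PoseAtom("C", (0.0, 0.0, 0.0))])
        with pytest.warns(UserWarning, match="role flags"):
            res = match_pose(pose, [self.acceptor])
        assert not res.matched

    def test_adding_atoms_is_monotone(self):
        feats = [feature("acceptor_favored", (0.0, 0.0, 0.0)),
                 feature("donor_favored", (5.0, 0.0, 0.0))]
        atoms = [PoseAtom("O", (0.0, 0.0, 0.0), frozenset({"acceptor"}))]
        partial = match_pose(LigandPose("p", list(atoms)), feats)
        atoms.append(PoseAtom("N", (5.0, 0.0, 0.0), frozenset({"donor"})))
        full = match_pose(LigandPose("p", atoms), feats)
        assert full.matched_feature_count >= partial.matched_feature_count
        assert full.matched

    def test_empty_feature_list_rejected(self):
        pose = LigandPose("p1", [PoseAtom("O", (0.0, 0.0, 0.0))])
        with pytest.raises(ValidationError):
            match_pose(pose, [])


class TestSimplifiedField:
    def test_single_neutral_atom_minimum_on_lj_shell(self):
        atom = ProteinAtom("C", (5.0, 5.0, 5.0), partial_charge=0.0)
        grid = compute_simplified_field([atom], "hydrophobic_DRY",
                                        spacing=0.25, padding=6.0)
        r0, eps = _LJ_PARAMS["C"]
        idx = np.unravel_index(np.argmin(grid.energies), grid.energies.shape)
        r_min = np.linalg.norm(grid.point(idx) - np.array([5.0, 5.0, 5.0]))
        assert r_min == pytest.approx(r0, abs=0.25)
        assert grid.energies.min() == pytest.approx(-eps, rel=0.05)

    def test_field_is_spherically_symmetric(self):
        atom = ProteinAtom("C", (5.0, 5.0, 5.0), partial_charge=0.0)
        grid = compute_simplified_field([atom], "hydrophobic_DRY",
                                        spacing=0.5, padding=5.0)
        e = grid.energies
        assert np.allclose(e, e[::-1, :, :], atol=1e-9)
        assert np.allclose(e, np.transpose(e, (1, 0, 2)), atol=1e-9)

    def test_translation_equivariance(self):
        shift = np.array([2.0, -1.0, 0.5])
        a = compute_simplified_field([ProteinAtom("C", (5.0, 5.0, 5.0), 0.0)],
                                     "hydrophobic_DRY", spacing=0.5, padding=5.0)
        b = compute_simplified_field(
            [ProteinAtom("C", tuple(np.array([5.0, 5.0, 5.0]) + shift), 0.0)],
            "hydrophobic_DRY", spacing=0.5, padding=5.0)
        ia = np.unravel_index(np.argmin(a.energies), a.energies.shape)
        ib = np.unravel_index(np.argmin(b.energies), b.energies.shape)
        np.testing.assert_allclose(b.point(ib) - a.point(ia), shift, atol=1e-9)

    def test_polar_probe_requires_charges(self):
        atoms = [ProteinAtom("N", (0.0, 0.0, 0.0), partial_charge=None, name="NZ")]
        with pytest.raises(ValidationError, match="NZ"):
            compute_simplified_field(atoms, "donor_N1")

    def test_empty_atom_list_rejected(self):
        with pytest.raises(ValidationError):
            compute_simplified_field([], "hydrophobic_DRY")

    def test_energies_clamped_above(self):
        atom = ProteinAtom("C", (2.0, 2.0, 2.0), partial_charge=0.0)
        grid = compute_simplified_field([atom], "hydrophobic_DRY", spacing=0.5)
        assert grid.energies.max() <= 5.0 + 1e-12


def test_assign_roles_from_mol_phenol():
    from rdkit import Chem

    from phscreen.pharmacophore import assign_roles_from_mol

    mol = Chem.MolFromSmiles("Oc1ccccc1")
    roles = assign_roles_from_mol(mol)
    assert "donor" in roles[0]        # phenolic OH donates
    assert any("hydrophobe" in r for r in roles[1:])  # aromatic ring
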