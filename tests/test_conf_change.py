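import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phscreen.conf_change import (
    Atom,
    DEFAULT_REGION_MAPS,
    RegionMap,
    ReplicateEnsemble,
    ResidueId,
    StructureSnapshot,
    backbone_rmsd_rmsf,
    classify_regions,
    per_residue_rmsd,
    residue_shift_stats,
    significance_tiers,
)
from phscreen.errors import ValidationError
from phscreen.synthetic_data import gen_complex_ensemble, make_reference_structure


def displace(snapshot, rid, atom_name, delta):
    atoms = dict(snapshot.residues[rid])
    old = atoms[atom_name]
    atoms[atom_name] = Atom(old.name, old.element,
                            tuple(np.asarray(old.coords) + delta))
    residues = dict(snapshot.residues)
    residues[rid] = atoms
    return StructureSnapshot(residues=residues)


class TestPerResidueRmsd:
    def test_identical_ensemble_is_zero(self, one_atom_reference):
        ens = ReplicateEnsemble("unbound", [[one_atom_reference] * 3])
        rid = next(iter(one_atom_reference.residues))
        series = per_residue_rmsd(ens, one_atom_reference, rid, align=False)
        assert np.allclose(series[0], 0.0)

    def test_single_atom_displacement_equals_distance(self, one_atom_reference):
        rid = next(iter(one_atom_reference.residues))
        moved = displace(one_atom_reference, rid, "CA", [3.0, 4.0, 0.0])
        ens = ReplicateEnsemble("bound:x", [[moved]])
        series = per_residue_rmsd(ens, one_atom_reference, rid, align=False)
        assert series[0][0] == pytest.approx(5.0)

    def test_gaussian_displacement_mean_square_is_3_sigma_sq(self, one_atom_reference):
        """Isotropic σ per coordinate gives E[RMSD²] = 3σ² for a 1-atom residue."""
        rid = next(iter(one_atom_reference.residues))
        sigma = 0.7
        ens = gen_complex_ensemble(one_atom_reference, {rid: sigma},
                                   n_snapshots=10_000, n_replicates=1, seed=41,
                                   baseline=0.0)
        series = per_residue_rmsd(ens, one_atom_reference, rid, align=False)
        assert np.mean(series[0] ** 2) == pytest.approx(3 * sigma ** 2, rel=0.05)

    def test_rigid_motion_removed_by_alignment(self):
        ref = make_reference_structure(n_residues=8)
        rot = Rotation.from_euler("xyz", [10, -20, 5], degrees=True)
        moved = {}
        for rid, atoms in ref.residues.items():
            moved[rid] = {
                n: Atom(a.name, a.element,
                        tuple(rot.apply(np.asarray(a.coords)) + [5.0, -2.0, 1.0]))
                for n, a in atoms.items()
            }
        snap = StructureSnapshot(residues=moved)
        ens = ReplicateEnsemble("bound:x", [[snap]])
        for rid in list(ref.residues)[:3]:
            series = per_residue_rmsd(ens, ref, rid, align=True)
            assert series[0][0] == pytest.approx(0.0, abs=1e-8)

    def test_atom_set_mismatch_lists_atoms(self, one_atom_reference):
        rid = next(iter(one_atom_reference.residues))
        other = StructureSnapshot(
            residues={rid: {"CB": Atom("CB", "C", (0.0, 0.0, 0.0))}})
        ens = ReplicateEnsemble("bound:x", [[other]])
        with pytest.raises(ValidationError, match="CB"):
            per_residue_rmsd(ens, one_atom_reference, rid, align=False)

    def test_hydrogens_excluded(self):
        rid = ResidueId("A", 1, "GLY")
        ref = StructureSnapshot(residues={rid: {
            "CA": Atom("CA", "C", (0.0, 0.0, 0.0)),
            "HA": Atom("HA", "H", (1.0, 0.0, 0.0)),
        }})
        moved = displace(ref, rid, "HA", [9.0, 9.0, 9.0])
        ens = ReplicateEnsemble("bound:x", [[moved]])
        series = per_residue_rmsd(ens, ref, rid, align=False)
        assert series[0][0] == 0.0


class TestSignificanceTiers:
    def test_identical_distributions_are_none(self):
        p, tier = significance_tiers([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert tier == "none" and p > 0.4

    def test_hand_welch_strong_separation(self):
        """Means 3.0 vs 0.5 with ~0.1 spreads: t ≈ 30, p << 0.01."""
        p, tier = significance_tiers([3.0, 3.1, 2.9], [0.5, 0.6, 0.4])
        assert tier == "**" and p < 1e-3

    def test_one_sided_direction(self):
        p, tier = significance_tiers([0.5, 0.6, 0.4], [3.0, 3.1, 2.9])
        assert tier == "none" and p > 0.5

    def test_single_replicate_warns_and_is_none(self):
        with pytest.warns(UserWarning):
            p, tier = significance_tiers([3.0], [0.5, 0.6])
        assert tier == "none" and np.isnan(p)

    def test_monotone_in_effect_size(self):
        baseline = [0.50, 0.55, 0.45]
        pvals = [significance_tiers([m, m + 0.05, m - 0.05], baseline)[0]
                 for m in (0.6, 1.0, 2.0, 4.0)]
        assert all(b <= a for a, b in zip(pvals, pvals[1:]))


class TestClassifyRegions:
    def _stats_and_map(self):
        ref = make_reference_structure(n_residues=20)
        rids = list(ref.residues)
        planted = [r for r in rids if r.number in (5, 6)]
        control = [r for r in rids if r.number == 15]
        region_map = RegionMap(
            protein="synthetic",
            regions={"II": {r.short for r in planted},
                     "I": {rids[0].short}},
            controls={control[0].short},
        )
        bound = gen_complex_ensemble(ref, {r: 4.0 for r in planted},
                                     n_snapshots=60, n_replicates=3, seed=21)
        unbound = gen_complex_ensemble(ref, {}, n_snapshots=60, n_replicates=3,
                                       seed=22, condition="unbound")
        stats = residue_shift_stats(bound, unbound, ref,
                                    residues=planted + control + [rids[0]])
        return stats, region_map, planted

    def test_planted_region_flagged_controls_clean(self):
        stats, region_map, planted = self._stats_and_map()
        report = classify_regions(stats, region_map)
        flagged = {e["residue"] for e in report["regions"]["II"]}
        assert flagged == {r.short for r in planted}
        assert all(e["tier"] == "**" for e in report["regions"]["II"])
        assert report["regions"]["I"] == []  # baseline residue below threshold
        assert report["warnings"] == []
        assert report["controls"][0]["tier"] == "none"

    def test_violated_control_is_reported(self):
        stats, region_map, _ = self._stats_and_map()
        control_label = next(iter(region_map.controls))
        for s in stats:
            if s.residue.short == control_label:
                s.pooled_mean = 5.0
                s.tier = "**"
        report = classify_regions(stats, region_map)
        assert any("control violated" in w for w in report["warnings"])

    def test_unknown_residue_in_map_rejected(self):
        stats, region_map, _ = self._stats_and_map()
        bad = RegionMap(protein="x", regions={"I": {"Z999"}}, controls=set())
        with pytest.raises(ValidationError, match="Z999"):
            classify_regions(stats, bad)

    def test_region_map_disjointness_enforced(self):
        with pytest.raises(ValidationError):
            RegionMap(protein="x", regions={"I": {"K14"}, "II": {"K14"}})

    def test_default_maps_cover_both_proteins(self):
        assert set(DEFAULT_REGION_MAPS) == {"GAB1", "IRS1"}
        gab1 = DEFAULT_REGION_MAPS["GAB1"]
        assert "K14" in gab1.regions["I"] and "R92" in gab1.regions["II"]
        assert gab1.controls == {"W107"}


class TestBackboneRmsdRmsf:
    def test_static_ensemble_is_zero(self):
        ref = make_reference_structure(n_residues=5)
        ens = ReplicateEnsemble("unbound", [[ref, ref, ref]])
        series, rmsf = backbone_rmsd_rmsf(ens, ref)
        assert np.allclose(series[0], 0.0)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rmsf.values())

    def test_oscillating_atom_rmsf_is_amplitude(self, one_atom_reference):
        rid = next(iter(one_atom_reference.residues))
        up = displace(one_atom_reference, rid, "CA", [0.8, 0.0, 0.0])
        down = displace(one_atom_reference, rid, "CA", [-0.8, 0.0, 0.0])
        ens = ReplicateEnsemble("unbound", [[up, down]])
        _, rmsf = backbone_rmsd_rmsf(ens, one_atom_reference, selection=("CA",),
                                     align=False)
        assert rmsf[rid] == pytest.approx(0.8)

    def test_rigid_translation_invariance_with_alignment(self):
        ref = make_reference_structure(n_residues=5)
        shifted = StructureSnapshot(residues={
            rid: {n: Atom(a.name, a.element,
                          tuple(np.asarray(a.coords) + [3.0, 3.0, 3.0]))
                  for n, a in atoms.items()}
            for rid, atoms in ref.residues.items()})
        ens = ReplicateEnsemble("unbound", [[shifted, shifted]])
        series, rmsf = backbone_rmsd_rmsf(ens, ref)
        assert np.allclose(series[0], 0.0, atol=1e-8)
        assert all(v == pytest.approx(0.0, abs=1e-8) for v in rmsf.values())

    def test_empty_selection_rejected(self):
        ref = make_reference_structure(n_residues=5)
        ens = ReplicateEnsemble("unbound", [[ref]])
        with pytest.raises(ValidationError):
            backbone_rmsd_rmsf(ens, ref, selection=())
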