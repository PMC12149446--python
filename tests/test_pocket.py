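"""Pocket volumetrics: analytic-sphere oracles, sphericity, invariances."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nrgeom.io import AtomRecord, StructureModel
from nrgeom.pocket import (
    PocketNotFoundError,
    define_pocket,
    effective_radius,
    merged_ligand_reference,
    pocket_deviation,
    pocket_normalization,
    pocket_volume_area,
    ses_volume_area,
    sphericity,
)
from nrgeom.synthetic import make_ideal_helix, make_spherical_cavity
from conftest import structure_atoms


def atom(xyz, element="C", name="C"):
    return AtomRecord(name, element, np.asarray(xyz, float))


class TestDefinePocket:
    def _structure(self, protein_coords):
        from nrgeom.io import ChainModel, ResidueRecord

        residues = [
            ResidueRecord(i + 1, "GLY", [atom(c, name="CA")])
            for i, c in enumerate(protein_coords)
        ]
        return StructureModel("t", [ChainModel("A", residues)])

    def test_cutoff_boundary(self):
        st = self._structure([(4.9, 0, 0), (5.1, 0, 0)])
        pocket = define_pocket(st, [atom((0, 0, 0))], cutoff=5.0)
        assert len(pocket.lining_atoms) == 1

    def test_zero_cutoff_errors(self):
        st = self._structure([(3.0, 0, 0)])
        with pytest.raises(ValueError, match="no protein atoms"):
            define_pocket(st, [atom((0, 0, 0))], cutoff=0.0)

    def test_overlapping_shells_union_without_duplicates(self):
        st = self._structure([(2.0, 0, 0), (8.0, 0, 0)])
        pocket = define_pocket(st, [atom((0, 0, 0)), atom((4, 0, 0))], cutoff=5.0)
        assert len(pocket.lining_atoms) == 2

    def test_empty_ligand_errors(self):
        with pytest.raises(ValueError, match="empty ligand"):
            define_pocket(self._structure([(1, 0, 0)]), [])


class TestSesVolumeArea:
    def test_single_atom_matches_vdw_sphere(self):
        # SES of an isolated atom is its own vdW sphere (Se, r = 1.90 Å)
        v, a = ses_volume_area([atom((0, 0, 0), element="SE")], voxel=0.2)
        assert v == pytest.approx(4 / 3 * math.pi * 1.9**3, rel=0.02)
        assert a == pytest.approx(4 * math.pi * 1.9**2, rel=0.03)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ses_volume_area([])

    def test_voxel_larger_than_probe_rejected(self):
        with pytest.raises(ValueError, match="undersampled"):
            ses_volume_area([atom((0, 0, 0))], probe=1.4, voxel=1.5)

    def test_two_touching_atoms_exceed_one(self):
        one, _ = ses_volume_area([atom((0, 0, 0))], voxel=0.3)
        two, _ = ses_volume_area([atom((0, 0, 0)), atom((3.0, 0, 0))], voxel=0.3)
        assert two > 1.5 * one


class TestCavity:
    def test_r5_volume_within_5pct_and_nearly_spherical(self, cavity5):
        prot = structure_atoms(cavity5)
        lig = cavity5.hetero_groups[("A", "LIG", 1)]
        v, a = pocket_volume_area(prot, lig, voxel=0.3)
        assert v == pytest.approx(4 / 3 * math.pi * 125, rel=0.05)
        assert sphericity(v, a) == pytest.approx(1.0, abs=0.03)

    def test_r3_volume(self):
        model = make_spherical_cavity(3.0)
        v, _ = pocket_volume_area(
            structure_atoms(model), model.hetero_groups[("A", "LIG", 1)], voxel=0.2
        )
        assert v == pytest.approx(4 / 3 * math.pi * 27, rel=0.05)

    def test_voxel_halving_convergence(self, cavity5):
        prot = structure_atoms(cavity5)
        lig = cavity5.hetero_groups[("A", "LIG", 1)]
        v_coarse, _ = pocket_volume_area(prot, lig, voxel=0.3)
        v_fine, _ = pocket_volume_area(prot, lig, voxel=0.15)
        assert abs(v_fine - v_coarse) / v_coarse < 0.02

    def test_rigid_transform_invariance(self, cavity5):
        prot = structure_atoms(cavity5)
        lig = cavity5.hetero_groups[("A", "LIG", 1)]
        v0, a0 = pocket_volume_area(prot, lig, voxel=0.3)
        rot = Rotation.random(random_state=3).as_matrix()
        shift = np.array([3.3, -8.1, 12.9])
        prot_t = [AtomRecord(x.name, x.element, rot @ x.coords + shift) for x in prot]
        lig_t = [AtomRecord(x.name, x.element, rot @ x.coords + shift) for x in lig]
        v1, a1 = pocket_volume_area(prot_t, lig_t, voxel=0.3)
        assert v1 == pytest.approx(v0, rel=0.02)
        assert a1 == pytest.approx(a0, rel=0.02)

    def test_occluded_pocket_reported_not_found(self, cavity5):
        # fill the cavity with atoms: no probe-admissible void remains
        prot = structure_atoms(cavity5)
        filler = [
            atom((x, y, z))
            for x in (-2.5, 0, 2.5)
            for y in (-2.5, 0, 2.5)
            for z in (-2.5, 0, 2.5)
        ]
        with pytest.raises(PocketNotFoundError):
            pocket_volume_area(prot + filler, cavity5.hetero_groups[("A", "LIG", 1)], voxel=0.3)

    def test_open_pocket_warns(self):
        # half shell: the probe escapes through the missing hemisphere
        model = make_spherical_cavity(5.0)
        prot = [a for a in structure_atoms(model) if a.coords[2] <= 0.5]
        with pytest.warns(UserWarning, match="open"):
            pocket_volume_area(prot, model.hetero_groups[("A", "LIG", 1)], voxel=0.4)


class TestShapeMetrics:
    def test_sphere_sphericity_and_radius(self):
        r = 2.0
        v, a = 4 / 3 * math.pi * r**3, 4 * math.pi * r**2
        assert sphericity(v, a) == pytest.approx(1.0)
        assert effective_radius(v, a) == pytest.approx(2.0)

    def test_cube_values(self):
        v, a = 8.0, 24.0  # side 2
        assert sphericity(v, a) == pytest.approx((math.pi / 6) ** (1 / 3), abs=1e-9)
        assert effective_radius(v, a) == pytest.approx(1.0)

    def test_isoperimetric_bound_on_computed_pockets(self, cavity5):
        prot = structure_atoms(cavity5)
        lig = cavity5.hetero_groups[("A", "LIG", 1)]
        v, a = pocket_volume_area(prot, lig, voxel=0.3)
        assert sphericity(v, a) <= 1.0 + 0.05

    def test_invalid_inputs(self):
        for fn in (sphericity, effective_radius):
            with pytest.raises(ValueError):
                fn(0.0, 10.0)
            with pytest.raises(ValueError):
                fn(10.0, 0.0)

    def test_normalization_and_deviation(self):
        assert pocket_normalization(100.0, 100.0) == pytest.approx(100.0)
        assert pocket_normalization(163.5, 100.0) == pytest.approx(163.5)
        assert pocket_normalization(50.0, 100.0) == pytest.approx(50.0)
        assert pocket_deviation(1.0, 1.0) == pytest.approx(0.0)
        assert pocket_deviation(0.9, 1.0) == pytest.approx(-10.0)
        assert pocket_deviation(1.2, 1.0) == pytest.approx(20.0)
        with pytest.raises(ValueError):
            pocket_normalization(1.0, 0.0)
        with pytest.raises(ValueError):
            pocket_deviation(1.0, 0.0)


class TestMergedLigand:
    def test_identity_holo_keeps_ligand(self):
        apo = make_ideal_helix(15)
        holo = make_ideal_helix(15)
        lig = [atom((1.0, 2.0, 3.0))]
        from nrgeom.io import DomainSpan

        merged = merged_ligand_reference(apo, [holo], [lig], DomainSpan("LBD", 1, 15))
        assert len(merged) == 1
        np.testing.assert_allclose(merged[0].coords, [1.0, 2.0, 3.0], atol=1e-9)

    def test_transformed_holo_ligand_returned_in_apo_frame(self):
        from nrgeom.io import ChainModel, DomainSpan, ResidueRecord

        apo = make_ideal_helix(15)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        shift = np.array([4.0, -2.0, 9.0])
        holo = ChainModel(
            "A",
            [
                ResidueRecord(
                    r.auth_seq, r.res_name,
                    [AtomRecord(a.name, a.element, rot @ a.coords + shift) for a in r.atoms],
                )
                for r in apo.residues
            ],
        )
        lig_pos = np.array([1.0, 2.0, 3.0])
        lig = [atom(rot @ lig_pos + shift)]
        merged = merged_ligand_reference(apo, [holo], [lig], DomainSpan("LBD", 1, 15))
        np.testing.assert_allclose(merged[0].coords, lig_pos, atol=1e-6)

    def test_duplicate_poses_not_deduplicated(self):
        apo = make_ideal_helix(15)
        holo = make_ideal_helix(15)
        lig = [atom((1.0, 2.0, 3.0))]
        from nrgeom.io import DomainSpan

        merged = merged_ligand_reference(
            apo, [holo, holo], [lig, lig], DomainSpan("LBD", 1, 15)
        )
        assert len(merged) == 2
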