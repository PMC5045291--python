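"""SASA, buried-area, rigid-transform, and superposition tests."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cafarch.structure import (
    RigidTransform,
    StructureModel,
    apply_transform,
    buried_surface_area,
    fibonacci_sphere,
    sasa,
    superpose_rmsd,
)
from cafarch.simulate import gen_ca_structure


def atom_model(coords, element="C"):
    atoms = [("A", i + 1, "ALA", "CA", element, *xyz) for i, xyz in enumerate(coords)]
    return StructureModel.from_atoms(atoms)


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


class TestSasa:
    def test_single_sphere_closed_form(self):
        model = atom_model([(0.0, 0.0, 0.0)])  # C: r = 1.7, probe 1.4
        _, total = sasa(model)
        assert total == pytest.approx(4 * math.pi * 3.1 ** 2, rel=1e-9)
        assert total == pytest.approx(120.76, abs=0.1)

    def test_separated_spheres_additive(self):
        single = sasa(atom_model([(0.0, 0.0, 0.0)]))[1]
        double = sasa(atom_model([(0.0, 0.0, 0.0), (10.0, 0.0, 0.0)]))[1]
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_overlapping_spheres_match_dense_lattice_oracle(self):
        model = atom_model([(0.0, 0.0, 0.0), (2.5, 0.0, 0.0)])
        coarse = sasa(model, n_points=960)[1]
        dense = sasa(model, n_points=10000)[1]
        assert coarse == pytest.approx(dense, rel=0.01)

    def test_overlapping_spheres_match_spherical_cap_formula(self):
        # two equal spheres radius R separated by d: exposed area per sphere
        # is 4 pi R^2 - 2 pi R h with cap height h = R - d/2
        r, d = 1.7 + 1.4, 2.5
        h = r - d / 2
        expected = 2 * (4 * math.pi * r * r - 2 * math.pi * r * h)
        model = atom_model([(0.0, 0.0, 0.0), (d, 0.0, 0.0)])
        assert sasa(model, n_points=10000)[1] == pytest.approx(expected, rel=0.005)

    def test_rigid_motion_invariance(self):
        model = gen_ca_structure(30, seed=5)
        t = RigidTransform(random_rotation(1), np.array([5.0, -3.0, 2.0]))
        moved = apply_transform(model, t)
        # the point lattice is fixed in space, so agreement is limited by the
        # finite sampling density
        assert sasa(moved)[1] == pytest.approx(sasa(model)[1], rel=0.01)

    def test_matches_independent_library_oracle(self):
        """Cross-check against biotite's Shrake-Rupley implementation."""
        import biotite.structure as bst

        model = gen_ca_structure(20, seed=8)
        arr = bst.AtomArray(len(model))
        arr.coord = model.coords.astype(np.float32)
        for i in range(len(model)):
            arr.chain_id[i] = "A"
            arr.res_id[i] = int(model.resnum[i])
            arr.res_name[i] = "ALA"
            arr.atom_name[i] = "CA"
            arr.element[i] = "C"
        ref = float(np.nansum(bst.sasa(arr, probe_radius=1.4, point_number=2000,
                                       vdw_radii=np.full(len(model), 1.7))))
        ours = sasa(model, n_points=2000)[1]
        assert ours == pytest.approx(ref, rel=0.01)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            StructureModel.from_atoms([])


class TestBuriedSurfaceArea:
    def test_separated_bodies_zero(self):
        a = atom_model([(0.0, 0.0, 0.0)])
        b = atom_model([(100.0, 0.0, 0.0)])
        out = buried_surface_area(a, b)
        assert out["delta_total"] == pytest.approx(0.0, abs=1e-9)

    def test_identical_superposed_copies(self):
        a = gen_ca_structure(10, seed=3)
        out = buried_surface_area(a, a)
        # union SASA equals SASA(a), so delta_total ~ SASA(a)
        assert out["delta_total"] == pytest.approx(out["sasa_a"], rel=1e-9)
        assert out["delta_half"] == pytest.approx(out["sasa_a"] / 2, rel=1e-9)

    def test_symmetric_in_arguments(self):
        a = gen_ca_structure(12, seed=1)
        b = apply_transform(gen_ca_structure(12, seed=2),
                            RigidTransform(np.eye(3), np.array([8.0, 0.0, 0.0])))
        ab = buried_surface_area(a, b)["delta_total"]
        ba = buried_surface_area(b, a)["delta_total"]
        assert ab == pytest.approx(ba, rel=1e-9)


class TestRigidTransform:
    def test_identity(self):
        model = gen_ca_structure(10, seed=0)
        out = apply_transform(model, RigidTransform.identity())
        assert np.allclose(out.coords, model.coords)

    def test_translation_preserves_distances(self):
        model = gen_ca_structure(10, seed=0)
        out = apply_transform(model, RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0])))
        d0 = np.linalg.norm(model.coords[0] - model.coords[-1])
        d1 = np.linalg.norm(out.coords[0] - out.coords[-1])
        assert d1 == pytest.approx(d0, rel=1e-12)

    def test_compose_with_inverse_is_identity(self):
        t = RigidTransform(random_rotation(4), np.array([1.0, -2.0, 0.5]))
        model = gen_ca_structure(10, seed=0)
        back = apply_transform(apply_transform(model, t), t.inverse())
        assert np.allclose(back.coords, model.coords, atol=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestSuperposeRmsd:
    def test_identical_models(self):
        a = gen_ca_structure(20, seed=6)
        out = superpose_rmsd(a, a)
        assert out["rmsd"] == pytest.approx(0.0, abs=1e-12)
        assert out["n_atoms"] == 20

    def test_rigidly_transformed_copy(self):
        a = gen_ca_structure(25, seed=7)
        t = RigidTransform(random_rotation(2), np.array([4.0, 5.0, -6.0]))
        out = superpose_rmsd(a, apply_transform(a, t))
        assert out["rmsd"] == pytest.approx(0.0, abs=1e-9)

    def test_swap_invariance(self):
        a = gen_ca_structure(20, seed=1)
        b = gen_ca_structure(20, seed=2)
        assert (superpose_rmsd(a, b)["rmsd"]
                == pytest.approx(superpose_rmsd(b, a)["rmsd"], rel=1e-9))

    def test_matches_scipy_rotation_oracle(self):
        a = gen_ca_structure(30, seed=11)
        b = gen_ca_structure(30, seed=12)
        ours = superpose_rmsd(a, b)["rmsd"]
        pa = a.coords - a.coords.mean(axis=0)
        pb = b.coords - b.coords.mean(axis=0)
        _, rssd = Rotation.align_vectors(pa, pb)
        assert ours == pytest.approx(rssd / math.sqrt(len(pa)), rel=1e-9)

    def test_offset_matching(self):
        a = gen_ca_structure(20, seed=3)
        shifted = StructureModel(a.chain, a.resnum + 100, a.resname, a.atomname,
                                 a.element, a.coords, a.radii)
        out = superpose_rmsd(a, shifted, offset=-100)
        assert out["rmsd"] == pytest.approx(0.0, abs=1e-12)
        assert out["n_atoms"] == 20

    def test_partial_overlap_matches_common_residues_only(self):
        a = gen_ca_structure(20, seed=3)
        b = a.select(a.resnum <= 12)
        assert superpose_rmsd(a, b)["n_atoms"] == 12

    def test_too_few_matches_rejected(self):
        a = gen_ca_structure(5, seed=0)
        b = a.select(a.resnum <= 2)
        with pytest.raises(ValueError, match="3 matched"):
            superpose_rmsd(a, b)

    def test_collinear_set_rejected(self):
        coords = [(float(i), 0.0, 0.0) for i in range(5)]
        a = atom_model(coords)
        with pytest.raises(ValueError, match="collinear"):
            superpose_rmsd(a, a)


def test_fibonacci_sphere_is_unit_and_balanced():
    pts = fibonacci_sphere(1000)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.linalg.norm(pts.mean(axis=0)) < 5e-3
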