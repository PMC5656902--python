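import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cpaselect import (ConeParams, Molecule3D, classify_catalyst,
                       compute_area_theta, scan_rotation_barrier)
from cpaselect.errors import GeometryError
from cpaselect.fixtures import (make_catalyst_3d, make_cone_toy,
                                make_torsion_toy)
from cpaselect.steric_descriptors import compute_profile


class TestAreaTheta:
    def test_single_sphere_matches_tangent_cone(self):
        mol, anchors, analytic = make_cone_toy([((0.0, 3.0, 3.0), "C")])
        params = ConeParams()
        theta = compute_area_theta(mol, anchors, params)
        assert abs(theta - analytic) <= params.angular_resolution

    @pytest.mark.parametrize("resolution", [0.25, 0.5, 1.0])
    def test_random_spheres_within_resolution(self, rng, resolution):
        params = ConeParams(angular_resolution=resolution)
        for _ in range(20):
            d = rng.uniform(4.5, 12.0)
            costh = rng.uniform(-0.3, 0.95)
            phi = rng.uniform(0, 2 * np.pi)
            sinth = np.sqrt(1 - costh**2)
            center = d * np.array([sinth * np.cos(phi), sinth * np.sin(phi), costh])
            element = rng.choice(["H", "C", "O", "Si"])
            mol, anchors, analytic = make_cone_toy([(tuple(center), element)])
            if not 2.0 < analytic < 175.0:
                continue
            theta = compute_area_theta(mol, anchors, params)
            assert abs(theta - analytic) <= resolution

    def test_adding_obstruction_never_widens(self):
        spheres = [((0.0, 3.0, 4.0), "C")]
        mol1, anchors, _ = make_cone_toy(spheres)
        t1 = compute_area_theta(mol1, anchors)
        mol2, _, _ = make_cone_toy(spheres + [((2.0, -2.0, 5.0), "O")])
        t2 = compute_area_theta(mol2, anchors)
        assert t2 <= t1

    def test_inner_sphere_dominates(self):
        # second sphere strictly inside the first sphere's tangent cone
        inner = ((0.0, 2.0, 6.0), "C")
        outer = ((0.0, 6.0, 6.0), "C")
        mol_i, anchors, analytic_i = make_cone_toy([inner])
        mol_b, _, _ = make_cone_toy([inner, outer])
        ti = compute_area_theta(mol_i, anchors)
        tb = compute_area_theta(mol_b, anchors)
        assert tb == ti
        assert abs(tb - analytic_i) <= 0.5

    def test_rigid_motion_invariance(self, phenyl_catalyst, rng):
        mol, anchors = phenyl_catalyst
        t0 = compute_area_theta(mol, anchors)
        R = Rotation.random(random_state=42).as_matrix()
        moved = Molecule3D(list(mol.symbols), mol.coords @ R.T + [3.0, -1.0, 2.0],
                           list(mol.bonds))
        assert compute_area_theta(moved, anchors) == pytest.approx(t0, abs=1e-9)

    def test_resolution_doubling_bounded(self, phenyl_catalyst):
        mol, anchors = phenyl_catalyst
        t1 = compute_area_theta(mol, anchors, ConeParams(angular_resolution=0.5))
        t2 = compute_area_theta(mol, anchors, ConeParams(angular_resolution=1.0))
        assert abs(t1 - t2) <= 1.0

    def test_no_remote_atoms_returns_maximum_with_warning(self):
        mol, anchors, _ = make_cone_toy([((0.0, 3.0, 3.0), "C")])
        wide = ConeParams(remote_cutoff=50.0)
        with pytest.warns(UserWarning, match="no remote atoms"):
            theta = compute_area_theta(mol, anchors, wide)
        assert theta == wide.max_theta


class TestRotationBarrier:
    def test_hydrogen_substituent_is_zero(self, parent_catalyst):
        mol, anchors = parent_catalyst
        scan = scan_rotation_barrier(mol, anchors)
        assert scan.barrier == 0.0

    def test_clash_free_diatomic_is_flat(self):
        mol, anchors = make_torsion_toy()
        scan = scan_rotation_barrier(mol, anchors)
        assert scan.barrier < 0.1

    def test_diatomic_matches_brute_force_of_potential(self):
        # independent route: rotate the rotor by hand and re-evaluate the
        # potential at each grid point
        from cpaselect.steric_descriptors import lj_steric_energy

        mol, anchors = make_torsion_toy()
        scan = scan_rotation_barrier(mol, anchors, step=30.0)
        c3, root = 5, 7
        axis = mol.coords[root] - mol.coords[c3]
        axis = axis / np.linalg.norm(axis)
        energies = []
        for phi in np.arange(0.0, 360.0, 30.0):
            R = Rotation.from_rotvec(np.radians(phi) * axis).as_matrix()
            coords = mol.coords.copy()
            for i in (7, 8):
                coords[i] = (coords[i] - mol.coords[c3]) @ R.T + mol.coords[c3]
            energies.append(lj_steric_energy(mol, coords))
        expected = max(energies) - min(energies)
        assert scan.barrier == pytest.approx(expected, abs=1e-9)

    def test_anthryl_exceeds_phenyl(self, anthryl_catalyst, phenyl_catalyst):
        m_a, a_a = anthryl_catalyst
        m_p, a_p = phenyl_catalyst
        assert scan_rotation_barrier(m_a, a_a).barrier > \
               scan_rotation_barrier(m_p, a_p).barrier

    def test_ortho_beats_peri_beats_para(self):
        """2,6-disubstituted aryl > 1-naphthyl > para-substituted phenyl."""
        barriers = {}
        for name in ["2,4,6-(iPr)3C6H3", "1-naphthyl", "4-PhC6H4"]:
            from cpaselect import find_catalyst_anchors

            mol = make_catalyst_3d(name)
            barriers[name] = scan_rotation_barrier(
                mol, find_catalyst_anchors(mol)).barrier
        assert barriers["2,4,6-(iPr)3C6H3"] > barriers["1-naphthyl"] \
            > barriers["4-PhC6H4"]

    def test_ring_bond_not_rotatable(self):
        mol, anchors = make_torsion_toy()
        bonds = list(mol.bonds) + [(8, 5, 1.0)]  # close rotor into a ring
        ringed = Molecule3D(list(mol.symbols), mol.coords.copy(), bonds)
        with pytest.raises(GeometryError, match="not rotatable"):
            scan_rotation_barrier(ringed, anchors)

    def test_scan_energies_normalised(self, phenyl_catalyst):
        mol, anchors = phenyl_catalyst
        scan = scan_rotation_barrier(mol, anchors)
        energies = [e for _, e in scan.energies]
        assert min(energies) == 0.0
        assert len(energies) == 36


class TestClassification:
    @pytest.mark.parametrize("theta,barrier,expected", [
        (61, 26.53, ("medium", "large")),    # 9-anthryl
        (29, 1.35, ("small", "small")),      # SiPh3 (no override)
        (70, 3.0, ("medium", "medium")),     # strict-inequality boundaries
        (107, 0.0, ("large", "small")),      # parent
        (51, 28.40, ("medium", "large")),    # TRIP
        (35, 2.51, ("small", "small")),      # 3,5-tBu2-4-OMe boundary
    ])
    def test_threshold_binning(self, theta, barrier, expected):
        assert classify_catalyst(theta, barrier) == expected

    def test_override_replaces_proximal(self):
        assert classify_catalyst(29, 1.35, override="large") == ("small", "large")

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_catalyst(float("nan"), 1.0)

    def test_profile_records_params(self, parent_catalyst):
        mol, anchors = parent_catalyst
        profile = compute_profile(mol, anchors)
        assert profile.params_used["cone"]["remote_cutoff"] == 4.0
        assert profile.params_used["acid_form"] == "acid"
        assert 0 < profile.area_theta < 180
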