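"""Superposition, deviation/fluctuation, compactness, and distance statistics.

Independent oracles: the quaternion superposition method (Horn's 4x4
eigenproblem), direct-sum formulas, and all-pairs brute force.
"""

import numpy as np
import pytest

from rnpdyn.geometry import (
    center_of_mass,
    com_angle_series,
    com_distance_series,
    count_clashes,
    kabsch_superpose,
    min_distance_series,
    radius_of_gyration_series,
    rmsd_series,
    rmsf_profile,
)
from rnpdyn.selection import select
from rnpdyn.synthetic import (
    FluctuationSpec,
    GeneratorConfig,
    generate_fluctuating_trajectory,
)
from rnpdyn.topology import AtomRecord, Topology
from rnpdyn.trajectory import Frame, Trajectory


def _point_topology(n, mass=1.0, masses=None):
    masses = masses if masses is not None else [mass] * n
    atoms = [
        AtomRecord(
            serial=i + 1, name="CA", element="C", mass=masses[i],
            residue_name="GLY", residue_index=i + 1, chain_id="A",
            polymer_class="protein",
        )
        for i in range(n)
    ]
    return Topology(atoms=atoms)


def _traj(coords_list, topology):
    return Trajectory(topology, [Frame(np.asarray(c, dtype=float)) for c in coords_list])


def quaternion_superpose_rmsd(mobile, reference):
    """Horn's closed-form quaternion solution for the optimal RMSD (oracle)."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k).max()
    n = mobile.shape[0]
    e0 = (np.sum(x**2) + np.sum(y**2)) - 2.0 * lam
    return np.sqrt(max(e0, 0.0) / n)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestCenterOfMass:
    def test_unit_masses(self):
        top = _point_topology(2)
        traj = _traj([[[0, 0, 0], [2, 0, 0]]], top)
        sel = select(top, "name CA")
        np.testing.assert_allclose(
            center_of_mass(traj.frames[0], sel, top), [1, 0, 0]
        )

    def test_weighted_mean(self):
        top = _point_topology(2, masses=[1.0, 3.0])
        traj = _traj([[[0, 0, 0], [4, 0, 0]]], top)
        sel = select(top, "name CA")
        assert center_of_mass(traj.frames[0], sel, top)[0] == pytest.approx(3.0)

    def test_against_direct_sum(self):
        rng = np.random.default_rng(11)
        masses = rng.uniform(1, 20, 10)
        coords = rng.normal(size=(10, 3))
        top = _point_topology(10, masses=list(masses))
        traj = _traj([coords], top)
        sel = select(top, "name CA")
        expected = sum(m * c for m, c in zip(masses, coords)) / masses.sum()
        np.testing.assert_allclose(
            center_of_mass(traj.frames[0], sel, top), expected, atol=1e-12
        )


class TestKabsch:
    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot = random_rotation(rng)
        res = kabsch_superpose(pts, pts @ rot.T)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.rotation, rot, atol=1e-8)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.normal(size=(2, 5, 3))
            res = kabsch_superpose(a, b)
            np.testing.assert_allclose(
                res.rotation.T @ res.rotation, np.eye(3), atol=1e-10
            )
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_rmsd_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(size=(5, 3))
            b = a + rng.normal(scale=0.3, size=(5, 3))
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_superpose_rmsd(a, b), abs=1e-10
            )

    def test_scipy_cross_check(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        a = rng.normal(size=(7, 3))
        b = a + rng.normal(scale=0.2, size=(7, 3))
        res = kabsch_superpose(a, b)
        rot, rssd = Rotation.align_vectors(
            b - b.mean(axis=0), a - a.mean(axis=0)
        )
        np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-8)
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)


class TestRmsdSeries:
    def test_reference_frame_is_zero(self, small_trajectory, toy_topology):
        sel = select(toy_topology, "name CA")
        res = rmsd_series(small_trajectory, sel, 0, fit=True)
        assert res.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_translation_with_and_without_fit(self):
        top = _point_topology(4)
        base = np.random.default_rng(5).normal(size=(4, 3))
        shifted = base + np.array([0.3, 0.4, 0.0])  # |shift| = 0.5
        traj = _traj([base, shifted], top)
        sel = select(top, "name CA")
        assert rmsd_series(traj, sel, fit=True).values[1] == pytest.approx(0, abs=1e-10)
        assert rmsd_series(traj, sel, fit=False).values[1] == pytest.approx(0.5)

    def test_matches_per_frame_kabsch_oracle(self, small_trajectory, toy_topology):
        sel = select(toy_topology, "protein and heavy")
        res = rmsd_series(small_trajectory, sel, 0, fit=True)
        masses = toy_topology.masses[sel.indices]
        ref = small_trajectory.frames[0].coordinates[sel.indices]
        for t in (3, 17, 29):
            mob = small_trajectory.frames[t].coordinates[sel.indices]
            assert res.values[t] == pytest.approx(
                kabsch_superpose(mob, ref, masses).rmsd, abs=1e-12
            )

    def test_invariant_under_rigid_transform_of_frames(self, toy_topology, toy_reference):
        rng = np.random.default_rng(6)
        spec = FluctuationSpec(sigmas=np.full(toy_topology.n_atoms, 0.03))
        plain = generate_fluctuating_trajectory(
            toy_reference, spec, GeneratorConfig(seed=9, n_frames=10), toy_topology
        )
        moved_frames = []
        for fr in plain.frames:
            rot = random_rotation(rng)
            moved_frames.append(Frame(fr.coordinates @ rot.T + rng.normal(size=3)))
        moved = Trajectory(toy_topology, moved_frames)
        sel = select(toy_topology, "name CA")
        np.testing.assert_allclose(
            rmsd_series(plain, sel, fit=True).values,
            rmsd_series(moved, sel, fit=True).values,
            atol=1e-8,
        )


class TestRmsf:
    def test_static_trajectory_zero(self, toy_topology, toy_reference):
        traj = Trajectory(toy_topology, [Frame(toy_reference.coordinates)] * 3)
        sel = select(toy_topology, "name CA")
        np.testing.assert_allclose(rmsf_profile(traj, sel).values, 0.0, atol=1e-12)

    def test_isotropic_gaussian_closed_form(self, toy_topology, toy_reference):
        """RMSF of sigma-per-coordinate Gaussian noise -> sigma*sqrt(3)."""
        sigma, n = 0.10, 5000
        spec = FluctuationSpec(sigmas=np.full(toy_topology.n_atoms, sigma))
        traj = generate_fluctuating_trajectory(
            toy_reference, spec, GeneratorConfig(seed=21, n_frames=n), toy_topology
        )
        sel = select(toy_topology, "name CA")
        values = rmsf_profile(traj, sel, fit=False).values
        expected = sigma * np.sqrt(3)
        # SE of the RMS of 3n iid normals ~ sigma*sqrt(3)/sqrt(2*3n)
        se = expected / np.sqrt(2 * 3 * n)
        assert np.all(np.abs(values - expected) < 3 * se * np.sqrt(len(values)))

    def test_planted_sigma_ordering_recovered(self, toy_topology, toy_reference):
        rng = np.random.default_rng(13)
        sigmas = np.full(toy_topology.n_atoms, 0.02)
        ca = select(toy_topology, "name CA").indices
        planted = np.linspace(0.02, 0.2, len(ca))
        sigmas[ca] = rng.permutation(planted)
        spec = FluctuationSpec(sigmas=sigmas)
        traj = generate_fluctuating_trajectory(
            toy_reference, spec, GeneratorConfig(seed=22, n_frames=2000), toy_topology
        )
        values = rmsf_profile(traj, select(toy_topology, "name CA"), fit=False).values
        assert np.array_equal(np.argsort(values), np.argsort(sigmas[ca]))

    def test_empty_window_errors(self, small_trajectory, toy_topology):
        sel = select(toy_topology, "name CA")
        with pytest.raises(ValueError):
            rmsf_profile(small_trajectory, sel, discard=small_trajectory.n_frames)


class TestRadiusOfGyration:
    def test_two_point_closed_form(self):
        top = _point_topology(2)
        traj = _traj([[[0, 0, 0], [0.2, 0, 0]]], top)
        sel = select(top, "name CA")
        assert radius_of_gyration_series(traj, sel).values[0] == pytest.approx(0.1)

    def test_square_closed_form(self):
        s = 0.4
        top = _point_topology(4)
        traj = _traj([[[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]]], top)
        sel = select(top, "name CA")
        assert radius_of_gyration_series(traj, sel).values[0] == pytest.approx(
            s / np.sqrt(2), abs=1e-12
        )

    def test_direct_formula_oracle_and_invariances(self):
        rng = np.random.default_rng(14)
        masses = rng.uniform(1, 16, 20)
        coords = rng.normal(size=(20, 3))
        top = _point_topology(20, masses=list(masses))
        sel = select(top, "name CA")
        com = masses @ coords / masses.sum()
        expected = np.sqrt(masses @ np.sum((coords - com) ** 2, axis=1) / masses.sum())
        rot = random_rotation(rng)
        scaled = 2.5 * coords
        traj = _traj([coords, coords @ rot.T + 5.0, scaled], top)
        values = radius_of_gyration_series(traj, sel).values
        assert values[0] == pytest.approx(expected, abs=1e-12)
        assert values[1] == pytest.approx(expected, abs=1e-10)  # rigid invariance
        assert values[2] == pytest.approx(2.5 * expected, abs=1e-10)  # linear scaling


class TestComSeries:
    def test_distance_345(self):
        top = _point_topology(2)
        traj = _traj([[[0, 0, 0], [0, 3, 4]]], top)
        a = select(top, "resid 1")
        b = select(top, "resid 2")
        assert com_distance_series(traj, a, b).values[0] == pytest.approx(5.0)

    def test_identical_selection_zero_distance(self, small_trajectory, toy_topology):
        sel = select(toy_topology, "name CA")
        np.testing.assert_allclose(
            com_distance_series(small_trajectory, sel, sel).values, 0.0, atol=1e-14
        )

    def test_right_angle_and_collinear(self):
        top = _point_topology(3)
        traj = _traj([[[1, 0, 0], [0, 0, 0], [0, 1, 0]],
                      [[1, 0, 0], [0, 0, 0], [-2, 0, 0]]], top)
        a, b, c = (select(top, f"resid {i}") for i in (1, 2, 3))
        values = com_angle_series(traj, a, b, c).values
        assert values[0] == pytest.approx(90.0)
        assert values[1] == pytest.approx(180.0)

    def test_angle_against_arccos_oracle_and_symmetry(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            pts = rng.normal(size=(3, 3))
            top = _point_topology(3)
            traj = _traj([pts], top)
            a, b, c = (select(top, f"resid {i}") for i in (1, 2, 3))
            v1, v2 = pts[0] - pts[1], pts[2] - pts[1]
            expected = np.degrees(
                np.arccos(
                    np.clip(
                        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1
                    )
                )
            )
            got = com_angle_series(traj, a, b, c).values[0]
            swapped = com_angle_series(traj, c, b, a).values[0]
            assert got == pytest.approx(expected, abs=1e-10)
            assert got == pytest.approx(swapped, abs=1e-12)
            assert 0.0 <= got <= 180.0

    def test_coincident_com_errors(self):
        top = _point_topology(3)
        traj = _traj([[[0, 0, 0], [0, 0, 0], [1, 0, 0]]], top)
        a, b, c = (select(top, f"resid {i}") for i in (1, 2, 3))
        with pytest.raises(ValueError, match="undefined"):
            com_angle_series(traj, a, b, c)


class TestMinDistance:
    def test_single_atoms(self):
        top = _point_topology(2)
        traj = _traj([[[0, 0, 0], [0, 0, 2]]], top)
        a, b = select(top, "resid 1"), select(top, "resid 2")
        assert min_distance_series(traj, a, b).values[0] == pytest.approx(2.0)

    def test_self_pair_excluded_on_overlap(self):
        top = _point_topology(2)
        traj = _traj([[[0, 0, 0], [1, 0, 0]]], top)
        both = select(top, "name CA")
        # overlapping selections: minimum over distinct atoms, not 0
        assert min_distance_series(traj, both, both).values[0] == pytest.approx(1.0)

    def test_brute_force_oracle_and_symmetry(self):
        rng = np.random.default_rng(16)
        coords = rng.normal(size=(40, 3))
        top = _point_topology(40)
        traj = _traj([coords], top)
        a = select(top, "resid 1-20")
        b = select(top, "resid 21-40")
        expected = min(
            np.linalg.norm(coords[i] - coords[j])
            for i in range(20)
            for j in range(20, 40)
        )
        ab = min_distance_series(traj, a, b).values[0]
        ba = min_distance_series(traj, b, a).values[0]
        assert ab == pytest.approx(expected, abs=1e-12)
        assert ab == ba


class TestClashes:
    def test_single_cross_pair(self):
        top = _point_topology(2)
        top2 = Topology(atoms=top.atoms)  # residues 1 and 2, no covalent pairs
        traj = _traj([[[0, 0, 0], [0.10, 0, 0]]], top2)
        assert count_clashes(traj.frames[0], top2, 0.22) == 1

    def test_separated_structure_zero(self, toy_reference, toy_topology):
        assert count_clashes(toy_reference, toy_topology, 0.05) == 0

    def test_nonpositive_threshold(self, toy_reference, toy_topology):
        with pytest.raises(ValueError):
            count_clashes(toy_reference, toy_topology, 0.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        n = 30
        coords = rng.uniform(0, 1.0, size=(n, 3))
        atoms = [
            AtomRecord(
                serial=i + 1, name="C", element="C", mass=12.0,
                residue_name="GLY", residue_index=i // 3 + 1, chain_id="A",
                polymer_class="protein",
            )
            for i in range(n)
        ]
        top = Topology(atoms=atoms, covalent_pairs={(0, 3), (6, 9)})
        threshold = 0.35
        expected = 0
        for i in range(n):
            for j in range(i + 1, n):
                if i // 3 == j // 3 or (i, j) in {(0, 3), (6, 9)}:
                    continue
                if np.linalg.norm(coords[i] - coords[j]) < threshold:
                    expected += 1
        assert count_clashes(Frame(coords), top, threshold) == expected
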