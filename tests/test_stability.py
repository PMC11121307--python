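"""Stability battery: superposition, RMSD/RMSF, RG, SASA, H-bonds, table."""

import numpy as np
import pytest

from halfchannel.chain import HBondCriteria
from halfchannel.core import Topology, Trajectory
from halfchannel.errors import (
    DegenerateGeometryError,
    InsufficientFramesError,
    ValidationError,
)
from halfchannel.stability import (
    count_intramolecular_hbonds,
    load_packaged_stability_table,
    radius_of_gyration,
    rmsd_series,
    rmsf_profile,
    round_half_up,
    sasa,
    summarize_stability_table,
    superpose,
)

from conftest import protein_atom


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent minimum-RMSD oracle via the quaternion (Horn) method."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    n = len(m)
    msd = (np.sum(m**2) + np.sum(r**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestSuperpose:
    def test_identical_coordinates_zero_rmsd(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        rot, tr, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-8)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3))
        rot90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        moved = pts @ rot90.T + np.array([3.0, -1.0, 2.0])
        rot, tr, rmsd = superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_always_proper(self):
        # a near-reflection pairing must still return det(+1)
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rot, _, _ = superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_selection_is_degenerate(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=(10, 3)) * 3.0
            b = rng.normal(size=(10, 3)) * 3.0
            _, _, rmsd = superpose(a, b)
            assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, static_trajectory):
        values, mean = rmsd_series(
            static_trajectory, np.arange(static_trajectory.n_atoms)
        )
        np.testing.assert_allclose(values, 0.0, atol=1e-10)
        assert values[0] == 0.0

    def test_jittered_frames_mean_in_band(self):
        from conftest import water_topology

        rng = np.random.default_rng(5)
        top = water_topology(500)
        base = rng.normal(scale=20.0, size=(500, 3))
        coords = base[None] + rng.normal(scale=0.1, size=(20, 500, 3))
        traj = Trajectory(top, coords)
        _, mean = rmsd_series(traj, np.arange(500))
        assert 0.05 < mean < 0.35

    def test_symmetric_radial_expansion_closed_form(self):
        # four atoms on the axes, each pushed outward by d: the optimal
        # rotation is the identity and the RMSD is exactly d.
        a = 3.0
        d = 0.5
        frame0 = np.array(
            [[a, 0, 0], [-a, 0, 0], [0, a, 0], [0, -a, 0]], dtype=float
        )
        frame1 = frame0 * (a + d) / a
        top = __import__("conftest").water_topology(4)
        traj = Trajectory(top, np.stack([frame0, frame1]))
        values, mean = rmsd_series(traj, np.arange(4))
        assert values[1] == pytest.approx(d, abs=1e-10)
        assert mean == pytest.approx(d / 2, abs=1e-10)

    def test_empty_selection_rejected(self, static_trajectory):
        with pytest.raises(ValidationError):
            rmsd_series(static_trajectory, np.array([], dtype=int))


class TestRmsf:
    def test_static_trajectory_all_zero(self, static_trajectory):
        profile = rmsf_profile(
            static_trajectory, static_trajectory.topology.select("backbone")
        )
        np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-10)

    def test_single_frame_insufficient(self, static_trajectory):
        single = Trajectory(
            static_trajectory.topology, static_trajectory.coordinates[:1]
        )
        with pytest.raises(InsufficientFramesError):
            rmsf_profile(single, np.arange(4))

    def test_jittered_residue_matches_gaussian_oracle(self):
        """One residue jittered with sigma: its RMSF -> sigma * sqrt(3)."""
        rng = np.random.default_rng(6)
        atoms = []
        serial = 1
        for res in range(1, 9):
            for name in ("N", "CA", "C", "O"):
                atoms.append(protein_atom(serial, name, "ALA", res))
                serial += 1
        top = Topology(atoms)
        base = rng.normal(scale=6.0, size=(top.n_atoms, 3))
        n_frames, sigma = 10_000, 0.3
        coords = np.repeat(base[None], n_frames, axis=0)
        target = top.select("resid 4")
        coords[:, target, :] += rng.normal(
            scale=sigma, size=(n_frames, len(target), 3)
        )
        traj = Trajectory(top, coords)
        profile = rmsf_profile(traj, np.arange(top.n_atoms))
        jittered = profile.rmsf[3]
        assert jittered == pytest.approx(sigma * np.sqrt(3), rel=0.10)
        assert profile.rmsf[[0, 1, 2, 4, 5, 6, 7]].max() < 0.5 * jittered

    def test_frame_permutation_invariance(self, wt_system):
        traj, _, _ = wt_system
        small = Trajectory(traj.topology, traj.coordinates[:40])
        sel = traj.topology.select("backbone")
        p1 = rmsf_profile(small, sel)
        perm = np.random.default_rng(7).permutation(40)
        shuffled = Trajectory(traj.topology, small.coordinates[perm])
        p2 = rmsf_profile(shuffled, sel)
        np.testing.assert_allclose(p1.rmsf, p2.rmsf, atol=1e-6)


class TestRadiusOfGyration:
    def test_two_unit_masses_two_angstroms_apart(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(frame, [0, 1], [1.0, 1.0]) == pytest.approx(1.0)

    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2, 3]]), [0], [12.0]) == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(100, 3)) * 5
        masses = rng.uniform(1, 16, size=100)
        com = (masses[:, None] * pts).sum(axis=0) / masses.sum()
        expected = np.sqrt(
            (masses * ((pts - com) ** 2).sum(axis=1)).sum() / masses.sum()
        )
        got = radius_of_gyration(pts, np.arange(100), masses)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValidationError):
            radius_of_gyration(np.zeros((2, 3)), [0, 1], [0.0, 0.0])


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        per_atom, total = sasa(np.zeros((1, 3)), np.array([1.5]), 1.4, 960)
        assert total == pytest.approx(4 * np.pi * 2.9**2, rel=1e-12)

    def test_coincident_atoms_one_sphere(self):
        frame = np.zeros((2, 3))
        _, total = sasa(frame, np.array([1.5, 1.5]), 1.4, 960)
        assert total == pytest.approx(4 * np.pi * 2.9**2, rel=0.02)

    def test_monotone_in_separation_and_matches_fine_quadrature(self):
        radii = np.array([1.5, 1.5])
        totals = []
        for sep in (0.5, 1.5, 2.5, 3.5, 4.5, 5.5):
            frame = np.array([[0.0, 0, 0], [sep, 0, 0]])
            _, total = sasa(frame, radii, 1.4, 960)
            _, fine = sasa(frame, radii, 1.4, 100_000)
            assert total == pytest.approx(fine, rel=0.01)
            totals.append(total)
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_point_doubling_converged(self, wt_system):
        traj, _, _ = wt_system
        protein = np.array(
            [i for i, a in enumerate(traj.topology.atoms) if a.chain_id != "W"]
        )
        frame = traj.coordinates[0][protein]
        radii = traj.topology.vdw_radii(protein)
        _, t1 = sasa(frame, radii, 1.4, 960)
        _, t2 = sasa(frame, radii, 1.4, 1920)
        assert abs(t2 - t1) / t2 < 0.005

    def test_matches_mdtraj_cross_check(self):
        """Independent implementation agreement on a toy all-carbon cluster."""
        md = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(9)
        n = 12
        xyz = rng.normal(scale=2.0, size=(n, 3))
        top = md.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(n):
            top.add_atom(f"C{i}", md.element.carbon, res)
        traj = md.Trajectory(xyz[None] / 10.0, top)  # mdtraj is in nm
        ref = md.shrake_rupley(
            traj, probe_radius=0.14, n_sphere_points=960
        ).sum() * 100.0  # nm^2 -> A^2
        radius_c = md.geometry.sasa._ATOMIC_RADII["C"] * 10.0
        _, total = sasa(xyz, np.full(n, radius_c), 1.4, 960)
        assert total == pytest.approx(ref, rel=0.02)

    def test_validation(self):
        with pytest.raises(ValidationError):
            sasa(np.zeros((1, 3)), np.array([1.5]), -1.0, 960)
        with pytest.raises(ValidationError):
            sasa(np.zeros((1, 3)), np.array([1.5]), 1.4, 32)


class TestHbondCount:
    def _two_serines(self, separation):
        atoms = [
            protein_atom(1, "OG", "SER", 10),
            protein_atom(2, "OG", "SER", 20),
        ]
        frame = np.array([[0.0, 0, 0], [separation, 0, 0]])
        return frame, Topology(atoms)

    def test_pair_within_cutoff_counts(self):
        frame, top = self._two_serines(2.8)
        assert count_intramolecular_hbonds(frame, top) == 1

    def test_pair_beyond_cutoff_does_not(self):
        frame, top = self._two_serines(3.4)
        assert count_intramolecular_hbonds(
            frame, top, HBondCriteria(max_heavy_distance=3.0)
        ) == 0

    def test_same_residue_and_water_excluded(self):
        from halfchannel.core import assign_role, AtomRecord

        atoms = [
            protein_atom(1, "OD1", "ASP", 10),
            protein_atom(2, "OD2", "ASP", 10),
            AtomRecord(3, "O", "O", "HOH", 100, "W", assign_role("HOH", "O")),
        ]
        frame = np.array([[0.0, 0, 0], [2.2, 0, 0], [1.0, 1.0, 0]])
        assert count_intramolecular_hbonds(frame, Topology(atoms)) == 0

    def test_matches_brute_force_oracle(self):
        from halfchannel.core import (
            is_acceptor_capable,
            is_donor_capable,
            ROLE_WATER_OXYGEN,
        )

        rng = np.random.default_rng(10)
        names = [("SER", "OG"), ("ASN", "OD1"), ("ASN", "ND2"), ("ARG", "NH1"),
                 ("GLU", "OE1"), ("ALA", "CB")]
        atoms = []
        for i in range(50):
            res_name, name = names[i % len(names)]
            atoms.append(protein_atom(i + 1, name, res_name, i + 1))
        top = Topology(atoms)
        frame = rng.uniform(0, 12, size=(50, 3))
        brute = 0
        for i in range(50):
            for j in range(i + 1, 50):
                a, b = top.atoms[i], top.atoms[j]
                if a.res_seq == b.res_seq:
                    continue
                if a.role in ("none", ROLE_WATER_OXYGEN) or b.role in (
                    "none", ROLE_WATER_OXYGEN
                ):
                    continue
                if np.linalg.norm(frame[i] - frame[j]) > 3.0:
                    continue
                if (is_donor_capable(a.role) and is_acceptor_capable(b.role)) or (
                    is_donor_capable(b.role) and is_acceptor_capable(a.role)
                ):
                    brute += 1
        assert count_intramolecular_hbonds(frame, top) == brute


class TestStabilityTable:
    def test_packaged_table_key_summaries(self):
        rows = load_packaged_stability_table()
        summary = summarize_stability_table(rows, printed_precision=2)
        assert summary["mutants_only"]["rmsd_alphafold_A"]["mean"] == 1.59
        assert summary["overall"]["rmsd_A"]["max"] == 2.94

    def test_single_row_degenerate(self):
        from halfchannel.stability import StabilityRow

        row = StabilityRow("only", 2.0, 22.0, 1.3, 60, 1.5)
        s = summarize_stability_table([row])["overall"]
        assert s["rmsd_A"] == {"mean": 2.0, "min": 2.0, "max": 2.0}

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            summarize_stability_table([])

    def test_half_up_rounding(self):
        assert round_half_up(1.585, 2) == 1.59
        assert round_half_up(59.6, 0) == 60.0
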