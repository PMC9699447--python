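import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hnpmd.forcefield import (
    ChainState,
    ForceField,
    SingularConfigurationError,
    bend_angles,
    bend_energy,
    dihedral_angles,
    energy_breakdown,
    nonbonded_energy,
    nonbonded_pairs,
    pair_potential,
    stretch_energy,
    torsion_energy,
    total_energy_and_forces,
)
from hnpmd.sequence import ResidueClass, Sequence, build_sequence, initial_configuration

from conftest import make_state, zigzag_positions

H, N, P = ResidueClass.H, ResidueClass.N, ResidueClass.P


def brute_force_nonbonded(state, ff):
    """Independent O(N^2) double loop over the shifted pair potential."""
    total = 0.0
    pos = state.positions
    classes = state.sequence.classes
    for i in range(len(pos)):
        for j in range(i + 4, len(pos)):
            r = float(np.linalg.norm(pos[i] - pos[j]))
            if r <= ff.rc:
                total += pair_potential(classes[i], classes[j], r, ff)
    return total


class TestForceFieldDefaults:
    def test_scalar_defaults(self, ff):
        assert ff.l0 == 0.153
        assert ff.kd == 7.0e4
        assert ff.theta0 == 1.231
        assert ff.ktheta == 100.0
        assert ff.kphi == 2.0
        assert ff.sigma == 0.3624
        assert ff.eps_h == 0.1984
        assert ff.rc == 0.95

    def test_epsilon_matrix(self, ff):
        e = ff.eps_h
        expected = {
            (H, H): e, (H, N): 2 * e / 3, (H, P): 7 * e / 12,
            (N, N): e / 3, (N, P): e / 4, (P, P): e / 6,
        }
        for (a, b), val in expected.items():
            assert ff.epsilon(a, b) == pytest.approx(val)
            assert ff.epsilon(b, a) == pytest.approx(val)
            assert val > 0

    def test_lambda_matrix(self, ff):
        assert ff.lam(H, H) == 1.0
        assert ff.lam(P, P) == -1.0
        for a, b in [(H, N), (H, P), (N, N), (N, P)]:
            assert ff.lam(a, b) == 0.0
            assert ff.lam(b, a) == 0.0

    def test_asymmetric_matrix_rejected(self):
        eps = ForceField().epsilon_matrix.copy()
        eps[0, 1] *= 2
        with pytest.raises(ValueError):
            ForceField(epsilon_matrix=eps)

    def test_yaml_roundtrip(self, tmp_path, ff):
        path = tmp_path / "ff.yaml"
        ff.to_yaml(path)
        back = ForceField.from_yaml(path)
        assert back.l0 == ff.l0
        np.testing.assert_allclose(back.epsilon_matrix, ff.epsilon_matrix)
        np.testing.assert_allclose(back.lambda_matrix, ff.lambda_matrix)


class TestStretchEnergy:
    def test_zero_at_equilibrium(self, ff, seq20, zigzag_state20):
        assert stretch_energy(zigzag_state20, ff) == pytest.approx(0.0, abs=1e-18)

    def test_single_displaced_bond(self, ff, seq20):
        # (1/2) * 7e4 * 0.01^2 = 3.5 kcal/mol
        pos = zigzag_positions(20)
        direction = pos[1] - pos[0]
        direction /= np.linalg.norm(direction)
        pos[0] -= 0.01 * direction
        state = make_state(pos, seq20)
        assert stretch_energy(state, ff) == pytest.approx(3.5, rel=1e-10)

    def test_harmonic_scaling(self, ff, seq20):
        pos = zigzag_positions(20)
        rng = np.random.default_rng(0)
        bonds = np.diff(pos, axis=0)
        lengths = np.linalg.norm(bonds, axis=1)
        scale = 1 + 0.01 * rng.random(19)
        pos2 = np.zeros_like(pos)
        pos4 = np.zeros_like(pos)
        for i in range(19):
            u = bonds[i] / lengths[i]
            pos2[i + 1] = pos2[i] + u * ff.l0 * scale[i]
            pos4[i + 1] = pos4[i] + u * ff.l0 * (1 + 2 * (scale[i] - 1))
        e2 = stretch_energy(make_state(pos2, seq20), ff)
        e4 = stretch_energy(make_state(pos4, seq20), ff)
        assert e4 == pytest.approx(4 * e2, rel=1e-9)


class TestBendEnergy:
    def test_zero_at_equilibrium(self, ff, zigzag_state20):
        assert bend_energy(zigzag_state20, ff) == pytest.approx(0.0, abs=1e-18)

    def test_single_angle_displacement(self, ff):
        # one angle at theta0 + 0.1: (1/2) * 100 * 0.1^2 = 0.5 kcal/mol
        seq = build_sequence("H1", 5)
        th = ForceField().theta0 + 0.1
        pos = np.zeros((5, 3))
        pos[1] = [0.153, 0, 0]
        # third bead so the deflection angle at bead 1 is exactly th
        pos[2] = pos[1] + 0.153 * np.array([np.cos(th), np.sin(th), 0])
        # keep remaining angles/dihedrals at equilibrium is unnecessary:
        # place far along to keep all other angles at theta0? Use N=3 chain
        seq3 = Sequence((ResidueClass.H,) * 5)
        state = make_state(pos[:3].tolist() + [
            (pos[2] + [10, 0, 0]).tolist(), (pos[2] + [20, 0, 0]).tolist()], seq3)
        # only the first angle deviates in a controlled way; compute directly
        angles = bend_angles(state.positions)
        assert angles[0] == pytest.approx(th, abs=1e-12)
        e_first = 0.5 * ff.ktheta * (angles - ff.theta0) ** 2
        assert e_first[0] == pytest.approx(0.5, rel=1e-9)

    def test_rotation_invariance(self, ff, random_state20):
        e0 = bend_energy(random_state20, ff)
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        rotated = make_state(random_state20.positions @ rot.T,
                             random_state20.sequence)
        assert bend_energy(rotated, ff) == pytest.approx(e0, rel=1e-12)

    def test_collinear_triplet_safe(self, ff):
        seq = Sequence((H,) * 5)
        pos = np.zeros((5, 3))
        pos[:, 0] = np.arange(5) * 0.153
        state = make_state(pos, seq)
        e = bend_energy(state, ff)  # all angles 0 -> (1/2) k theta0^2 each
        assert e == pytest.approx(3 * 0.5 * ff.ktheta * ff.theta0 ** 2, rel=1e-12)


class TestTorsionEnergy:
    def test_zero_for_all_trans_zigzag(self, ff, zigzag_state20):
        assert torsion_energy(zigzag_state20, ff) == pytest.approx(0.0, abs=1e-12)

    def test_cis_barrier_is_kphi(self, ff):
        # rotate the last bead of a 4-bead quadruplet to phi = pi
        seq = Sequence((H,) * 5)
        pos = zigzag_positions(5)
        phi = dihedral_angles(pos)
        assert np.allclose(phi, 0.0, atol=1e-12)
        # rotate the tail about the bond 1->2 axis by pi: first dihedral
        # moves from trans (0) to the cis barrier (pi), angles unchanged
        pos_cis = pos.copy()
        axis = (pos[2] - pos[1]) / np.linalg.norm(pos[2] - pos[1])
        rot = Rotation.from_rotvec(axis * np.pi).as_matrix()
        pos_cis[3:] = (pos_cis[3:] - pos[2]) @ rot.T + pos[2]
        phi_cis = dihedral_angles(pos_cis)
        assert abs(abs(phi_cis[0]) - np.pi) < 1e-9
        state = make_state(pos_cis, seq)
        # first dihedral at the cis barrier contributes exactly kphi
        e = torsion_energy(state, ff)
        per = 0.5 * ff.kphi * (1 - np.cos(3 * dihedral_angles(pos_cis)))
        assert per[0] == pytest.approx(ff.kphi, rel=1e-9)
        assert e == pytest.approx(per.sum(), rel=1e-12)

    def test_gauche_minima_are_zero(self, ff):
        for phi0 in (2 * np.pi / 3, -2 * np.pi / 3):
            e = 0.5 * ff.kphi * (1 - np.cos(3 * phi0))
            assert e == pytest.approx(0.0, abs=1e-12)

    def test_n5_has_two_dihedral_terms(self, ff):
        pos = zigzag_positions(5)
        assert dihedral_angles(pos).shape == (2,)

    def test_maximum_over_grid_equals_kphi(self, ff):
        phi = np.linspace(-np.pi, np.pi, 100001)
        e = 0.5 * ff.kphi * (1 - np.cos(3 * phi))
        assert e.max() == pytest.approx(ff.kphi, rel=1e-8)


class TestPairPotential:
    def test_hh_minimum_depth(self, ff):
        # numerical minimization oracle over r
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(
            lambda r: pair_potential(H, H, r, ff, shifted=False),
            bounds=(0.2, ff.rc), method="bounded",
            options={"xatol": 1e-12})
        assert res.fun == pytest.approx(-ff.eps_h, rel=1e-8)
        assert res.x == pytest.approx(2 ** (1 / 6) * ff.sigma, rel=1e-6)

    def test_hh_zero_at_sigma(self, ff):
        assert pair_potential(H, H, ff.sigma, ff, shifted=False) == pytest.approx(
            0.0, abs=1e-12)

    def test_pp_positive_and_decreasing(self, ff):
        r = np.linspace(0.25, ff.rc, 2000)
        u = pair_potential(P, P, r, ff, shifted=False)
        assert np.all(u > 0)
        assert np.all(np.diff(u) < 0)

    def test_shifted_vanishes_at_cutoff(self, ff):
        for a, b in itertools.combinations_with_replacement((H, N, P), 2):
            assert pair_potential(a, b, ff.rc, ff) == pytest.approx(0.0, abs=1e-15)
            assert pair_potential(a, b, ff.rc + 0.01, ff) == 0.0

    def test_nonpositive_distance_rejected(self, ff):
        with pytest.raises(ValueError):
            pair_potential(H, H, 0.0, ff)


class TestNonbondedEnergy:
    def test_n5_straight_chain_beyond_cutoff(self, ff):
        seq = Sequence((H,) * 5)
        pos = np.zeros((5, 3))
        pos[:, 0] = np.arange(5) * 0.3
        state = make_state(pos, seq)
        assert nonbonded_energy(state, ff) == 0.0

    def test_n5_single_candidate_pair(self):
        i, j = nonbonded_pairs(5)
        assert len(i) == 1 and (i[0], j[0]) == (0, 4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, ff, seed):
        seq = build_sequence("H4N2P2", 40)
        state = initial_configuration(seq, seed=seed)
        assert nonbonded_energy(state, ff) == pytest.approx(
            brute_force_nonbonded(state, ff), rel=1e-12)

    def test_kernel_matches_brute_force_n60(self, ff):
        seq = build_sequence("H3N1P1", 60)
        state = initial_configuration(seq, seed=9)
        bd, _ = total_energy_and_forces(state, ff)
        assert bd.nonbonded == pytest.approx(brute_force_nonbonded(state, ff),
                                             rel=1e-12)


class TestTotalEnergyAndForces:
    def test_breakdown_consistent_with_terms(self, ff, random_state20):
        bd, _ = total_energy_and_forces(random_state20, ff)
        ref = energy_breakdown(random_state20, ff)
        assert bd.stretch == pytest.approx(ref.stretch, rel=1e-12, abs=1e-12)
        assert bd.bend == pytest.approx(ref.bend, rel=1e-12)
        assert bd.torsion == pytest.approx(ref.torsion, rel=1e-12)
        assert bd.nonbonded == pytest.approx(ref.nonbonded, rel=1e-12)
        assert bd.total == pytest.approx(
            bd.stretch + bd.bend + bd.torsion + bd.nonbonded, rel=1e-10)

    def test_normalizations(self, ff, random_state20):
        bd, _ = total_energy_and_forces(random_state20, ff)
        n = random_state20.n_beads
        assert bd.per_bond_stretch == pytest.approx(bd.stretch / (n - 1))
        assert bd.per_angle == pytest.approx(bd.bend / (n - 2))
        assert bd.per_dihedral == pytest.approx(bd.torsion / (n - 3))

    def test_forces_vanish_at_minimum(self, zigzag_state20):
        # zigzag: bonds l0, angles theta0, dihedrals trans; with rc shortened
        # below the closest |i-j| >= 4 distance every term sits at its minimum
        ff_short = ForceField(rc=0.45)
        _, f = total_energy_and_forces(zigzag_state20, ff_short)
        assert np.abs(f).max() < 1e-8

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_finite_difference_gradient(self, ff, seq20, seed):
        state = initial_configuration(seq20, seed=seed)
        _, f = total_energy_and_forces(state, ff)
        h = 1e-6
        fd = np.zeros_like(f)
        for i in range(state.n_beads):
            for k in range(3):
                for sign, target in ((1, 0), (-1, 1)):
                    pos = state.positions.copy()
                    pos[i, k] += sign * h
                    s = ChainState(pos, state.velocities, state.masses,
                                   state.sequence)
                    if sign == 1:
                        e_plus = energy_breakdown(s, ff).total
                    else:
                        e_minus = energy_breakdown(s, ff).total
                fd[i, k] = -(e_plus - e_minus) / (2 * h)
        scale = max(np.abs(fd).max(), 1.0)
        assert np.abs(f - fd).max() / scale < 1e-4

    def test_newtons_third_law_and_torque(self, ff, random_state20):
        _, f = total_energy_and_forces(random_state20, ff)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-8
        com = random_state20.positions.mean(axis=0)
        torque = np.cross(random_state20.positions - com, f).sum(axis=0)
        assert np.linalg.norm(torque) < 1e-8

    def test_overlap_raises(self, ff):
        seq = Sequence((H,) * 6)
        pos = zigzag_positions(6)
        pos[5] = pos[0] + 1e-6
        state = make_state(pos, seq)
        with pytest.raises(SingularConfigurationError):
            total_energy_and_forces(state, ff)

    def test_energy_invariant_under_rigid_motion(self, ff, random_state20):
        bd0 = energy_breakdown(random_state20, ff)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = make_state(random_state20.positions @ rot.T + np.array([1., -2., 3.]),
                           random_state20.sequence)
        bd1 = energy_breakdown(moved, ff)
        for term in ("stretch", "bend", "torsion", "nonbonded"):
            a, b = getattr(bd0, term), getattr(bd1, term)
            assert b == pytest.approx(a, rel=1e-9, abs=1e-12)


class TestCompositionEnergetics:
    """Only H-H pairs can contribute negative nonbonded energy."""

    @staticmethod
    def _compact_frame(ff):
        # collapse a short chain at low T to get many in-range pairs
        from hnpmd.integrator import RunProtocol, run_quench
        seq = build_sequence("H3N1P1", 12)
        proto = RunProtocol(schedule=((1.5, 5000), (0.4, 30000)), seed=4,
                            snapshot_stride=5000)
        traj = run_quench(seq, ff, proto)
        return traj.positions[-1]

    def test_only_hh_negative(self, ff):
        r = np.linspace(0.3, ff.rc, 500)
        for a, b in itertools.combinations_with_replacement((H, N, P), 2):
            u = pair_potential(a, b, r, ff)
            if (a, b) == (H, H):
                assert u.min() < 0
            else:
                assert np.all(u >= 0)

    def test_all_h_is_exhaustive_minimum_n12(self, ff):
        """Over all 3^12 labelings of one compact frame, the all-H labeling
        minimizes the nonbonded energy, and energy falls with H-H pair count."""
        pos = self._compact_frame(ff)
        i, j = nonbonded_pairs(12)
        d = np.linalg.norm(pos[i] - pos[j], axis=1)
        within = d <= ff.rc
        i, j, d = i[within], j[within], d[within]
        assert len(d) > 5  # frame must actually be compact
        sr6 = (ff.sigma / d) ** 6
        shift = ff.cutoff_shift_matrix()
        labelings = np.array(list(itertools.product(range(3), repeat=12)))
        ai, aj = labelings[:, i], labelings[:, j]
        eps = ff.epsilon_matrix[ai, aj]
        lam = ff.lambda_matrix[ai, aj]
        energies = (4 * eps * (sr6 ** 2 - lam * sr6) - shift[ai, aj]).sum(axis=1)
        all_h = np.flatnonzero((labelings == 0).all(axis=1))[0]
        assert energies.argmin() == all_h
        hh_pairs = ((ai == 0) & (aj == 0)).sum(axis=1)
        # energy falls strongly with the number of attractive H-H pairs
        from scipy import stats
        counts = np.unique(hh_pairs)
        means = np.array([energies[hh_pairs == k].mean() for k in counts])
        assert stats.spearmanr(counts, means).statistic < -0.95
        assert np.corrcoef(hh_pairs, energies)[0, 1] < -0.8
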