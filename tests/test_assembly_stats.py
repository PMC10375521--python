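"""Chain statistics, Flory distribution, angles, S(Q) and gyration radii."""

import numpy as np
import pytest

from g4stack import (CylinderShape, InteractionParams, M_from_energy,
                     chain_length_distribution_theory, chain_statistics,
                     dispersity, adjacent_angles, bond_graph, structure_factor,
                     gyration_radius)
from g4stack.assembly_stats import chain_labels, first_peak, fit_M_from_histogram
from g4stack.simulator import SystemState, Trajectory

from _oracles import cylinder_moments_closed_form

SHAPE = CylinderShape()


class TestFloryDistribution:
    def test_monomer_limit(self):
        assert chain_length_distribution_theory(1, rho=2.0, M=1.0) == 2.0
        assert chain_length_distribution_theory(5, rho=2.0, M=1.0) == 0.0

    @pytest.mark.parametrize("M", [1.0, 1.02, 1.5, 2.0, 3.31])
    def test_first_moment_recovers_density(self, M):
        l = np.arange(1, 5000)
        rho = 3.6e-4
        total = float((l * chain_length_distribution_theory(l, rho, M)).sum())
        assert total == pytest.approx(rho, rel=1e-12)

    def test_explicit_values_at_M2(self):
        # rho=1, M=2: nu(l) = 2^-(l+1) * 1^(l-1)
        assert chain_length_distribution_theory(1, 1.0, 2.0) == pytest.approx(0.25)
        assert chain_length_distribution_theory(2, 1.0, 2.0) == pytest.approx(0.125)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            chain_length_distribution_theory(1, 1.0, 0.9)
        with pytest.raises(ValueError):
            chain_length_distribution_theory(0, 1.0, 1.5)


class TestMeanChainLength:
    def test_no_bonds_is_monomeric(self):
        assert M_from_energy(0.0) == 1.0

    def test_all_dimers(self):
        # N/2 bonds: eps = -1/2 per particle -> M = 2
        assert M_from_energy(-0.5) == pytest.approx(2.0)

    def test_branched_or_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            M_from_energy(-1.0)
        with pytest.raises(ValueError):
            M_from_energy(0.3)

    @pytest.mark.parametrize("M,D", [(1.0, 1.0), (1.66, 1.40), (1.13, 1.12)])
    def test_dispersity_closed_form(self, M, D):
        assert dispersity(M) == pytest.approx(D, abs=5e-3)

    def test_histogram_fit_recovers_exponential_M(self):
        M = 1.8
        l = np.arange(1, 30)
        counts = np.round(1e6 / M ** 2 * ((M - 1) / M) ** (l - 1)).astype(int)
        assert fit_M_from_histogram(counts) == pytest.approx(M, rel=1e-3)


class TestAngles:
    def _two_particle_traj(self, axis2, dz=3.5):
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 2] = dz
        ax = np.zeros((1, 2, 3))
        ax[0, 0] = [0, 0, 1]
        ax[0, 1] = axis2
        fr = np.zeros((1, 2, 3))
        fr[:, :, 0] = 1
        return Trajectory(pos, ax, fr, np.zeros(2), 1, 1, 100.0, SHAPE,
                          InteractionParams.monomer(0.1), "monomer", 0)

    def _trimer_traj_with_axes(self, a2):
        """One trimer, middle axis z, third axis ``a2``."""
        pos = np.zeros((1, 3, 3))
        pos[0, :, 2] = [0.0, 3.5, 7.0]
        pos += 30.0
        ax = np.zeros((1, 3, 3))
        ax[0, 0] = ax[0, 1] = [0, 0, 1]
        ax[0, 2] = a2
        fr = np.zeros((1, 3, 3))
        fr[..., 0] = 1
        sh = CylinderShape(K=1.4)
        return Trajectory(pos, ax, fr, np.zeros(2), 1, 1, 100.0, sh,
                          InteractionParams.trimer(0.2, sh.D0), "trimer", 0)

    def test_parallel_axes_give_zero(self):
        th = adjacent_angles(self._trimer_traj_with_axes([0, 0, 1]))
        np.testing.assert_allclose(th, 0.0, atol=1e-7)

    def test_perpendicular_axes_give_ninety(self):
        th = adjacent_angles(self._trimer_traj_with_axes([1, 0, 0]))
        assert th[0, 0] == pytest.approx(0.0, abs=1e-7)
        assert th[0, 1] == pytest.approx(90.0, abs=1e-7)

    def test_nematic_convention_for_bonded_pairs(self):
        # a bonded coaxial pair with flipped axis still reads as 0 degrees
        t = self._two_particle_traj([0, 0, -1], dz=2 * SHAPE.site_offset + 0.3)
        ang = adjacent_angles(t)
        assert len(ang) == 1 and ang[0] == pytest.approx(0.0)

    def test_bonded_multimer_mean_angle_near_twenty_degrees(self, multimeric_traj):
        ang = adjacent_angles(multimeric_traj)
        assert len(ang) > 1000
        assert 12.0 < ang.mean() < 28.0


class TestChainStatistics:
    def test_monomer_conservation_every_snapshot(self, multimeric_traj):
        sp, sm = multimeric_traj.snapshot_state(0).site_masks()
        for k in range(0, multimeric_traj.n_snapshots, 10):
            st = multimeric_traj.snapshot_state(k)
            edges = bond_graph(st)
            labels, ncomp = chain_labels(st.n, edges)
            sizes = np.bincount(labels)
            assert sizes.sum() == st.n
        cs = chain_statistics(multimeric_traj)
        l = np.arange(1, len(cs.length_histogram) + 1)
        assert (l * cs.length_histogram).sum() == (
            multimeric_traj.n * cs.n_snapshots)

    def test_estimators_agree_at_equilibrium(self, multimeric_traj):
        cs = chain_statistics(multimeric_traj)
        assert cs.M_energy == pytest.approx(cs.M_cluster, rel=0.10)
        assert cs.M_energy == pytest.approx(cs.M_fit, rel=0.10)
        assert 1.0 <= cs.dispersity < 2.0

    def test_histogram_consistent_with_flory_law(self, multimeric_traj):
        """The pooled sampled histogram must follow nu(l) with its own M:
        compare observed chain counts to the Flory prediction chi-square."""
        cs = chain_statistics(multimeric_traj)
        M = cs.M_cluster
        h = cs.length_histogram.astype(float)
        n_chains = h.sum()
        l = np.arange(1, len(h) + 1)
        p = (1.0 / M) * ((M - 1) / M) ** (l - 1)  # chain-number fractions
        p /= p.sum()
        expected = n_chains * p
        sel = expected > 10
        chi2 = float(((h[sel] - expected[sel]) ** 2 / expected[sel]).sum())
        # snapshots are correlated, so allow a generous chi2 per bin
        assert chi2 / sel.sum() < 30.0


class TestStructureFactor:
    def _traj_from_positions(self, pos, box):
        s = pos.shape
        ax = np.zeros(s)
        ax[..., 2] = 1
        fr = np.zeros(s)
        fr[..., 0] = 1
        return Trajectory(pos, ax, fr, np.zeros(2), 1, 1, box, SHAPE,
                          InteractionParams.monomer(0.1), "monomer", 0)

    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 60.0, size=(30, 200, 3))
        q = np.linspace(0.5, 5.0, 40)
        s = structure_factor(self._traj_from_positions(pos, 60.0), q)
        assert np.abs(s - 1.0).max() < 0.12
        assert abs(s.mean() - 1.0) < 0.02

    def test_two_particles_closed_form(self):
        # Q well above 2 pi / box, where the finite-box background
        # subtraction is negligible and S = 1 + sinc(Qd) holds
        d = 3.1
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 2] = d
        pos += 20.0
        q = np.linspace(0.6, 4.0, 60)
        s = structure_factor(self._traj_from_positions(pos, 100.0), q)
        expected = 1.0 + np.sin(q * d) / (q * d)
        np.testing.assert_allclose(s, expected, atol=6e-3)

    def test_multimeric_state_first_peak_near_stacking_distance(self, crowded_traj):
        q = np.arange(0.3, 5.0, 0.05)
        s = structure_factor(crowded_traj, q)
        peak = first_peak(q, s, qmin=1.0)
        assert peak == pytest.approx(2.0, abs=0.2)
        # large-Q limit decorrelates to unity
        assert abs(s[q > 4.0].mean() - 1.0) < 0.05


class TestGyrationRadius:
    def test_single_cylinder_closed_form(self):
        rg2, _ = cylinder_moments_closed_form(SHAPE.D, SHAPE.L)
        assert SHAPE.gyration_radius == pytest.approx(np.sqrt(rg2))
        assert SHAPE.gyration_radius == pytest.approx(1.168, abs=2e-3)

    def test_coaxial_dimer_parallel_axis_theorem(self):
        # two cylinders at contact along z: Rg^2 = rg_unit^2 + (d/2)^2
        d = SHAPE.L + 0.1
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 2] = d
        pos += 30.0
        ax = np.zeros((1, 2, 3))
        ax[..., 2] = 1
        fr = np.zeros((1, 2, 3))
        fr[..., 0] = 1
        traj = Trajectory(pos, ax, fr, np.zeros(2), 1, 1, 100.0, SHAPE,
                          InteractionParams.monomer(0.1), "monomer", 0)
        edges = np.array([[0, 1]])
        rg = gyration_radius(traj, 0, edges=edges,
                             labels=(np.zeros(2, dtype=int), 1))
        expected = np.sqrt(SHAPE.gyration_radius ** 2 + (d / 2) ** 2)
        assert rg[0] == pytest.approx(expected, rel=1e-12)

    def test_point_sampled_oracle_for_dimer(self):
        """Monte Carlo estimate of the composite-body Rg from uniform volume
        samples agrees with the closed-form composition."""
        rng = np.random.default_rng(9)
        d = SHAPE.L + 0.1
        n = 200_000
        pts = []
        for zc in (0.0, d):
            while True:
                xy = rng.uniform(-SHAPE.radius, SHAPE.radius, (3 * n // 2, 2))
                xy = xy[np.linalg.norm(xy, axis=1) <= SHAPE.radius][:n]
                if len(xy) == n:
                    break
            z = rng.uniform(-SHAPE.half_length, SHAPE.half_length, n) + zc
            pts.append(np.column_stack([xy, z]))
        pts = np.concatenate(pts)
        com = pts.mean(axis=0)
        rg_mc = np.sqrt(((pts - com) ** 2).sum(axis=1).mean())
        expected = np.sqrt(SHAPE.gyration_radius ** 2 + (d / 2) ** 2)
        assert rg_mc == pytest.approx(expected, rel=5e-3)

    def test_monomeric_ensemble_matches_single_cylinder(self, monomeric_traj):
        cs = chain_statistics(monomeric_traj)
        assert cs.Rg_mean == pytest.approx(SHAPE.gyration_radius, rel=0.05)
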