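"""Monte Carlo engine: initialization, detailed balance, invariants."""

import numpy as np
import pytest

from g4stack import (CylinderShape, InteractionParams, MCSchedule, SystemState,
                     init_lattice, attempt_move, run,
                     box_edge_from_concentration, energy_is_stationary,
                     molar_from_mass_concentration)
from g4stack.geometry import cylinders_overlap
from g4stack import _kernels


class TestInitialization:
    def test_box_edge_from_density_arithmetic(self):
        # N_av * 0.6 mM = 3.613e-4 nm^-3; (6292 / rho)^(1/3)
        rho = 6.02214076e23 * 0.6e-3 * 1e-24
        expected = (6292 / rho) ** (1 / 3)
        assert box_edge_from_concentration(6292, 0.6e-3) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(259.2, abs=0.1)

    def test_dilute_lattice_has_zero_energy_and_spread_particles(self):
        conc = 8 / (6.02214076e23 * 1e-24 * 100.0 ** 3)  # box = 100 nm
        st = init_lattice(8, CylinderShape(), conc, seed=0)
        assert st.box == pytest.approx(100.0)
        assert st.energy == 0.0
        d = st.pos[None, :, :] - st.pos[:, None, :]
        d -= st.box * np.round(d / st.box)
        dist = np.linalg.norm(d, axis=-1)
        assert dist[~np.eye(8, dtype=bool)].min() >= 50.0 - 1e-9

    def test_trimer_lattice_satisfies_covalent_constraints(self):
        shape = CylinderShape(K=1.4)
        st = init_lattice(6, shape, 1e-5, mode="trimer", seed=0,
                          params=InteractionParams.trimer(0.2, shape.D0))
        assert st.n == 6
        assert st.tethers_ok()
        assert not st.has_overlap()
        # two separate molecules: no tether between index 2 and 3
        nxt, prv = st.covalent_partners()
        assert nxt.tolist() == [1, 2, -1, 4, 5, -1]

    def test_overcrowded_lattice_rejected(self):
        with pytest.raises(ValueError, match="density too high"):
            init_lattice(64, CylinderShape(), 0.5)  # 0.5 M is far too dense

    def test_deterministic_given_seed(self):
        st1 = init_lattice(27, CylinderShape(), 1e-4, seed=3)
        st2 = init_lattice(27, CylinderShape(), 1e-4, seed=3)
        np.testing.assert_array_equal(st1.pos, st2.pos)


class TestMoves:
    def _dilute_state(self, n=8, seed=0):
        conc = n / (6.02214076e23 * 1e-24 * 60.0 ** 3)
        return init_lattice(n, CylinderShape(), conc, seed=seed,
                            params=InteractionParams.monomer(0.1))

    def test_isolated_particle_moves_always_accepted(self):
        st = self._dilute_state()
        rng = np.random.default_rng(0)
        accepted = sum(attempt_move(st, 0, rng, max_translation=1.0)
                       for _ in range(200))
        assert accepted == 200

    def test_accepted_moves_keep_energy_bookkeeping_exact(self):
        st = init_lattice(64, CylinderShape(), 2e-3, seed=5,
                          params=InteractionParams.monomer(0.09))
        rng = np.random.default_rng(1)
        for k in range(2000):
            attempt_move(st, int(rng.integers(st.n)), rng)
        assert st.energy == pytest.approx(st.total_energy(), abs=1e-9)

    def test_run_reproducible_and_consistent_with_full_recompute(self):
        st1 = init_lattice(64, CylinderShape(), 2e-3, seed=7,
                           params=InteractionParams.monomer(0.09))
        st2 = st1.copy()
        sch = MCSchedule(n_equil=500, n_prod=1_500, sample_every=100)
        t1 = run(st1, sch)
        t2 = run(st2, sch)
        np.testing.assert_array_equal(t1.pos, t2.pos)
        np.testing.assert_array_equal(t1.energy_trace, t2.energy_trace)
        assert st1.energy == pytest.approx(st1.total_energy(), abs=1e-9)

    def test_no_snapshot_contains_overlaps(self):
        st = init_lattice(64, CylinderShape(), 2e-3, seed=11,
                          params=InteractionParams.monomer(0.09))
        traj = run(st, MCSchedule(n_equil=1_000, n_prod=2_000, sample_every=200))
        for k in range(traj.n_snapshots):
            s = traj.snapshot_state(k)
            assert not s.has_overlap()

    def test_trimer_tethers_never_exceed_cutoff(self, trimer_traj):
        for k in range(0, trimer_traj.n_snapshots, 25):
            s = trimer_traj.snapshot_state(k)
            assert s.tethers_ok()

    def test_high_temperature_limit_is_athermal(self):
        st = init_lattice(64, CylinderShape(), 2e-3, seed=13,
                          params=InteractionParams.monomer(10.0))
        traj = run(st, MCSchedule(n_equil=2_000, n_prod=4_000, sample_every=200))
        # T* = 10: bonds barely bias sampling; mean energy per particle ~ 0
        assert abs(traj.mean_energy_per_particle()) < 0.02


class TestTrajectoryIO:
    def test_hdf5_round_trip(self, tmp_path):
        from g4stack import Trajectory

        st = init_lattice(27, CylinderShape(K=1.1), 1e-4, seed=19,
                          params=InteractionParams.monomer(0.12))
        traj = run(st, MCSchedule(n_equil=200, n_prod=600, sample_every=200))
        p = tmp_path / "t.h5"
        traj.save(str(p))
        back = Trajectory.load(str(p))
        np.testing.assert_array_equal(back.pos, traj.pos)
        np.testing.assert_array_equal(back.energy_trace, traj.energy_trace)
        assert back.shape.K == traj.shape.K
        assert back.params.Tstar == traj.params.Tstar
        assert back.mode == "monomer" and back.params.delta_cov is None


class TestDetailedBalance:
    def test_two_particle_bonded_fraction_matches_configurational_integral(self):
        """The Metropolis chain must reproduce the two-state Boltzmann ratio
        p_bond = Z_b e^(1/T*) / (Z_free + Z_b e^(1/T*)) with Z_b and the
        excluded volume measured by direct Monte Carlo integration of the
        two-particle configuration space."""
        tstar = 0.15
        # box/2 must exceed the full interaction reach (2*site_offset + delta
        # = 3.92 nm) so that simulation and oracle see the same unique image
        box = 8.0
        shape = CylinderShape()
        params = InteractionParams.monomer(tstar)
        hL, R, soff, delta = (shape.half_length, shape.radius,
                              shape.site_offset, params.delta)

        # --- brute-force configurational integral (importance sampling) ---
        rng = np.random.default_rng(2024)
        ns = 40_000
        axes = rng.standard_normal((ns, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        z1 = np.array([0.0, 0.0, 1.0])
        sites1 = np.array([soff * z1, -soff * z1])
        v_ball = 4.0 / 3.0 * np.pi * delta ** 3
        acc = 0.0
        for k in range(ns):
            a2 = axes[k]
            sites2_off = np.array([soff * a2, -soff * a2])
            combo = rng.integers(0, 4)
            i, j = divmod(combo, 2)
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            r = sites1[i] - sites2_off[j] + u * delta * rng.random() ** (1 / 3)
            # multiplicity: how many of the 4 site pairs are inside the well
            d = np.linalg.norm(sites1[None, :, :] -
                               (r[None, None, :] + sites2_off[:, None, :]),
                               axis=-1)
            m = np.count_nonzero(d.T < delta)
            if m == 0:
                continue
            if _kernels.gjk_cylinders_overlap(np.zeros(3), z1, hL, R, r, a2,
                                              hL, R):
                continue
            acc += 1.0 / m
        Z_b = 4.0 * v_ball * acc / ns
        # excluded volume for the free-state normalization
        reach = 2.0 * shape.circumscribed_radius
        nov = 0
        for k in range(ns):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            r = u * reach * rng.random() ** (1 / 3)
            if _kernels.gjk_cylinders_overlap(np.zeros(3), z1, hL, R, r,
                                              axes[ns - 1 - k], hL, R):
                nov += 1
        V_excl = 4.0 / 3.0 * np.pi * reach ** 3 * nov / ns
        V = box ** 3
        boltz = Z_b * np.exp(1.0 / tstar)
        p_theory = boltz / (V - V_excl - Z_b + boltz)

        # --- Metropolis sampling of the same two-particle system ---
        pos = np.array([[2.0, 2.0, 2.0], [6.0, 6.0, 6.0]])
        axis = np.tile(z1, (2, 1))
        frame = np.tile(np.array([1.0, 0.0, 0.0]), (2, 1))
        st = SystemState(pos, axis, frame, box, shape, params, "monomer", 31)
        traj = run(st, MCSchedule(n_equil=100_000, n_prod=1_200_000,
                                  sample_every=600_000, max_rotation=np.pi))
        e = traj.production_energy()
        p_sim = float(np.mean(-e))
        blocks = np.array_split(e, 20)
        bm = np.array([-b.mean() for b in blocks])
        se_sim = bm.std(ddof=1) / np.sqrt(len(bm))
        se_oracle = p_theory / np.sqrt(max(acc, 1.0))
        tol = 3.0 * np.hypot(se_sim, se_oracle)
        assert p_sim == pytest.approx(p_theory, abs=max(tol, 0.008)), (
            p_sim, p_theory, se_sim, se_oracle)


class TestIntensivity:
    def test_mean_chain_length_independent_of_system_size(self):
        """M at fixed (C, K, T*) is an intensive quantity: small and large
        boxes agree within the sampling scatter (about +-0.03 per run at this
        state point)."""
        ms = {}
        for n in (128, 512):
            st = init_lattice(n, CylinderShape(K=1.0), 0.6e-3, seed=61,
                              params=InteractionParams.monomer(0.10))
            traj = run(st, MCSchedule(n_equil=120_000, n_prod=80_000,
                                      sample_every=2_000))
            from g4stack import M_from_energy
            ms[n] = M_from_energy(min(traj.mean_energy_per_particle(), 0.0))
        assert ms[128] == pytest.approx(ms[512], abs=0.10)


class TestStationarity:
    def test_flat_noise_is_stationary(self):
        rng = np.random.default_rng(0)
        assert energy_is_stationary(-50 + rng.standard_normal(10_000))

    def test_strong_monotone_drift_is_not_stationary(self):
        x = np.linspace(0, 1, 10_000)
        assert not energy_is_stationary(-100 * x)
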