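"""Shared fixtures: the expensive equilibrium simulations are run once per
session and reused by unit, property and acceptance tests."""

import numpy as np
import pytest

from g4stack import (CylinderShape, InteractionParams, MCSchedule,
                     init_lattice, run, molar_from_mass_concentration)


def _monomer_traj(K, Tstar, conc_molar, n, n_equil, n_prod, sample_every, seed):
    st = init_lattice(n, CylinderShape(K=K), conc_molar, seed=seed,
                      params=InteractionParams.monomer(Tstar))
    return run(st, MCSchedule(n_equil=n_equil, n_prod=n_prod,
                              sample_every=sample_every))


@pytest.fixture(scope="session")
def monomeric_traj():
    """Dilute potassium-buffer state point: K=1, T*=0.14, C=0.5 mM."""
    return _monomer_traj(1.0, 0.14, 0.5e-3, 256, 20_000, 25_000, 500, 101)


@pytest.fixture(scope="session")
def sodium_traj():
    """Sodium-buffer monomer state point: K=0.95, T*=0.12, C=0.5 mM."""
    return _monomer_traj(0.95, 0.12, 0.5e-3, 256, 30_000, 30_000, 500, 103)


@pytest.fixture(scope="session")
def multimeric_traj():
    """Self-assembled multimer state point: K=1, T*=0.085, C=0.6 mM.

    N=500 with a long equilibration: the bond count is slow at this dilution
    and the mean chain length carries a visible finite-size bias below a few
    hundred particles.
    """
    return _monomer_traj(1.0, 0.085, 0.6e-3, 500, 200_000, 120_000, 2_000, 107)


@pytest.fixture(scope="session")
def crowded_traj():
    """Concentrated multimeric state point (C=4.5 mM) for S(Q)."""
    return _monomer_traj(1.0, 0.085, 4.5e-3, 512, 40_000, 40_000, 1_000, 109)


@pytest.fixture(scope="session")
def trimer_traj():
    """200 covalently linked trimers at the Tel72 best-fit point
    (K=1.4, T*=0.195, 10 mg/mL at 22600 g/mol)."""
    conc = molar_from_mass_concentration(10.0, 22_600.0)
    shape = CylinderShape(K=1.4)
    st = init_lattice(600, shape, conc, mode="trimer", seed=113,
                      params=InteractionParams.trimer(0.195, shape.D0))
    return run(st, MCSchedule(n_equil=25_000, n_prod=45_000, sample_every=150))
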