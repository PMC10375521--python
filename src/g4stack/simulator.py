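"""Canonical (NVT*) Metropolis Monte Carlo of hard cylinders with square-well
stacking sites, under cubic periodic boundary conditions.

Two topologies are supported:

* ``monomer`` -- N independent cylinders, each with both stacking sites; this is
  the self-assembly (equilibrium polymerization) setting.
* ``trimer`` -- particles grouped in consecutive covalently tethered triplets
  (a model of a three-G4 single strand).  Covalent rim sites of adjacent
  cylinders must stay within ``delta_cov`` (hard tether, no restoring force)
  and the terminal cylinders carry no stacking site on their outward bases, so
  distinct trimers do not stack.

Energy bookkeeping is in units of the well depth u0 (a bond contributes -1);
temperature enters only through the reduced T* = k_B T / u0.  One "sweep" is N
attempted single-particle moves, half translations and half rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants, stats

from . import _kernels
from .geometry import CylinderShape, CylinderParticle, InteractionParams

__all__ = [
    "SystemState",
    "MCSchedule",
    "Trajectory",
    "init_lattice",
    "attempt_move",
    "run",
    "box_edge_from_concentration",
    "molar_from_mass_concentration",
    "energy_is_stationary",
]

#: Avogadro constant in 1/mol
N_AV = constants.Avogadro

#: conversion: 1 mol/L = 1e-24 * N_av particles per nm^3
_MOLAR_TO_PER_NM3 = N_AV * 1e-24


def molar_from_mass_concentration(mg_per_mL: float, molar_mass: float) -> float:
    """Molar concentration (mol/L) from a mass concentration.

    ``molar_mass`` is in g/mol; 10 mg/mL of a 22600 g/mol strand is 0.4425 mM.
    """
    return mg_per_mL / molar_mass


def box_edge_from_concentration(n_molecules: int, conc_molar: float) -> float:
    """Cubic box edge (nm) holding ``n_molecules`` at molar concentration."""
    rho = conc_molar * _MOLAR_TO_PER_NM3  # molecules per nm^3
    return float((n_molecules / rho) ** (1.0 / 3.0))


@dataclass
class MCSchedule:
    """Move counts and amplitudes for one run.

    ``n_equil``/``n_prod`` are sweeps (one sweep = N attempted moves);
    snapshots are taken every ``sample_every`` production sweeps.  Translation
    amplitude defaults to a quarter box -- at the dilute conditions of interest
    large jumps dominate the association kinetics.  If ``tune`` is set, the
    amplitudes are adjusted in short bursts during equilibration only (clamped
    to [1e-3 nm, box/2] and [1e-3, pi]) toward an acceptance of 0.2-0.6, then
    frozen for production so detailed balance is preserved.
    """

    n_equil: int = 20_000
    n_prod: int = 20_000
    sample_every: int = 200
    max_translation: float | None = None
    max_rotation: float = np.pi / 2.0
    tune: bool = False

    def __post_init__(self):
        if self.n_equil < 0 or self.n_prod <= 0 or self.sample_every <= 0:
            raise ValueError("schedule counts must be positive")


@dataclass
class SystemState:
    """Full configuration of the cylinder system (array-of-structs layout).

    ``pos``/``axis``/``frame`` are (N, 3) float arrays; ``frame`` fixes the rim
    azimuth and is only physically meaningful in trimer mode.  ``energy`` is
    the cached total SW energy in units of u0 and is kept in sync by accepted
    moves.
    """

    pos: np.ndarray
    axis: np.ndarray
    frame: np.ndarray
    box: float
    shape: CylinderShape
    params: InteractionParams
    mode: str = "monomer"
    rng_seed: int = 0
    energy: float = 0.0
    concentration_molar: float | None = None

    def __post_init__(self):
        if self.mode not in ("monomer", "trimer"):
            raise ValueError("mode must be 'monomer' or 'trimer'")
        if self.mode == "trimer":
            if self.n % 3:
                raise ValueError("trimer mode needs a particle count divisible by 3")
            if self.params.delta_cov is None:
                raise ValueError("trimer mode needs params.delta_cov")

    # -- derived topology -------------------------------------------------
    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def site_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(has_plus_site, has_minus_site) boolean arrays.

        In trimer mode the outward base of each terminal cylinder carries no
        stacking site: cylinder 3k lacks its minus site, 3k+2 its plus site.
        """
        sp = np.ones(self.n, dtype=np.bool_)
        sm = np.ones(self.n, dtype=np.bool_)
        if self.mode == "trimer":
            idx = np.arange(self.n)
            sm[idx % 3 == 0] = False
            sp[idx % 3 == 2] = False
        return sp, sm

    def covalent_partners(self) -> tuple[np.ndarray, np.ndarray]:
        """(cov_next, cov_prev): tether partner indices, -1 where absent.

        Cylinder i's plus-end rim site is tethered to cov_next[i]'s minus-end
        rim site.
        """
        nxt = np.full(self.n, -1, dtype=np.int64)
        prv = np.full(self.n, -1, dtype=np.int64)
        if self.mode == "trimer":
            idx = np.arange(self.n)
            inner = idx[idx % 3 != 2]
            nxt[inner] = inner + 1
            prv[inner + 1] = inner
        return nxt, prv

    def __getitem__(self, i: int) -> CylinderParticle:
        return CylinderParticle(self.pos[i].copy(), self.axis[i].copy(),
                                self.shape, self.frame[i].copy())

    # -- invariant checks -------------------------------------------------
    def total_energy(self) -> float:
        """Recomputed (all pairs) SW energy in u0 units."""
        sp, sm = self.site_masks()
        return float(_kernels.total_energy(
            self.pos, self.axis, sp, sm, self.shape.site_offset,
            self.params.delta, self.box))

    def has_overlap(self) -> bool:
        return bool(_kernels.any_overlap(self.pos, self.axis,
                                         self.shape.half_length,
                                         self.shape.radius, self.box))

    def tethers_ok(self) -> bool:
        if self.mode != "trimer":
            return True
        return bool(np.all(self.tether_distances() <= self.params.delta_cov))

    def tether_distances(self) -> np.ndarray:
        """Distances of all covalent rim-site pairs (trimer mode)."""
        nxt, _ = self.covalent_partners()
        ii = np.nonzero(nxt >= 0)[0]
        jj = nxt[ii]
        hL, R = self.shape.half_length, self.shape.radius
        si = self.pos[ii] + hL * self.axis[ii] + R * self.frame[ii]
        sj = self.pos[jj] - hL * self.axis[jj] + R * self.frame[jj]
        d = sj - si
        d -= self.box * np.round(d / self.box)
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "SystemState":
        return replace(self, pos=self.pos.copy(), axis=self.axis.copy(),
                       frame=self.frame.copy())


@dataclass
class Trajectory:
    """Sampled production snapshots plus the per-sweep energy trace."""

    pos: np.ndarray        # (S, N, 3)
    axis: np.ndarray       # (S, N, 3)
    frame: np.ndarray      # (S, N, 3)
    energy_trace: np.ndarray  # (n_equil + n_prod,) energy per sweep, u0 units
    n_equil: int
    sample_every: int
    box: float
    shape: CylinderShape
    params: InteractionParams
    mode: str
    rng_seed: int
    acceptance: dict = field(default_factory=dict)

    @property
    def n_snapshots(self) -> int:
        return self.pos.shape[0]

    @property
    def n(self) -> int:
        return self.pos.shape[1]

    def snapshot_state(self, k: int) -> SystemState:
        st = SystemState(self.pos[k].copy(), self.axis[k].copy(),
                         self.frame[k].copy(), self.box, self.shape,
                         self.params, self.mode, self.rng_seed)
        st.energy = st.total_energy()
        return st

    def production_energy(self) -> np.ndarray:
        return self.energy_trace[self.n_equil:]

    def mean_energy_per_particle(self) -> float:
        """<E>/N over production, in u0 units (negative when bonded)."""
        return float(self.production_energy().mean() / self.n)

    # -- simple HDF5 container (one record per snapshot) ------------------
    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("pos", data=self.pos)
            f.create_dataset("axis", data=self.axis)
            f.create_dataset("frame", data=self.frame)
            f.create_dataset("energy_trace", data=self.energy_trace)
            f.attrs.update({
                "n_equil": self.n_equil, "sample_every": self.sample_every,
                "box": self.box, "mode": self.mode, "rng_seed": self.rng_seed,
                "D0": self.shape.D0, "L0": self.shape.L0, "K": self.shape.K,
                "delta": self.params.delta, "Tstar": self.params.Tstar,
                "delta_cov": self.params.delta_cov or 0.0,
            })

    @classmethod
    def load(cls, path: str) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            a = dict(f.attrs)
            shape = CylinderShape(float(a["D0"]), float(a["L0"]), float(a["K"]))
            dcov = float(a["delta_cov"]) or None
            params = InteractionParams(delta=float(a["delta"]),
                                       Tstar=float(a["Tstar"]), delta_cov=dcov)
            return cls(f["pos"][...], f["axis"][...], f["frame"][...],
                       f["energy_trace"][...], int(a["n_equil"]),
                       int(a["sample_every"]), float(a["box"]), shape, params,
                       str(a["mode"]), int(a["rng_seed"]))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def init_lattice(n: int, shape: CylinderShape, concentration_molar: float,
                 mode: str = "monomer", seed: int = 0,
                 params: InteractionParams | None = None) -> SystemState:
    """Non-overlapping starting configuration on an orthorhombic lattice.

    ``concentration_molar`` is the molar concentration of *molecules*
    (individual cylinders in monomer mode, triplets in trimer mode); the box
    satisfies rho = n_molecules / V = N_av * C.  In trimer mode ``n`` counts
    cylinders and must be divisible by 3; each lattice node holds one coaxial
    triplet with its tethers satisfied.  Raises if the lattice spacing cannot
    accommodate the particles without overlap.
    """
    if params is None:
        params = (InteractionParams.trimer(0.1, shape.D0) if mode == "trimer"
                  else InteractionParams.monomer(0.1))
    if mode == "trimer" and n % 3:
        raise ValueError("trimer mode needs n divisible by 3")
    n_mol = n // 3 if mode == "trimer" else n
    box = box_edge_from_concentration(n_mol, concentration_molar)

    m = int(np.ceil(n_mol ** (1.0 / 3.0)))
    spacing = box / m
    # stacked-trimer extent along z vs lateral cylinder extent
    if mode == "trimer":
        dz_intra = shape.L + 0.25 * (params.delta_cov or 0.5 * shape.D0)
        z_extent = 2.0 * dz_intra + shape.L
    else:
        z_extent = shape.L
    if spacing <= max(shape.D, z_extent) + 1e-9:
        raise ValueError(
            f"density too high for lattice placement: spacing {spacing:.3f} nm "
            f"vs particle extent {max(shape.D, z_extent):.3f} nm")

    nodes = []
    for ix in range(m):
        for iy in range(m):
            for iz in range(m):
                nodes.append(((ix + 0.5) * spacing, (iy + 0.5) * spacing,
                              (iz + 0.5) * spacing))
                if len(nodes) == n_mol:
                    break
            if len(nodes) == n_mol:
                break
        if len(nodes) == n_mol:
            break
    nodes = np.asarray(nodes)

    if mode == "trimer":
        pos = np.repeat(nodes, 3, axis=0)
        pos[0::3, 2] -= dz_intra
        pos[2::3, 2] += dz_intra
    else:
        pos = nodes
    axis = np.zeros((n, 3))
    axis[:, 2] = 1.0
    frame = np.zeros((n, 3))
    frame[:, 0] = 1.0

    st = SystemState(pos, axis, frame, box, shape, params, mode, seed,
                     concentration_molar=concentration_molar)
    if st.has_overlap():
        raise ValueError("lattice initialization produced overlapping particles")
    if not st.tethers_ok():
        raise ValueError("lattice initialization violates covalent tethers")
    st.energy = st.total_energy()
    return st


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------


def _kernel_args(state: SystemState):
    sp, sm = state.site_masks()
    nxt, prv = state.covalent_partners()
    sh = state.shape
    dcov = state.params.delta_cov if state.mode == "trimer" else -1.0
    return sp, sm, nxt, prv, sh.half_length, sh.radius, sh.site_offset, sh.radius, dcov


def attempt_move(state: SystemState, particle_index: int,
                 rng: np.random.Generator,
                 max_translation: float | None = None,
                 max_rotation: float = np.pi / 2.0) -> bool:
    """One Metropolis single-particle move (reference implementation).

    Proposes a translation (uniform in a cube of side 2*max_translation) or a
    rotation (uniform angle in +-max_rotation about a random axis) with equal
    probability; rejects on hard-core overlap or broken covalent tether,
    otherwise accepts with probability min(1, exp(-dE / T*)).  Mutates
    ``state`` (positions and cached energy) on acceptance.

    This pure-Python path mirrors the jitted sweep kernel and is intended for
    small systems and tests; ``run`` is the fast path.
    """
    i = particle_index
    sh, pr = state.shape, state.params
    if max_translation is None:
        max_translation = state.box / 4.0
    if rng.random() < 0.5:
        new_pos = state.pos[i] + rng.uniform(-max_translation, max_translation, 3)
        new_pos %= state.box
        new_axis = state.axis[i].copy()
        new_frame = state.frame[i].copy()
    else:
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        ang = rng.uniform(-max_rotation, max_rotation)
        c, s = np.cos(ang), np.sin(ang)

        def rot(v):
            return v * c + np.cross(u, v) * s + u * (u @ v) * (1 - c)

        new_pos = state.pos[i].copy()
        new_axis = rot(state.axis[i])
        new_axis /= np.linalg.norm(new_axis)
        new_frame = rot(state.frame[i])
        new_frame /= np.linalg.norm(new_frame)

    sp, sm, nxt, prv, hL, R, soff, rimR, dcov = _kernel_args(state)
    if state.mode == "trimer":
        ok = _kernels._tether_ok(
            i, new_pos[0], new_pos[1], new_pos[2],
            new_axis[0], new_axis[1], new_axis[2],
            new_frame[0], new_frame[1], new_frame[2],
            state.pos, state.axis, state.frame, nxt, prv,
            hL, rimR, dcov * dcov, state.box)
        if not ok:
            return False

    def local_energy(p, a):
        e = 0.0
        d2 = pr.delta * pr.delta
        for j in range(state.n):
            if j == i:
                continue
            e -= _kernels._pair_bonds(
                p[0], p[1], p[2], a[0], a[1], a[2], sp[i], sm[i],
                state.pos[j, 0], state.pos[j, 1], state.pos[j, 2],
                state.axis[j, 0], state.axis[j, 1], state.axis[j, 2],
                sp[j], sm[j], soff, d2, state.box)
        return e

    # overlap check of the candidate against all others (min image)
    trial_pos = state.pos.copy()
    trial_axis = state.axis.copy()
    trial_pos[i] = new_pos
    trial_axis[i] = new_axis
    for j in range(state.n):
        if j != i and _kernels.overlap_mi(trial_pos, trial_axis, i, j, hL, R,
                                          state.box):
            return False

    de = local_energy(new_pos, new_axis) - local_energy(state.pos[i], state.axis[i])
    if de > 0 and rng.random() >= np.exp(-de / pr.Tstar):
        return False
    state.pos[i] = new_pos
    state.axis[i] = new_axis
    state.frame[i] = new_frame
    state.energy += de
    return True


def _mc_chunk(state: SystemState, n_equil: int, n_prod: int, sample_every: int,
              max_tr: float, max_rot: float, seed: int):
    sp, sm, nxt, prv, hL, R, soff, rimR, dcov = _kernel_args(state)
    nsnap = max(1, (n_prod + sample_every - 1) // sample_every) if n_prod else 0
    pos_out = np.empty((nsnap, state.n, 3))
    ax_out = np.empty_like(pos_out)
    up_out = np.empty_like(pos_out)
    e_trace = np.empty(n_equil + n_prod)
    out = _kernels.mc_run(
        state.pos, state.axis, state.frame, sp, sm, nxt, prv,
        hL, R, soff, rimR, state.params.delta, dcov, state.params.Tstar,
        state.box, max_tr, max_rot, n_equil, n_prod, sample_every,
        seed, state.energy, pos_out, ax_out, up_out, e_trace)
    state.energy = out[0]
    acc = {"translation": (out[1], out[2]), "rotation": (out[3], out[4])}
    return pos_out, ax_out, up_out, e_trace, acc


def run(state: SystemState, schedule: MCSchedule) -> Trajectory:
    """Equilibrate then sample; returns the production trajectory.

    Deterministic given ``state.rng_seed`` (single RNG stream, single thread).
    The state is advanced in place to the final configuration.  The energy
    trace covers every sweep (equilibration + production) so stationarity can
    be assessed afterwards with :func:`energy_is_stationary`.
    """
    max_tr = schedule.max_translation
    if max_tr is None:
        # dilute self-assembly benefits from box-scale jumps; tethered trimers
        # need local moves that keep the covalent constraints satisfiable
        max_tr = 0.4 if state.mode == "trimer" else state.box / 4.0
    max_rot = schedule.max_rotation
    if state.mode == "trimer" and schedule.max_rotation == MCSchedule.max_rotation:
        max_rot = 0.6
    seed = int(state.rng_seed) & 0x7FFFFFFF

    traces = []
    n_equil = schedule.n_equil
    if schedule.tune and n_equil > 0:
        # short tuning bursts on the first half of equilibration
        n_burst = max(200, n_equil // 10)
        used = 0
        k = 0
        while used + n_burst <= n_equil // 2:
            _, _, _, tr, acc = _mc_chunk(state, n_burst, 0, schedule.sample_every,
                                         max_tr, max_rot, seed + 7919 * (k + 1))
            traces.append(tr)
            used += n_burst
            k += 1
            for kind, (na, natt) in acc.items():
                frac = na / max(natt, 1)
                fac = 1.25 if frac > 0.6 else (0.8 if frac < 0.2 else 1.0)
                if kind == "translation":
                    max_tr = float(np.clip(max_tr * fac, 1e-3, state.box / 2.0))
                else:
                    max_rot = float(np.clip(max_rot * fac, 1e-3, np.pi))
        n_equil -= used

    pos_out, ax_out, up_out, e_trace, acc = _mc_chunk(
        state, n_equil, schedule.n_prod, schedule.sample_every,
        max_tr, max_rot, seed)
    traces.append(e_trace)
    full_trace = np.concatenate(traces)
    return Trajectory(pos_out, ax_out, up_out, full_trace,
                      full_trace.size - schedule.n_prod,
                      schedule.sample_every, state.box, state.shape,
                      state.params, state.mode, state.rng_seed,
                      acceptance=acc)


def energy_is_stationary(trace: np.ndarray, rel_tol: float = 0.05,
                         abs_tol: float = 1.0, n_blocks: int = 20) -> bool:
    """Drift test on the last half of an energy trace.

    A linear trend is fitted to block means of the last half; the trace counts
    as stationary when the predicted drift across that window is small against
    the mean level: |drift| <= rel_tol * |mean| + abs_tol (abs_tol in u0
    units, i.e. one bond by default).  A magnitude criterion is used rather
    than a significance test because the bond count is strongly
    autocorrelated, which makes trend tests reject stationary traces.
    """
    tail = np.asarray(trace, dtype=float)[len(trace) // 2:]
    if tail.size < 4:
        return True
    if tail.size < n_blocks:
        n_blocks = max(2, tail.size // 2)
    blocks = np.array_split(tail, n_blocks)
    means = np.array([b.mean() for b in blocks])
    if np.allclose(means, means[0]):
        return True
    x = np.arange(n_blocks)
    slope, intercept = np.polyfit(x, means, 1)
    drift = abs(slope) * n_blocks
    if drift <= rel_tol * abs(means.mean()) + abs_tol:
        return True
    # a large apparent drift must also stand out of the block-to-block noise,
    # otherwise it is an equilibrium fluctuation of the (slow) bond count
    resid = means - (slope * x + intercept)
    se = np.sqrt((resid ** 2).sum() / max(n_blocks - 2, 1) /
                 ((x - x.mean()) ** 2).sum())
    return bool(abs(slope) <= 3.0 * se)
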