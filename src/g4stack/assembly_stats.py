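"""Multimer observables: bond graph, chain statistics, angles, gyration radii,
and the center-of-mass structure factor.

The self-assembly of two-site square-well cylinders is an equilibrium
step-growth polymerization: at equilibrium the number density of chains of
length l follows the exponential (Flory) law

    nu(l) = rho * M**-(l+1) * (M-1)**(l-1),

where rho = N/V and M is the mean chain length.  M is measured here by three
independent routes -- from the mean potential energy per particle (bonds per
particle b gives M = 1/(1-b)), from the number of bond-graph connected
components (M = N / n_chains), and from the slope of the log length histogram
-- which must agree at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .simulator import SystemState, Trajectory

__all__ = [
    "chain_length_distribution_theory",
    "M_from_energy",
    "dispersity",
    "bond_graph",
    "chain_labels",
    "ChainStatistics",
    "chain_statistics",
    "adjacent_angles",
    "TrimerBondStats",
    "trimer_bond_classification",
    "structure_factor",
    "gyration_radius",
]


# ---------------------------------------------------------------------------
# step-growth (Flory) statistics
# ---------------------------------------------------------------------------


def chain_length_distribution_theory(l, rho: float, M: float):
    """Flory chain-length density nu(l) = rho M^-(l+1) (M-1)^(l-1).

    ``l`` may be scalar or array (l >= 1).  At M = 1 the convention 0**0 = 1
    gives the monodisperse monomer limit nu(1) = rho, nu(l>1) = 0.  The first
    moment satisfies sum_l l*nu(l) = rho.
    """
    if M < 1:
        raise ValueError("mean chain length M must be >= 1")
    if rho <= 0:
        raise ValueError("number density rho must be positive")
    l = np.asarray(l)
    if np.any(l < 1):
        raise ValueError("chain length l must be >= 1")
    if M == 1.0:
        out = np.where(l == 1, rho, 0.0)
        return out if out.ndim else float(out)
    # evaluate in log space: the direct product overflows for long chains
    lognu = np.log(rho) - (l + 1.0) * np.log(M) + (l - 1.0) * np.log(M - 1.0)
    out = np.exp(lognu)
    return out if out.ndim else float(out)


def M_from_energy(mean_energy_per_particle: float, u0: float = 1.0) -> float:
    """Mean chain length from the mean SW energy per particle.

    With b = |eps|/u0 bonds per particle (eps is the negative mean square-well
    energy per particle), chains give n_chains = N - N_bonds and hence
    M = 1/(1 - b).  Inputs implying M < 1 (positive energy) or M = inf
    (b >= 1, ring/branch dominated) are rejected.
    """
    b = abs(mean_energy_per_particle) / u0
    if mean_energy_per_particle > 1e-12:
        raise ValueError("mean SW energy per particle must be <= 0")
    if b >= 1.0:
        raise ValueError(
            f"bonds per particle {b:.4f} >= 1 implies infinite/branched chains")
    return 1.0 / (1.0 - b)


def dispersity(M: float) -> float:
    """Step-growth dispersity (mass- over number-average): D = 2 - 1/M."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return 2.0 - 1.0 / M


# ---------------------------------------------------------------------------
# bond graph and chains
# ---------------------------------------------------------------------------


def bond_graph(state: SystemState) -> np.ndarray:
    """(m, 2) array of bonded particle index pairs (stacking sites within
    delta, strict)."""
    sp, sm = state.site_masks()
    return _kernels.bond_edges(state.pos, state.axis, sp, sm,
                               state.shape.site_offset, state.params.delta,
                               state.box)


def _edges_for_snapshot(traj: Trajectory, k: int, sp, sm) -> np.ndarray:
    return _kernels.bond_edges(traj.pos[k], traj.axis[k], sp, sm,
                               traj.shape.site_offset, traj.params.delta,
                               traj.box)


def chain_labels(n: int, edges: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected-component labels of the bond graph (chains)."""
    if len(edges) == 0:
        return np.arange(n), n
    g = coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                   shape=(n, n))
    ncomp, labels = connected_components(g, directed=False)
    return labels, ncomp


@dataclass
class ChainStatistics:
    """Pooled multimer observables of one production trajectory."""

    length_histogram: np.ndarray   # counts per length l = 1.. (pooled)
    M_energy: float
    M_cluster: float
    M_fit: float
    dispersity: float
    mean_adjacent_angle: float     # degrees, bonded pairs, nematic convention
    Rg_mean: float                 # nm, scattering-equivalent mass
    n_branch_nodes: int            # particles with bond-graph degree > 2
    n_snapshots: int = 0
    rho: float = 0.0               # particles per nm^3


def _histogram_of_lengths(labels: np.ndarray, ncomp: int) -> np.ndarray:
    sizes = np.bincount(labels, minlength=ncomp)
    return np.bincount(sizes)[1:]  # index 0 unused


def fit_M_from_histogram(hist: np.ndarray) -> float:
    """M from the exponential decay of the chain-length histogram.

    The Flory law gives n(l) proportional to x**l with x = (M-1)/M, i.e. a
    straight line in log n(l); a weighted least-squares slope over the occupied
    lengths yields x and hence M = 1/(1-x).  With only monomers present this
    returns 1.
    """
    l = np.arange(1, len(hist) + 1, dtype=float)
    mask = hist > 0
    if mask.sum() < 2:
        return 1.0
    # Poisson-ish weights: var(log n) ~ 1/n
    w = hist[mask].astype(float)
    slope = np.polyfit(l[mask], np.log(hist[mask].astype(float)), 1, w=np.sqrt(w))[0]
    x = np.exp(slope)
    x = min(x, 1.0 - 1e-12)
    return 1.0 / (1.0 - x)


def chain_statistics(traj: Trajectory) -> ChainStatistics:
    """All chain observables pooled over the production snapshots.

    Monomer conservation (sum_l l * count_l = N) holds exactly per snapshot and
    therefore for the pooled histogram.
    """
    sp, sm = traj.snapshot_state(0).site_masks()
    n = traj.n
    pooled = np.zeros(0, dtype=np.int64)
    ncomp_tot = 0
    branch = 0
    angles = []
    rgs = []
    for k in range(traj.n_snapshots):
        edges = _edges_for_snapshot(traj, k, sp, sm)
        labels, ncomp = chain_labels(n, edges)
        ncomp_tot += ncomp
        h = _histogram_of_lengths(labels, ncomp)
        if len(h) > len(pooled):
            h, pooled = pooled, h.astype(np.int64)
        pooled[:len(h)] += h
        deg = np.bincount(edges.ravel(), minlength=n) if len(edges) else np.zeros(n)
        branch += int(np.count_nonzero(deg > 2))
        angles.append(_bonded_angles(traj.axis[k], edges, nematic=traj.mode == "monomer"))
        rgs.append(gyration_radius(traj, k, edges=edges, labels=(labels, ncomp)))
    M_cluster = traj.n_snapshots * n / ncomp_tot
    M_energy = M_from_energy(min(traj.mean_energy_per_particle(), 0.0))
    M_fit = fit_M_from_histogram(pooled)
    all_angles = np.concatenate([a for a in angles if len(a)]) if any(
        len(a) for a in angles) else np.array([])
    all_rg = np.concatenate(rgs)
    rho = n / traj.box ** 3
    return ChainStatistics(
        length_histogram=pooled,
        M_energy=M_energy,
        M_cluster=M_cluster,
        M_fit=M_fit,
        dispersity=dispersity(M_energy),
        mean_adjacent_angle=float(all_angles.mean()) if len(all_angles) else 0.0,
        Rg_mean=float(all_rg.mean()),
        n_branch_nodes=branch,
        n_snapshots=traj.n_snapshots,
        rho=rho,
    )


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------


def _bonded_angles(axes: np.ndarray, edges: np.ndarray, nematic: bool) -> np.ndarray:
    if len(edges) == 0:
        return np.zeros(0)
    c = np.einsum("ij,ij->i", axes[edges[:, 0]], axes[edges[:, 1]])
    if nematic:
        c = np.abs(c)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def adjacent_angles(traj: Trajectory) -> np.ndarray:
    """Angles (degrees) between adjacent cylinder axes, pooled over snapshots.

    Monomer mode: one angle per stacking bond, nematic convention
    arccos(|a.b|).  Trimer mode: the two consecutive-pair angles (theta1,
    theta2) per trimer with axes oriented head-to-tail along the covalent
    topology, regardless of bonding; shape (n_samples, 2).
    """
    if traj.mode == "trimer":
        a = traj.axis
        c1 = np.einsum("sij,sij->si", a[:, 0::3], a[:, 1::3])
        c2 = np.einsum("sij,sij->si", a[:, 1::3], a[:, 2::3])
        th1 = np.degrees(np.arccos(np.clip(c1, -1, 1))).ravel()
        th2 = np.degrees(np.arccos(np.clip(c2, -1, 1))).ravel()
        return np.column_stack([th1, th2])
    sp, sm = traj.snapshot_state(0).site_masks()
    out = [_bonded_angles(traj.axis[k], _edges_for_snapshot(traj, k, sp, sm),
                          nematic=True)
           for k in range(traj.n_snapshots)]
    return np.concatenate(out) if out else np.zeros(0)


# ---------------------------------------------------------------------------
# trimer bond classification
# ---------------------------------------------------------------------------


@dataclass
class TrimerBondStats:
    """Fractions of trimers with 0/1/2 intra-trimer stacking bonds and the
    (theta1, theta2) distributions conditioned on the bond count."""

    f0: float
    f1: float
    f2: float
    angle_edges: np.ndarray                 # histogram bin edges, degrees
    angle_hists: dict = field(default_factory=dict)  # bond count -> 2D counts
    n_trimers_sampled: int = 0

    def _pooled_marginal(self, nbonds: int) -> tuple[np.ndarray, np.ndarray]:
        h = self.angle_hists[nbonds]
        marg = h.sum(axis=0) + h.sum(axis=1)  # pooled theta1 & theta2
        centers = 0.5 * (self.angle_edges[:-1] + self.angle_edges[1:])
        return centers, marg

    def mode_angle(self, nbonds: int, smooth_bins: int = 3) -> float:
        """Location (degrees) of the peak of the pooled theta distribution
        conditioned on the bond count (lightly smoothed against bin noise)."""
        centers, marg = self._pooled_marginal(nbonds)
        k = np.ones(smooth_bins) / smooth_bins
        return float(centers[np.argmax(np.convolve(marg, k, mode="same"))])

    def center_angle(self, nbonds: int) -> float:
        """Mean (degrees) of the pooled conditional theta distribution -- the
        robust location statistic for the broad 0-bond distribution."""
        centers, marg = self._pooled_marginal(nbonds)
        return float((centers * marg).sum() / marg.sum())


def trimer_bond_classification(traj: Trajectory, angle_bin: float = 3.0
                               ) -> TrimerBondStats:
    """Classify every sampled trimer by its number of stacking bonds.

    A bond is a facing stacking site pair (plus site of HC_i, minus site of
    HC_{i+1}) within delta, strictly.  f0 + f1 + f2 = 1 exactly.
    """
    if traj.mode != "trimer":
        raise ValueError("trimer_bond_classification needs a trimer trajectory")
    soff = traj.shape.site_offset
    delta = traj.params.delta
    edges = np.arange(0.0, 180.0 + angle_bin, angle_bin)
    counts = np.zeros(3, dtype=np.int64)
    hists = {k: np.zeros((len(edges) - 1, len(edges) - 1)) for k in range(3)}
    for k in range(traj.n_snapshots):
        pos, ax = traj.pos[k], traj.axis[k]
        sp_plus = pos + soff * ax     # plus-end stacking site
        sp_minus = pos - soff * ax
        d1 = sp_plus[0::3] - sp_minus[1::3]
        d2 = sp_plus[1::3] - sp_minus[2::3]
        d1 -= traj.box * np.round(d1 / traj.box)
        d2 -= traj.box * np.round(d2 / traj.box)
        b1 = np.linalg.norm(d1, axis=1) < delta
        b2 = np.linalg.norm(d2, axis=1) < delta
        nb = b1.astype(int) + b2.astype(int)
        c1 = np.einsum("ij,ij->i", ax[0::3], ax[1::3])
        c2 = np.einsum("ij,ij->i", ax[1::3], ax[2::3])
        th1 = np.degrees(np.arccos(np.clip(c1, -1, 1)))
        th2 = np.degrees(np.arccos(np.clip(c2, -1, 1)))
        for m in range(3):
            sel = nb == m
            counts[m] += int(sel.sum())
            h, _, _ = np.histogram2d(th1[sel], th2[sel], bins=[edges, edges])
            hists[m] += h
    tot = counts.sum()
    return TrimerBondStats(f0=counts[0] / tot, f1=counts[1] / tot,
                           f2=counts[2] / tot, angle_edges=edges,
                           angle_hists=hists, n_trimers_sampled=int(tot))


# ---------------------------------------------------------------------------
# structure factor and gyration radius
# ---------------------------------------------------------------------------


def structure_factor(traj: Trajectory, q: np.ndarray) -> np.ndarray:
    """Orientationally averaged center-of-mass S(Q), averaged over snapshots.

    Debye sum over minimum-image pair distances with the uniform (ideal-gas)
    background subtracted bin by bin and the histogram truncated at box/2,

        S(Q) = 1 + (2/N) sum_bins [hist_b - n_pairs vshell_b / V] sinc(Q r_b),

    which removes the finite-box truncation ripple: an ideal gas gives
    S(Q) = 1 up to sampling noise at every Q.  Correlations must decay within
    box/2 for the truncation to be harmless, which holds comfortably for the
    chain lengths sampled here.
    """
    q = np.asarray(q, dtype=float)
    n = traj.n
    dr = 0.02
    nbins = int(np.floor(0.5 * traj.box / dr))
    edges = np.arange(nbins + 1) * dr
    vshell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    npairs = n * (n - 1) / 2.0
    ideal = npairs * vshell / traj.box ** 3
    centers = 0.5 * (edges[1:] + edges[:-1])
    sinc = np.sinc(np.outer(q, centers) / np.pi)
    s = np.zeros_like(q)
    for k in range(traj.n_snapshots):
        hist = _kernels.pair_distance_hist(traj.pos[k], traj.box, True, dr, nbins)
        s += 1.0 + 2.0 / n * (sinc @ (hist - ideal))
    return s / traj.n_snapshots


def first_peak(q: np.ndarray, s: np.ndarray, qmin: float = 1.0,
               qmax: float = 3.5, smooth: float = 0.15) -> float:
    """Location of the dominant maximum of S(Q) in [qmin, qmax].

    A boxcar of width ``smooth`` (in Q units) suppresses sampling ripple
    before the argmax is taken; for the stacked-multimer state the nearest
    neighbor peak at Q ~ 2 pi / stacking distance dominates this window.
    """
    dq = float(np.median(np.diff(q)))
    w = max(1, int(round(smooth / dq)))
    kernel = np.ones(w) / w
    ss = np.convolve(s, kernel, mode="same")
    sel = (q >= qmin) & (q <= qmax)
    return float(q[sel][np.argmax(ss[sel])])


def _unwrap_chain(pos: np.ndarray, box: float, members: np.ndarray,
                  edges: np.ndarray) -> np.ndarray:
    """Unwrap one chain across periodic boundaries by walking its bonds."""
    idx = {p: i for i, p in enumerate(members)}
    adj = [[] for _ in members]
    for a, b in edges:
        if a in idx and b in idx:
            adj[idx[a]].append(idx[b])
            adj[idx[b]].append(idx[a])
    out = np.empty((len(members), 3))
    seen = np.zeros(len(members), dtype=bool)
    out[0] = pos[members[0]]
    seen[0] = True
    stack = [0]
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if not seen[j]:
                d = pos[members[j]] - pos[members[i]]
                d -= box * np.round(d / box)
                out[j] = out[i] + d
                seen[j] = True
                stack.append(j)
    return out


def gyration_radius(traj: Trajectory, k: int, edges: np.ndarray | None = None,
                    labels: tuple[np.ndarray, int] | None = None) -> np.ndarray:
    """Per-chain gyration radii (nm) of snapshot ``k``.

    The mass distribution is the uniform cylinder volume (consistent with the
    scattering model): Rg^2 = mean_i |c_i - c_mean|^2 + L^2/12 + D^2/8, using
    the parallel-axis composition of the per-unit inertia (the scalar per-unit
    term is orientation independent).  Chains are unwrapped across the
    periodic boundaries before the center spread is taken.
    """
    st = traj.snapshot_state(k)
    if edges is None:
        edges = bond_graph(st)
    if labels is None:
        labels = chain_labels(traj.n, edges)
    lab, ncomp = labels
    rg_unit2 = traj.shape.L ** 2 / 12.0 + traj.shape.D ** 2 / 8.0
    out = np.empty(ncomp)
    for c in range(ncomp):
        members = np.nonzero(lab == c)[0]
        if len(members) == 1:
            out[c] = np.sqrt(rg_unit2)
            continue
        up = _unwrap_chain(traj.pos[k], traj.box, members, edges)
        centered = up - up.mean(axis=0)
        out[c] = np.sqrt((centered ** 2).sum(axis=1).mean() + rg_unit2)
    return out
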