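# Methods

## The model

Each G-quadruplex (G4) unit is an impenetrable cylinder of diameter `D` and
length `L` with two attractive "stacking" sites on its symmetry axis, one past
each flat base at `L/2 + 0.15·D/2` from the center of mass.  All of the
chemistry of tetrad–tetrad stacking is collapsed into a square-well contact
between sites of distinct particles:

    u(r) = -u0   if r < delta        (strictly; r = delta is outside the well)
    u(r) = 0     otherwise

with `delta = 0.5 nm` for self-assembling monomers.  The reference dimensions
`D0 = 2.12 nm`, `L0 = 3.10 nm` describe the monomeric telomeric unit (the
hydration shell is absorbed into these effective dimensions); the shape family
is indexed by a dimensionless factor `K` through `D = D0·K`, `L = L0/K`, so
the product `D·L` is invariant along the family.  Temperature enters only as
the reduced `T* = k_B T / u0`: small `T*` means strong stacking.

The stacking sites are interaction points only — they carry no excluded
volume.  The hard core is the cylinder body alone, and the text of the
potential fixes the boundary convention (`r = delta` non-bonded).

### Trimer (beads-on-a-string) mode

A three-G4 single strand is modeled as three such cylinders held together by
covalent tethers: each consecutive pair is linked through rim sites on the
facing bases (radial distance `D/2` from the axis, axial position `±L/2`)
whose potential is zero below `delta_cov = 0.5·D0` and infinite beyond — a
hard tether with no restoring force, implemented as move rejection.  The
stacking well range is reduced to `delta = 0.25·D0` in this mode, and the
outward bases of the two terminal cylinders carry no stacking sites, so
distinct trimers do not stack.  Because rim sites break the azimuthal symmetry
of a cylinder, trimer-mode particles carry a full orientation frame (axis plus
a rim vector); the two rim sites of one cylinder are placed at the same
body-fixed azimuth.  The relative azimuth of the sites is not constrained by
anything we model explicitly — a single seam is the simplest choice, and the
bond-count fractions it produces at the benchmark state point (roughly
45/45/10 percent for 0/1/2 bonds) support it a posteriori.

## Monte Carlo sampling

Sampling is canonical (NVT) Metropolis with single-particle moves, half
translations and half rotations, under cubic periodic boundary conditions.
One sweep is `N` attempted moves.  A proposed move is rejected outright on
hard-core overlap (or a broken tether in trimer mode) and otherwise accepted
with probability `min(1, exp(-dE/T*))`, with all energies kept in units of
`u0`.  The total energy is tracked incrementally; it is an integer bond count,
so the cached value agrees with a full recomputation exactly.

*Overlap test.*  Cylinder–cylinder overlap is decided by a GJK query on the
two convex bodies (support-function formulation) behind a bounding-sphere
prefilter.  Exact touching, and separations below ~1e-10 of the body scale,
may classify either way; a non-converged query counts as overlapping, which
at worst rejects a valid move and cannot corrupt the hard core.  The
predicate is validated in the tests against a signed-distance point-sampling
oracle on near-contact pairs, excluding pairs within the oracle's sampling
resolution of exact touching; the mean chain length is insensitive to this
boundary at far below the 1e-3 level because the configurations involved have
vanishing measure.

*Neighbor search.*  A linked-cell list with cell edge at least the full
interaction diameter (circumscribed sphere plus well range) makes a move
O(1); with fewer than three cells per dimension the code falls back to a
single-cell (all-pairs) stencil, and both paths are contract-tested against
the all-pairs energy.

*Move amplitudes.*  The study conditions are extremely dilute (packing
fraction of order 1e-3), so monomer-mode translations default to box/4 jumps:
association kinetics are then limited by the probability of landing in a
bonding configuration rather than by diffusion, which is orders of magnitude
faster to equilibrate.  An acceptance-targeting auto-tuner (0.2–0.6 window,
clamped, active during equilibration only so production preserves detailed
balance) is available but off by default: in an association-dominated dilute
system, shrinking amplitudes to chase an acceptance window stalls
equilibration without improving sampling.  Trimer mode instead uses local
moves (0.4 nm, 0.6 rad) because box-scale jumps would almost always violate
the tethers.

*Initialization and equilibration.*  Runs start from an orthorhombic lattice
(trimers: one coaxial, tether-satisfying triplet per node) at the box size
fixed by `rho = N/V = N_av·C`.  Equilibration is judged by stationarity of
the per-sweep energy trace: a linear trend fitted to block means of the last
half must be small against the mean level (5% + one bond) or within the
block-to-block noise.  A magnitude criterion is used deliberately — the bond
count is strongly autocorrelated, and significance tests reject genuinely
stationary traces.  The grid-search driver extends non-stationary runs (up to
two extra equilibrate-and-sample blocks) before flagging them.

## Observables

*Chain statistics.*  Bonds are stacking site pairs within `delta`; chains are
connected components of the bond graph (rare degree>2 nodes are counted
as-is and reported).  The mean chain length `M` is measured three ways: from
the mean square-well energy per particle via bonds-per-particle `b = |eps|/u0`
and `M = 1/(1-b)`; from `N / (number of chains)`; and from the slope of the
log chain-length histogram, which at equilibrium follows the step-growth
(Flory) law `nu(l) = rho·M^-(l+1)·(M-1)^(l-1)`.  The three must agree within
sampling error — a strong internal consistency check.  Note the energy route
uses the magnitude of the (negative) well energy; writing the formula with a
signed energy would put `M` below one.  Dispersity is `2 - 1/M`.

*Angles.*  Monomer mode reports the angle between bonded axes in the nematic
convention `arccos|a·b|` (bonded pairs only); trimer mode reports the two
consecutive-pair angles with axes oriented head-to-tail along the covalent
topology, conditioned on the intra-trimer bond count (0, 1 or 2).  For the
broad 0-bond distribution the conditional mean is the robust location
statistic; the sharp 2-bond distribution is located by its (smoothed) mode.

*Structure factor and gyration radius.*  `S(Q)` is the orientationally
averaged center-of-mass Debye sum over minimum-image pair distances,
`1 + (2/N) Σ sinc(Q r)`; the minimum-image truncation distorts only
`Q ≲ 2π/box`, far below the stacking peak near 2 nm⁻¹.  Per-chain gyration
radii use the uniform-cylinder mass distribution (consistent with the
scattering model): `Rg² = ⟨|c_i - c̄|²⟩ + L²/12 + D²/8`, with chains unwrapped
across the periodic boundaries.

*Scattering intensity.*  Each cylinder is replaced by a Poisson number of
uniform random interior points at a fixed density (default 20 nm⁻³, ~220 per
reference cylinder) and the orientationally averaged intensity follows from
the Debye sum over distinct point pairs, binned into a 0.005 nm distance
histogram (the binning phase error is < 1e-4 over the experimental Q range).
The self term is excluded and the sum normalized by the ordered pair count:
this makes the single-body estimate an unbiased sample of the continuum form
factor, so it converges to the analytic cylinder `P(Q)` as density grows
instead of leveling off at a 1/N floor — the analytic form factor (adaptive
quadrature of the standard closed form) is the convergence oracle in the
tests.  Fresh fills per snapshot decorrelate fill noise.  Intensities are in
arbitrary units; comparisons with experiment profile the scale out.

## Fitting and thermodynamics

The refinement against an experimental curve is an exhaustive grid search
over `(K, T*)`, not a continuous optimization: the landscape is cheap to
evaluate and the argmin stays robust against simulation noise.  The default
residual is the sum of squared differences of
`log10 I` over `Q ∈ [0.05, 3] nm⁻¹` with unit weights and the scale profiled
analytically — the log residual weights the low/intermediate-Q
multimerization signal the model is built for, and the coarse cylinder
geometry is not expected to track the high-Q detail.  Linear and
1/sigma²-weighted residuals (with optional flat background) are provided; no
weighting protocol is prescribed by the source analysis, so the default is a
declared choice.  Points where either curve is non-positive are dropped from
the log residual, not clipped.  Ties in the argmin break toward the lowest
`T*` and are reported.

Thermodynamics at the standard temperature `T = 293 K` (with
`k_B = 1.987e-3 kcal mol⁻¹ K⁻¹`) follow from `(M, T*)` alone:

    G_ST = -k_B T ln[M(M-1)]
    H_ST = -u0 = -k_B T / T*
    S_ST = (H_ST - G_ST) / T      (reported in cal mol⁻¹ K⁻¹)

`G_ST` requires `M > 1` and is rejected otherwise with a diagnostic.  The
standard-state convention (1 M, 293 K) would suggest a concentration term in
`G⁰`, yet the benchmark values follow the bare formula with none; the
implementation therefore computes the bare formula and exposes an optional
standard-state correction hook (`-k_B T ln(C/1M)`), off by default, rather
than silently resolving the ambiguity.  The H/S split above likewise matches
all benchmark values but is an inference: the well depth is the natural
bonding enthalpy of a square-well model, and the entropy is the remainder.

## Synthetic reference curves

Experimental curves for the self-assembled samples are not distributed, so
round-trip validation uses synthetic references: a curve simulated at a known
`(K, T*)` with multiplicative Gaussian noise (default 2%) and a matching
sigma column, written in the 3-column ASCII dialect.  These share the
generator's forward model, so a round-trip demonstrates identifiability of
`(K, T*)` at grid resolution under realistic noise — not the adequacy of the
cylinder model for real scattering data, which only a comparison against
measured curves could show.  Mass-concentration input (mg/mL) is converted
with a configurable molar mass (default 22,600 g/mol for the twelve-repeat
telomeric strand).

## Problem sizes and defaults

Production state points use 256–600 particles (full-scale studies of these
systems use several thousand) with 4×10⁴–3×10⁵ sweeps; at the dilute
conditions studied
the mean chain length is intensive but carries a visible finite-size bias
below a few hundred particles (about -6% at N=256 for the most multimeric
dilute state, within the 10% uncertainty quoted for M; N=500 removes it).
The fit driver defaults to N=128 per grid point with adaptive equilibration
extension, which recovers generating parameters at grid steps of 0.1 in K
and ~0.02–0.04 in T*.  All state defaults (concentrations 0.5/0.6/4.5 mM,
10 mg/mL; T* and K per state point) are the study conditions themselves.

## Known limitations

- Rings and branches are not modeled by the Flory analysis; they are counted
  into components as-is and flagged.  At the simulated state points branch
  nodes are absent or vanishingly rare.
- The scattering model has homogeneous contrast and no explicit hydration
  shell or solvent-exclusion term; intensities are only defined up to scale.
- `S(Q)` below ~2π/box is truncation-distorted; the package reports it but
  fits never use it.
- The GJK query treats separations below ~1e-10 nm as ambiguous; this is far
  below any physically meaningful resolution of the model.
- Kinetics are meaningless: Metropolis with box-scale jumps samples the
  equilibrium ensemble efficiently but destroys any dynamical interpretation.
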