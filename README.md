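# g4stack

Extremely coarse-grained Monte Carlo of G-quadruplex (G4) multimerization,
with SAXS-comparable scattering intensities, chain statistics, stacking
thermodynamics, and grid-search refinement of the model parameters against
experimental curves.

## The problem

Guanine-rich telomeric DNA folds into G-quadruplexes, and under biologically
relevant conditions G4 units stack end-to-end into multimers.  Small-angle
X-ray scattering sees this as a low-Q excess over the monomer curve, but a
measured I(Q) alone cannot separate single-particle shape from aggregation.
This package implements the complementary simulation side: each G4 unit is a
hard cylinder (reference dimensions D0 = 2.12 nm, L0 = 3.10 nm) with two
attractive sites on its axis at L/2 + 0.15·D/2 from the center, interacting
through a square well of depth u0 and range δ = 0.5 nm.  Two dimensionless
knobs span the model space:

* **K** — shape factor, D = D0·K, L = L0/K (D·L invariant);
* **T\*** = k_BT/u0 — reduced temperature; lower T\* means stronger stacking.

NVT Metropolis sampling of N such cylinders at the experimental number
density ρ = N_av·C yields equilibrium ensembles whose scattering intensity
(by the scattering-point Debye method) can be compared directly with
experiment, and whose chain statistics follow step-growth polymerization:
the chain-length density is the Flory law ν(l) = ρ·M^−(l+1)·(M−1)^(l−1) with
mean chain length M = (1 − ε/u0)⁻¹ measured from the mean well energy per
particle ε (equivalently from bond-graph components, or the histogram
slope).  From (M, T\*) follow dispersity Đ = 2 − 1/M and the standard-state
stacking thermodynamics

    G_ST = −k_B T ln[M(M−1)],   H_ST = −u0 = −k_B T/T*,   S_ST = (H−G)/T.

A trimer mode models a three-G4 single strand (beads on a string): three
cylinders tethered by hard covalent rim-site constraints (cutoff 0.5·D0),
stacking well δ = 0.25·D0, no stacking sites on the outward terminal bases.

Intended users: scattering and nucleic-acid structure groups who need a
cheap, quantitative forward model for G4 multimerization — not atomistic
detail.

## Worked example

Self-assembly at the multimeric state point (K = 1, T\* = 0.085, C = 0.6 mM,
N = 500; `examples/01_self_assembly.py`):

```text
box = 111.4 nm for 500 particles at 0.6 mM
M (energy route)    = 1.940
M (cluster count)   = 1.940
M (histogram slope) = 1.988
dispersity          = 1.484
mean bonded angle   = 21.1 deg
mean Rg             = 2.08 nm
G_ST0 = -0.35 kcal/mol, H_ST0 = -6.85 kcal/mol, S_ST0 = -22.2 cal/mol/K at 293 K
```

Half the material is in dimers and longer stacks (M ≈ 1.9), the three M
estimators agree within a few percent (the internal consistency check of the
step-growth picture), bonded neighbors are tilted by ~21° on average, and
the implied stacking free energy at 293 K is weakly favorable.  The other
examples cover the scattering-point form factor (`02`), the S(Q) stacking
peak at 4.5 mM (`03`), trimer flexibility (`04`) and the (K, T\*) grid fit
(`05`); each prints a line explaining its numbers.

A thin CLI wraps the same capabilities:

```bash
g4stack simulate --config run.yaml --out traj.h5
g4stack analyze  --traj traj.h5 --out stats.json
g4stack scatter  --traj traj.h5 --qmin 0.05 --qmax 5.2 --out curve.dat
g4stack thermo   --m 1.66 --tstar 0.09
g4stack fit      --exp data.dat --out fitreport/
g4stack make-reference --k 1.0 --tstar 0.085 --out ref.dat
```

Experimental input is the 2–3 column ASCII `.dat` dialect (Q, I, σ), with
automatic Å⁻¹/nm⁻¹ detection.

## Layout

```
src/g4stack/        geometry, simulator, assembly_stats, scattering,
                    thermo, fitting, cli (+ numba kernels in _kernels)
tests/              pytest suite; _oracles.py holds the brute-force oracles
examples/           one narrative script per capability
docs/methods.md     model, algorithms, defaults, limitations
scripts/acceptance.py
```
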