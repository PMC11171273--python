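# Methods

This note records the models, algorithms, numerical choices, and known
limitations behind `dmguess`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The task

A converged Kohn-Sham calculation produces a one-particle density matrix
ρ over the atomic-orbital basis; with the overlap matrix S it satisfies
Tr[ρS] = N_e (we use the closed-shell convention D = 2 C_occ C_occ^T).
`dmguess` trains a small dense network to map a molecule's internal
coordinates directly to all independent elements of ρ (its upper
triangle), then uses the prediction three ways: as an SCF initial guess,
as a source of non-self-consistent energies and forces, and as the force
provider of molecular dynamics that needs at most one SCF step per frame.

Because a dense network is an invariant model and ρ is equivariant, every
geometry is first brought into a canonical pose (anchor atom at the
origin, designated atoms on axes/planes — see `FRAMES.md`), and forces
are rotated back afterwards. The feature vectors are 3 internal
coordinates for the triatomics (H2O, S2O) and the 6 Fe-O distances for
the hexaaqua iron(II) complex.

## The DFT engine

The engine is a self-contained restricted Kohn-Sham implementation over
Gaussian orbitals written for this package (numpy + numba):

* **Integrals.** McMurchie-Davidson Hermite expansions for overlap,
  kinetic, nuclear-attraction and two-electron repulsion integrals over
  Cartesian primitives, transformed to normalized real solid harmonics.
  The Boys function uses a downward-recursion series for x ≤ 35 and the
  asymptotic form above. ERIs use 8-fold permutational symmetry and
  Schwarz screening (threshold 1e-12).
* **Basis.** cc-pVDZ parameters for H, O and S are bundled as plain text
  (transcribed from the published compilations; see the header of
  `engine/data/cc-pvdz.dat`). For Fe only the published contraction
  pattern [6s5p3d1f] (43 functions) is bundled: dimension queries work,
  while an SCF on the 187-function complex — far beyond a single-CPU
  desk scale — raises a clear error. Engine correctness is anchored
  against literature energies reproduced in the test suite
  (H2 RHF/cc-pVDZ −1.128709 Ha; water RHF/cc-pVDZ ≈ −76.0268 Ha) and
  against the published atomic values of the functionals below.
* **Exchange-correlation.** BLYP: Becke-88 exchange plus Lee-Yang-Parr
  correlation (Miehlich form specialized to a spin-compensated density).
  The energy density is written symbolically once and vρ, vσ are
  generated by symbolic differentiation (sympy), eliminating
  hand-derivation errors; both functionals reproduce their papers' atomic
  benchmarks (B88 H-atom exchange −0.3098 Ha, LYP He correlation
  ≈ −0.0437 Ha) in dedicated validation runs. Quadrature uses Becke
  fuzzy-cell partitioning with Bragg-radius size adjustment, Mura-Knowles
  radial points and a Gauss-Legendre × uniform-φ angular product rule.
  Grid levels: coarse (40 radial, 10 θ-nodes), medium (55, 14),
  fine (75, 18); energies move by ~1e-5 Ha between medium and fine.
* **Solvers.** `diis` is Pulay mixing of Fock matrices (subspace 8,
  commutator error in the orthogonal basis); convergence is an energy
  difference below 1e-9 Ha between cycles, with a 50-cycle cap —
  the reference protocol's convergence definition. `sos` is a
  second-order solver: trust-region Newton on occupied-virtual orbital
  rotations with finite-difference Hessian-vector products inside a
  preconditioned CG (inexact Newton), plus up to three Knowles-Handy
  refreshes on freshly rebuilt Fock matrices per reported cycle. A cycle
  therefore means "one inner solve + its refreshes", mirroring how
  co-iterative second-order solvers count macro-iterations; convergence
  is declared on the orbital-gradient norm (‖g‖_F < 3e-5), which bounds
  the residual energy error quadratically below the DIIS criterion.
* **Initial guesses.** Five conventional schemes are implemented as
  members of the standard families: `minao` (superposed spherically
  averaged fractional-occupation atomic densities used directly),
  `atom` (aufbau DM from the Fock matrix built on that density),
  `vsap` (aufbau DM from superposed neutral-atom potentials, no XC),
  `huckel` (on-the-fly extended Hückel over the atomic orbitals,
  Wolfsberg-Helmholz K = 1.75), and `one_electron` (core-Hamiltonian
  eigenstates). They are family-faithful rather than bitwise ports of
  any particular code.
* **Gradients.** Analytic nuclear gradients: raise/lower derivative
  integrals contracted on the fly (nothing four-index stored), the
  energy-weighted density matrix for the overlap term, translational
  invariance for nuclear-operator and fourth-center terms, and the
  basis-motion XC term. Grid response (point motion plus weight
  derivatives) is neglected — the two pieces cancel to quadrature
  accuracy for a consistent atom-centered scheme; the residual
  force-consistency floor is ~1e-5 Ha/bohr at the medium grid and is the
  dominant term in NVE energy drift. Central-difference validation is
  part of the test suite (agreement ~1e-5 Ha/bohr, far inside the 1e-3
  oracle tolerance).
* **Non-self-consistent evaluation.** `single_point_from_dm` supports 0
  SCF steps (one Fock build at the supplied DM) and 1 step (a single
  diagonalization first). For a general, possibly non-idempotent DM the
  Pulay term uses W = ¼ D F D, which reduces to the canonical
  energy-weighted DM at convergence. Both modes exist because the
  deployment protocol uses one step for dynamics while the force parity
  analysis is defined without any step.

## Sampling and datasets

Triatomic training geometries come either from NVT dynamics on converged
engine forces (the reference procedure) or from the desk-scale surrogate
used by default here: Gaussian displacements of the internal coordinates
with classical thermal widths σ = sqrt(kT/k) at 150 K (force constants:
O-H stretch 8.45 aJ/Å², H-O-H bend 0.76 aJ/rad²; S-S 4.9 and S-O
9.1 aJ/Å², bend 1.1 aJ/rad²). The surrogate reproduces the width of a
harmonic 150 K ensemble but not mode-mode correlation or anharmonic
skew, so thermal *means* from datasets built on it are trusted only at
the few-1e-3 Å level. Hexaaqua geometries are uniform rigid ligand
displacements within ±10% of the 2.0525 Å equilibrium Fe-O distance.
Each geometry is canonicalized, converged (warm-started from the
previous frame's DM — the converged target is guess-independent), and
stored as features plus the row-major upper triangle of ρ; symmetrizing
the mirrored triangle reproduces the engine matrix exactly.
Non-convergent frames are logged and dropped. Splits default to
9000/800/1000 at full scale; reduced runs keep the same proportions.
Feature/target standardization statistics are computed on the training
split only.

## Networks and training

Two ELU hidden layers per molecule — (18, 32) for H2O, (18, 28) for S2O,
(16, 32) for the Fe complex — mapping 3 (or 6) standardized coordinates
to the standardized DM triangle (300 / 1275 / 17578 outputs). Training
is plain numpy (forward, backprop, Adam): MSE loss on standardized
elements, batch 64, learning rate 1e-3 with plateau decay, early
stopping on the validation MAE in physical units (patience 50-400
epochs depending on scale), weights selected at the best validation MAE.
Runs are bitwise-reproducible under a fixed seed. Element magnitudes
span several orders, hence the per-element target standardization.

Post-processing: the triangle is mirrored to a symmetric matrix, and the
DM is rescaled by N_e / Tr[ρS] so it describes the right electron count
(the raw prediction is typically off by well under 0.1%). The prediction
is not idempotent — ρSρ − 2ρ ≠ 0 — which is tolerated, not constrained;
the one SCF step used in dynamics also repairs most of it.

## Benchmarks and dynamics

The benchmark module reports per-(guess, solver) iteration means and
variances over geometry ensembles (capped non-convergent runs are kept
in the statistics and also counted separately, and a converged-only mean
is reported because the averaging convention for capped runs is
ambiguous), convergence histories E(n) − E_GS and ‖ρ_GS − ρ_n‖_F
(Frobenius — the only norm consistent with an elementwise definition),
percent DM variation 100·‖a−b‖_F/‖b‖_F stated explicitly with its
reference matrix, the element-magnitude census with open bins and a
separate ≥ 1 overflow bin, and force parity on the in-plane atom with
per-component MAEs in meV/Å.

MD is velocity Verlet with a Nosé-Hoover chain (length 3, 50 fs
coupling, Martyna-Tuckerman splitting) or NVE; timestep 0.5 fs by
default; Maxwell-Boltzmann initial velocities with the total momentum
removed. The ML force provider executes per step: canonicalize →
predict → rescale → one SCF step → forces → back-rotate. Reference
providers run full SCF per step, or a single step from the `minao`
density. The reference trajectory lengths (~0.1 ns) are presets, not
defaults; desk-scale runs use hundreds of steps and correspondingly
wider error bars.

## Problem sizes used by the shipped checks

Chosen as this package's desk-scale operating points: the water
laboratory trains on 1000 configurations (validation 120, test 130) on
the coarse grid; the S2O laboratory uses a 64-geometry ensemble; force
parity uses single-digit ensembles; the acceptance script trains on 600
water configurations and averages its first-iteration DM change over 20
fresh geometries; MD checks run a few hundred steps. Full-scale settings
(9000/800/1000, 0.1 ns trajectories) are plain parameter changes.

## Known limitations and open choices

* Restricted closed-shell only, including low-spin Fe(II); no
  spin-polarization, no functionals beyond GGA in production (a plain
  Hartree-Fock mode exists for validation), no periodic systems.
* The S cc-pVDZ contraction coefficients are the least-anchored data
  item (validated through internal consistency and the molecular
  energies, not an external printed energy); all S2O comparisons are
  internal (ML vs this engine's reference), which they remain valid for.
* Our independently validated BLYP/cc-pVDZ water optimum is
  r(O-H) ≈ 0.980 Å, θ ≈ 101.8° — the angle sits ~2.3° below the 104.14°
  sometimes quoted for the static structure, but agrees with the 150 K
  thermal mean (101.83°) and with the systematic angle reduction that
  small double-zeta basis sets produce in correlated methods. The
  geometry checks in the acceptance suite report whatever this engine
  measures; no parameter is steered toward the quoted angle.
* The angular product grid is only approximately rotation-invariant;
  canonical-frame evaluation (which the deployment workflow uses anyway)
  removes the orientation noise from learned-vs-reference comparisons.
* Fe-complex SCF is out of desk-scale reach (the ERI tensor alone is
  ~10 GB); its geometry/feature/benchmark plumbing is exercised with the
  synthetic mock engine instead.
* The S2O terminal-atom assignment (axis vs plane) follows input order;
  swapping gives the mirror-equivalent labeling.
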