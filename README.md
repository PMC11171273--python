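# dmguess

Machine-learned one-particle density matrices as SCF initial guesses,
non-self-consistent energies and forces, and drivers of accelerated
ab initio molecular dynamics.

## The problem

Kohn-Sham DFT is solved iteratively: the effective potential depends on
the density it generates, so a self-consistent-field (SCF) cycle updates
the one-particle density matrix ρ until the energy settles (here: below
10⁻⁹ Ha between cycles). How many cycles that takes depends strongly on
the starting ρ. `dmguess` trains a small dense neural network that maps a
molecule's internal coordinates straight to all independent elements of
the converged ρ (its upper triangle, D(D+1)/2 numbers for a D-function
basis). Because ρ transforms with the molecule while a dense network is
invariant, geometries are first brought into a canonical pose — anchor
atom at the origin, designated atoms on axes and planes — and predicted
forces are rotated back to the laboratory frame.

The predicted ρ̂ is symmetrized and rescaled by N_e / Tr[ρ̂S] so it
carries the right electron count. It is then used three ways:

1. **SCF initial guess** — benchmarked against the conventional schemes
   (superposed atomic densities, core-Hamiltonian eigenstates, atomic
   Fock, extended Hückel, superposed atomic potentials) with both DIIS
   and a second-order solver;
2. **non-self-consistent observables** — energies and analytic forces
   evaluated from ρ̂ with zero or one SCF step;
3. **molecular dynamics** — NVT/NVE trajectories whose forces come from
   the predicted ρ̂ plus a single SCF step per frame.

Everything runs on the package's own all-electron Gaussian-basis
restricted Kohn-Sham engine (BLYP/cc-pVDZ by default): McMurchie-
Davidson integrals compiled with numba, Becke-grid quadrature,
symbolically differentiated exchange-correlation, DIIS and trust-region
Newton solvers, and analytic nuclear gradients. The reference systems
are H₂O, S₂O (3 internal coordinates each) and the hexaaqua Fe(II)
complex (6 Fe-O distances; geometry and pipeline support — its
187-function SCF is beyond single-CPU scale).

## Worked example

```python
import numpy as np
from dmguess.engine.api import RealEngine, SCFConfig
from dmguess.data_factory import (sample_thermal_geometries, build_dataset,
                                  split_dataset)
from dmguess.model import ModelSpec, train_model, predict_dm, rescale_dm
from dmguess.geometry import features, canonical_frame
from dmguess.engine.rks import scf_sos

engine = RealEngine()
cfg = SCFConfig(grid_level="coarse")

# 1) thermally sampled water geometries and their converged DMs
geoms = sample_thermal_geometries("h2o", 150.0, 320, "perturbation", seed=11)
ds = split_dataset(build_dataset(geoms, cfg, engine), (256, 32, 32), seed=1)

# 2) train the 3 -> 18 -> 32 -> 300 network
spec = ModelSpec.for_molecule("h2o")
model, hist = train_model(spec, *ds.rows("train"), *ds.rows("validation"),
                          seed=2, molecule="h2o")

# 3) use the prediction as an SCF starting point on a fresh geometry
geom = sample_thermal_geometries("h2o", 150.0, 1, "perturbation", seed=99)[0]
sys_ = engine.system(geom, cfg)
dm = rescale_dm(predict_dm(model, features(geom, "h2o")), sys_.S, 10)
sol = scf_sos(sys_, dm.matrix, tol=1e-9)
print(sol.iterations, sol.energies[0] - sol.energy)
```

Printed with these settings (320 geometries, seed 11): the second-order
solver reports `1` cycle from the learned start, with the starting
energy `5.4e-06` Ha above the converged ground state — against about
five cycles from the core-Hamiltonian guess and three to four from the
other conventional guesses on the same ensemble. The companion
evaluation (`evaluate_model` on the held-out split) reports
MAE `1.1e-04` au, RMSE `2.7e-04` au and R² `0.999998` at this reduced
training size.

## Command line

```
dmguess pipeline    --config run.yaml        # sample -> dataset -> train
dmguess bench-guess --config run.yaml        # iteration table per guess/solver
dmguess bench-history --config run.yaml --guess ml
dmguess bench-forces  --config run.yaml
dmguess run-md        --config run.yaml
```

with a YAML configuration such as

```yaml
molecule: h2o
scf:      {solver: diis, grid_level: coarse}
sampling: {n_frames: 400, temperature: 150, seed: 0}
md:       {mode: ml, n_steps: 500}
```

Stages cache their artifacts per config hash and are skipped on re-runs
unless `--force` is given.

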