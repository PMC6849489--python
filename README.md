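# photodyn

Machine-learned potentials for nonadiabatic surface-hopping photodynamics.

Simulating what a molecule does after absorbing light requires excited-state
dynamics across several coupled electronic potential-energy surfaces, with
transitions between them.  The accurate electronic-structure methods this
needs (multireference CI and relatives) cost minutes to hours per geometry,
capping direct simulations at ~100 fs.  `photodyn` implements the
machine-learning alternative end to end for method development and teaching:
feed-forward neural networks learn the per-state energies E_i, forces, the
nonadiabatic coupling vectors **d**_ij that drive transitions, and dipole
moments, then replace the electronic-structure code inside a fewest-switches
surface-hopping (FSSH) propagator.  Bundled analytic diabatic models — an
avoided crossing, a true conical intersection, and a three-state S2→S1→S0
cascade — play the role of the quantum-chemistry reference, including its
awkward habit of returning wavefunctions with random overall signs, so the
entire pipeline runs and is testable with no external data.

The pieces, each usable on its own:

* **Phase correction** — wavefunction signs are arbitrary per geometry, so
  raw off-diagonal properties (NACs, transition dipoles, spin–orbit
  couplings) are sign-discontinuous and unlearnable.  Overlaps between the
  eigenvectors of adjacent geometries, with recursive path bisection where
  the overlap is indecisive, restore a single global sign convention:
  element (i,j) is multiplied by p_i·p_j with p ∈ {±1} per state.
* **NN potentials** — inverse-distance descriptor (translation/rotation
  invariant), shared trunk, one head per property.  Forces are the exact
  analytic derivative of the energy heads (conservative field, energy-
  conserving dynamics); NAC vectors are built covariantly from predicted
  coefficients contracted with the descriptor Jacobian.  Seeded random grid
  search over hyperparameters.
* **FSSH dynamics** — velocity-Verlet nuclei (dt = 0.5 fs default), unitary
  electronic propagation of c_i with the v·**d**_ij coupling, stochastic
  hops with probability g_{a→j} = max(0, 2 dt (v·d_aj) Re[c_a*c_j]/|c_a|²),
  energy-conserving velocity rescaling, frustrated-hop bookkeeping.
* **Adaptive sampling** — an ensemble of networks trained from the same
  training set; when their predictions disagree beyond per-property
  thresholds, the geometry is recomputed with the reference provider,
  phase-corrected, added, and the ensemble retrained.  Thresholds tighten
  by ×0.95 per trigger and freeze after a configurable simulated time.
* **Critical points** — gradient-only minimum and minimum-energy conical
  intersection (MECI) optimization via a penalty objective, seam scans, and
  near-seam gap statistics comparing surrogate to reference.
* **Analysis** — classical population curves, population MAE between
  methods, and sequential-kinetics time constants (closed-form A→B→C fit).

## Worked example

Train a surrogate for the three-state cascade model, run 100 paired
surface-hopping trajectories with the network and with the exact model, and
compare:

```python
import numpy as np
from photodyn.experiments import train_sequential_decay_nn
from photodyn.models import SequentialDecayModel
from photodyn.dynamics import initialize, run_ensemble_of_trajectories
from photodyn.sampling import compute_hessian
from photodyn.analysis import fit_time_constants, population_mae

model = SequentialDecayModel()
nn = train_sequential_decay_nn(seed=0)   # phase-corrected scan, ~1 min
print("validation RMSE:", {k: round(v, 4) for k, v in nn.val_rmse.items()})

g0 = model.reference_geometry()
wigner = {"kind": "wigner", "hessian": compute_hessian(model, g0), "n_states": 3}
pops_nn, _ = run_ensemble_of_trajectories(
    lambda s: initialize(g0, wigner, initial_state=2, seed=s),
    nn, n_traj=100, dt_fs=0.5, t_max_fs=100.0, seed=7)
pops_ref, _ = run_ensemble_of_trajectories(
    lambda s: initialize(g0, wigner, initial_state=2, seed=s),
    model, n_traj=100, dt_fs=0.5, t_max_fs=100.0, seed=7)

print("population MAE (NN vs exact):", round(population_mae(pops_nn, pops_ref), 3))
fit = fit_time_constants(pops_nn)
print(f"time constants: tau1 = {fit.tau1:.1f} fs, tau2 = {fit.tau2:.1f} fs")
```

Output:

```
validation RMSE: {'energy': 0.001, 'force': 0.0093, 'nac': 0.0576, 'dipole': 0.0162}
population MAE (NN vs exact): 0.068
time constants: tau1 = 40.6 fs, tau2 = 55.3 fs
```

The validation RMSEs are in atomic units (energy in Hartree, ~0.03 eV here).
The MAE is the mean absolute difference between NN-driven and exact-model
populations over all times and states for the same initial conditions and
hop random streams, so it measures how much the learned surfaces perturb
the dynamics; 0.07 at 100 trajectories shrinks toward ~0.04 at 200.  The
time constants are the S2 decay and S1→S0 transfer times of the fitted
sequential kinetics for this model.

The same workflow is scriptable from the shell:

```bash
photodyn generate -c config.yaml -o run/gen        # normal-mode initial set (phase-corrected)
photodyn train    -c config.yaml -i run/gen/dataset.h5 -o run/model
photodyn dynamics -c config.yaml --model run/model/model.npz -o run/dyn
photodyn analyze  -i run/dyn/populations.tsv -o run/analysis
```

plus `phase-correct`, `sample` (the adaptive loop) and `optimize`
(`--type min|meci`).  Every run directory receives the resolved
configuration and a log, so any stage can be re-run reproducibly.

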