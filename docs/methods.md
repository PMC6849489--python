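# Methods

`photodyn` implements a machine-learning molecular-dynamics pipeline for
photochemistry: neural-network potentials for several coupled electronic
states drive fewest-switches surface-hopping (FSSH) trajectories, the
training data are made learnable by wavefunction phase correction, the
training set grows itself by ensemble-disagreement adaptive sampling, and
critical points of the learned surfaces (minima, minimum-energy conical
intersections) are optimized with gradient-only methods.  Analytic
diabatic models stand in for the electronic-structure reference, so the
whole pipeline is runnable and testable without external quantum-chemistry
data.  This note records the models, the numerical choices, and what the
bundled experiments do and do not demonstrate.

## Reference models

All models define a smooth symmetric diabatic matrix H(R) with analytic
Cartesian derivatives.  Diagonalization yields adiabatic energies E_i,
Hellmann–Feynman gradients G_i = U_i^T (∂H/∂R) U_i and nonadiabatic
coupling vectors d_ij = U_i^T (∂H/∂R) U_j / (E_j − E_i).  Near
degeneracies the gap in the NAC denominator is floored at 1e−8 Hartree, so
the coupling is capped (and flagged) rather than infinite at a conical
intersection itself.  With `randomize_phase=True`, every evaluation
multiplies each eigenvector by an independent random sign from a dedicated
RNG stream — the arbitrary-global-phase behaviour of real electronic-
structure codes, which flips the sign of every off-diagonal property
(NACs, transition dipoles, SOCs) unpredictably between calls.

* **Avoided crossing** (`avoided_crossing`): an H₂-like diatomic with two
  displaced harmonic diabats (k = 0.02 Hartree/Bohr², minima at 2.0 and
  3.0 Bohr, offset 0.015 Hartree) and a Gaussian coupling of height
  0.005 Hartree centred at the diabatic crossing r = 3.25 Bohr.  The NAC
  peaks near the crossing; the adiabatic gap there is 0.01 Hartree.
* **Conical intersection** (`conical_intersection`): three unit-mass
  particles; in bond displacements x = r₁₂ − 2, y = r₁₃ − 2, z = r₂₃ − 3
  (Bohr) the Hamiltonian is a linear vibronic model,
  H = k/2 (x²+y²+z²) I + [[κx, λy], [λy, −κx]] with k = 0.02, κ = λ = 0.03.
  The coupling vanishes on the 1-D seam x = y = 0; the minimum-energy
  conical intersection (MECI) is at x = y = z = 0 with E = 0 — an analytic
  fixture for optimizer tests.  With κ = λ the lower-state minimum is a
  ring of radius κ/k; tests that need a unique minimum use λ ≠ κ.
* **Sequential decay** (`sequential_decay`): a diatomic with three diabats
  sharing one harmonic confinement and differing by linear slopes, so the
  S2/S1 diabats cross at r = 3.45 Bohr and S1/S0 at r = 3.03 Bohr, each
  with a Gaussian coupling of height 0.002 Hartree (width 0.25 Bohr); the
  direct S0–S2 coupling is zero.  A trajectory excited at the compressed
  ground-state minimum (r = 1.2 Bohr) oscillates outward through both
  crossings and relaxes S2 → S1 → S0 on a tens-of-femtoseconds scale.
  Masses (1 amu) and Landau–Zener parameters were chosen so the 0.5 fs
  time step resolves the coupling regions and per-passage transfer is
  large (diabatic passage probability ≈ 0.9).

## Phase correction

Adiabatic wavefunctions are defined only up to a sign per state, so
off-diagonal properties of neighbouring geometries can differ by random
signs and cannot be fit by a smooth regressor.  The correction tracks
signs from one reference record to every other record: the overlap matrix
S = U_a^T U_b between the eigenvector sets of two geometries has diagonal
entries near ±1 when the electronic character is unchanged; state k is
*decided* with sign(S_kk) when |S_kk| ≥ 0.5 (default).  If any state is
undecided — e.g. across an avoided crossing, where the character rotates —
the straight-line path between the geometries is bisected recursively
(default depth ≤ 10) and per-segment signs chain by elementwise product;
any random sign of an intermediate evaluation appears in two adjacent
segments and cancels.  Off-diagonal element (i, j) is multiplied by
p_i·p_j; diagonal observables are untouched (the sign enters squared).

Two consequences worth knowing:

* The "deterministic" convention of making each eigenvector's largest
  component positive is itself discontinuous exactly at avoided crossings
  (the leading component switches there).  The package therefore treats a
  *tracked* run — correction applied to a sign-deterministic provider — as
  the smooth reference curve; a corrected randomized run reproduces it up
  to one global sign per state pair.
* Around a conical intersection the sign acquired along a path is path
  dependent (geometric phase).  Straight-line tracking ignores this; it is
  an accepted approximation, adequate for training-set construction, and
  no seam-aware path logic is attempted.

## Neural-network potentials

The descriptor is the vector of inverse pair distances 1/r_ab (fixed
lexicographic order), giving exact translation and rotation invariance;
its Jacobian ∂D/∂R is analytic.  One feed-forward network with a shared
trunk (default 2 × 50 shifted-softplus units; the activation must be
smooth because forces are derivatives) carries heads for all state
energies, NAC-vector coefficients, dipole components and optional SOCs.

Forces are never a separate head: G_i = (∂E_i/∂D)(∂D/∂R) is the exact
derivative of the predicted energy, evaluated analytically.  This makes
the force field conservative by construction — closed-loop work vanishes
and surface-hopping total energy is conserved to the Verlet error — and
the force loss is computed through the same expression during training.
The implementation builds the energy-head input-Jacobian symbolically
inside a small reverse-mode tape, so the combined energy+force+coupling
loss is minimized with ordinary first-order backpropagation (Adam,
full-batch, early stopping on validation loss with best-weights restore).

NAC vectors are predicted *covariantly*: the network outputs expansion
coefficients c_k per state pair and the vector is assembled as
d_ij(R) = Σ_k c_k(D) ∂D_k/∂R.  Since ∂D_k/∂R rotates with the molecule,
predicted couplings stay consistent under rigid motion, which matters for
trajectories that rotate.  Signed couplings are learned directly (not
absolute values — the sign enters the hopping flux).  Dipole heads
predict lab-frame components; dipoles are trained and carried along but
not consumed by the dynamics, and their frame non-invariance is a known
limitation.  Inputs are z-scored with training-set statistics; energy and
dipole heads are de-standardized with per-output mean/std; NAC coefficient
heads are scaled by (std of NAC targets)/(RMS of the descriptor Jacobian)
so head outputs are O(1) — without this the coupling heads are fragile to
initialization where couplings spike.

Hyperparameters (width, depth, learning rate, epochs, loss weights:
energy 1.0, force 1.0, NAC 0.1, dipole 0.1, SOC 0.1) are configurable and
searchable by seeded random grid search ranked energy-first on validation
RMSE.  Because the surrogate is smooth everywhere it cannot reproduce the
conical cusp: the two fitted states retain a small positive minimum gap at
the seam, quantified below.

## Surface hopping

Nuclei follow velocity-Verlet on the active adiabatic surface (default
dt = 0.5 fs).  Electronic coefficients obey
iċ_i = E_i c_i − i Σ_j (v·d_ij) c_j and are propagated by the exact
matrix exponential over 20 substeps per nuclear step with linear
interpolation of E and v·d, preserving the norm to machine precision.
Hop probabilities are the fewest-switches flux
g_{a→j} = max(0, 2 dt (v·d_aj) Re[c_a* c_j] / |c_a|²), clipped to [0, 1]
and renormalized if their sum exceeds one.  An accepted hop rescales the
full velocity vector (optionally only the component along the NAC) to
conserve total energy; energetically forbidden hops are logged as
frustrated with velocities unchanged.  Along a trajectory the electronic
sign convention is kept continuous step-to-step (eigenvector-overlap
alignment for model providers; NAC-continuity alignment otherwise).
Energy-based decoherence damping is available but off by default, which
reproduces plain fewest-switches.  Populations are reported classically
(active-state fractions over the ensemble); quantum |c_i|² are logged per
trajectory.  Trajectories are bit-reproducible given seed, step and
source; a mid-run provider failure truncates the trajectory rather than
discarding it.

## Adaptive sampling

Two or more networks trained on the same training set (one shared split,
different initialization seeds) form the ensemble; the RMSE between
member predictions, pooled over a property's components, is the error
signal.  A trajectory step whose disagreement exceeds any property's
threshold hands its geometry to the reference provider; the new record is
phase-corrected against the training set's reference record, appended,
and all members are retrained.  Each pre-freeze trigger also multiplies
the thresholds by 0.95, so the acceptance criterion tightens as coverage
improves; after a configurable amount of *cumulative simulated time*
(default 10 ps) thresholds are kept at their current value.  The freeze
clock is cumulative across trajectories and restarts because individual
short trajectories would otherwise never reach it and the compounding
decay makes the loop diverge: each trigger then makes every future
trigger more likely, regardless of model quality.  Initial thresholds
come either from the members' validation errors times a per-property
safety factor (default 3) or from predefined absolute values; predefined
thresholds are the robust choice when the initial training region is much
easier than the region dynamics will visit, because a validation error
measured on easy data understates the disagreement floor reachable after
expansion.  The loop sweeps its trajectory budget in rounds until one
full pass runs trigger-free, so on completion the final ensemble
reproduces every trajectory within tolerance.

One caution from the bundled experiments: NAC magnitudes diverge near an
intersection seam, so near-seam records carry very large coupling
targets; with the default NAC loss weight these can dominate training and
degrade the energy heads.  The adaptive-sampling demonstration therefore
uses a NAC loss weight of 0.01 and a generous NAC threshold.

## Critical points

State minima are found by L-BFGS on the predicted energy with its
analytic gradient, with rigid translations/rotations projected out of the
reported gradient norm (the descriptor makes them exactly flat).  MECIs
use a gradient-only penalty objective
F = (E_i+E_j)/2 + σ·ΔE²/(|ΔE|+α) with σ₀ = 3.5, α = 0.02 Hartree and
σ-growth ×1.5 until the gap drops below `gap_tol` (1e−4 Hartree on exact
models); |ΔE| keeps the penalty repulsive even if a surrogate's fitted
states cross.  On a smooth surrogate the reachable gap is bounded below,
so convergence is declared on the seam-projected gradient once the gap
stalls below a looser tolerance.  Near-seam gap statistics select
geometries with reference gap < 0.8 eV and report the mean signed
difference (surrogate − reference) with a bootstrap CI; the
smoothing-induced overestimation is an apex effect, so the experiment
samples tightly (σ = 0.01 Bohr) around the MECI — at wider radii flank
points, where a fit may undershoot, can dominate the mean.

## Kinetics

Sequential first-order kinetics A → B → C has the closed form
P_A = e^{−t/τ₁}, P_B = τ₂/(τ₂−τ₁)(e^{−t/τ₂} − e^{−t/τ₁}),
P_C = 1 − P_A − P_B, with the degenerate limit (t/τ)e^{−t/τ} used when
the constants coincide.  Both constants are fit jointly to all three
population curves by least squares in log-τ space, with √count binomial
weights when per-time trajectory counts are available; a fitted constant
above 10⁶ fs is flagged non-decaying.

## Problem sizes and what the experiments show

The bundled validation experiments use: 200-point scans for phase
correction; 60–300-record training sets; 200 surface-hopping trajectories
of 100 fs at dt = 0.5 fs for the surrogate-vs-reference population
comparison (paired seeds, so the comparison isolates surface error plus
chaotic decorrelation rather than independent sampling noise); 10⁴ draws
for hop statistics; 300 near-seam geometries for gap statistics.  These
sizes make every experiment reproducible on one CPU core in minutes.

Passing them shows the pipeline is internally correct on low-dimensional
analytic surfaces with the right topology (avoided crossings, a true
conical seam, sequential decay).  It does not demonstrate accuracy for
real molecules: the models have 1–3 internal degrees of freedom, no
electron correlation structure, scalar SOCs at most, and their NAC spikes
are resolvable at 0.5 fs by construction.  Known limitations: Cartesian
dipole heads are not rotationally covariant; straight-line phase tracking
ignores the geometric phase; capping NACs at quasi-degeneracies biases
trajectories that pass exactly through a seam; and energy conservation at
narrow avoided crossings degrades at 0.5 fs on the steep bundled models
(the conservation experiment uses a hop-free vibrating trajectory, where
the Verlet drift and its dt² scaling are cleanly measurable).
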