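"""Fewest-switches surface-hopping (FSSH) molecular dynamics.

Classical nuclei move on the currently active adiabatic surface by
velocity-Verlet; the electronic wavefunction coefficients c_i are
propagated quantum mechanically with the NAC-velocity coupling,

    i dc_i/dt = E_i c_i - i sum_j (v . d_ij) c_j        (atomic units)

and stochastic hops between surfaces are drawn from the fewest-switches
probabilities

    g_{a->j} = max(0, 2 dt (v . d_aj) Re[c_a^* c_j] / |c_a|^2).

A hop is accepted only if kinetic energy can absorb the potential-energy
jump; velocities are rescaled to conserve total energy, otherwise the hop
is frustrated and logged.  The surface source can be an exact analytic
model, a trained NN potential, or an ensemble of NNs (whose per-step
prediction disagreement feeds adaptive sampling).

Internally everything is in atomic units; the public interface takes
femtoseconds and the default time step is 0.5 fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .core import ElectronicProperties, Geometry, state_pairs
from .errors import InvalidInputError, PhotodynError, TrajectoryAbortError
from .phase import PhaseVector, apply_phase, detect_phases, overlap
from .units import AU_PER_FS, ME_PER_AMU

DEFAULT_DT_FS = 0.5
DEFAULT_SUBSTEPS = 20
COEFF_FLOOR = 1e-12


@dataclass
class HopEvent:
    time_fs: float
    from_state: int
    to_state: int
    probability: float
    random_draw: float
    outcome: str  # "accepted" | "frustrated"
    #: |(KE + E_active) before - after| across an accepted hop, Hartree
    energy_error: float = 0.0


@dataclass
class TrajectoryState:
    """Mutable state of one surface-hopping trajectory (atomic units)."""

    time_fs: float
    geometry: Geometry
    velocities: np.ndarray          # (N, 3), Bohr per atomic time unit
    coefficients: np.ndarray        # (S,) complex
    active: int
    rng: np.random.Generator
    props: ElectronicProperties | None = None
    hops: list = field(default_factory=list)

    @property
    def masses_au(self) -> np.ndarray:
        return self.geometry.masses * ME_PER_AMU

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses_au[:, None] * self.velocities ** 2))


def initialize(geom_0: Geometry, sampling_spec: dict, initial_state: int,
               seed: int = 0) -> TrajectoryState:
    """Initial conditions for one trajectory.

    ``sampling_spec`` is either ``{"kind": "fixed"}`` (geometry as given,
    zero velocities) or ``{"kind": "wigner", "hessian": H}`` drawing
    positions and momenta from the harmonic ground-state Wigner
    distribution of the supplied Cartesian Hessian (translations/rotations
    excluded).  The electronic coefficients start as the basis vector of
    ``initial_state`` — a vertical excitation.
    """
    rng = np.random.default_rng(seed)
    kind = sampling_spec.get("kind", "fixed")
    coords = geom_0.coords.copy()
    vel = np.zeros_like(coords)
    if kind == "fixed":
        if "velocities" in sampling_spec:
            vel = np.asarray(sampling_spec["velocities"], dtype=float).copy()
    elif kind == "wigner":
        hessian = np.asarray(sampling_spec["hessian"], dtype=float)
        n = geom_0.n_atoms
        if hessian.shape != (3 * n, 3 * n):
            raise InvalidInputError("hessian shape does not match geometry")
        m = np.repeat(geom_0.masses * ME_PER_AMU, 3)
        mw = hessian / np.sqrt(np.outer(m, m))
        w2, modes = np.linalg.eigh(mw)
        vib = w2 > 1e-10
        omega = np.sqrt(w2[vib])
        L = modes[:, vib]
        # ground-state Wigner widths in mass-weighted coordinates
        q = rng.normal(0.0, np.sqrt(1.0 / (2.0 * omega)))
        qdot = rng.normal(0.0, np.sqrt(omega / 2.0))
        coords = coords + ((L @ q) / np.sqrt(m)).reshape(n, 3)
        vel = ((L @ qdot) / np.sqrt(m)).reshape(n, 3)
    else:
        raise InvalidInputError(f"unknown sampling kind {kind!r}")
    c = np.zeros(sampling_spec.get("n_states", initial_state + 1), dtype=complex)
    if not (0 <= initial_state < len(c)):
        raise InvalidInputError(f"initial state {initial_state} out of range")
    c[initial_state] = 1.0
    return TrajectoryState(time_fs=0.0, geometry=geom_0.with_coords(coords),
                           velocities=vel, coefficients=c,
                           active=initial_state, rng=rng)


# ---------------------------------------------------------------------------
# Elementary steps
# ---------------------------------------------------------------------------

def nuclear_step_positions(state: TrajectoryState, forces: np.ndarray,
                           dt_au: float) -> tuple[np.ndarray, np.ndarray]:
    """First velocity-Verlet half: returns (new coords, half-step velocities)."""
    if not np.all(np.isfinite(forces)):
        raise TrajectoryAbortError(f"non-finite force at t = {state.time_fs} fs")
    acc = forces / state.masses_au[:, None]
    v_half = state.velocities + 0.5 * dt_au * acc
    coords = state.geometry.coords + dt_au * v_half
    return coords, v_half


def nuclear_step_velocities(v_half: np.ndarray, forces_new: np.ndarray,
                            masses_au: np.ndarray, dt_au: float) -> np.ndarray:
    """Second velocity-Verlet half."""
    if not np.all(np.isfinite(forces_new)):
        raise TrajectoryAbortError("non-finite force after position update")
    return v_half + 0.5 * dt_au * forces_new / masses_au[:, None]


def coupling_matrix(props: ElectronicProperties, velocities: np.ndarray) -> np.ndarray:
    """Antisymmetric matrix of v . d_ij for all state pairs."""
    s = props.n_states
    vd = np.zeros((s, s))
    for p, (i, j) in enumerate(state_pairs(s)):
        val = float(np.sum(velocities * props.nacs[p]))
        vd[i, j] = val
        vd[j, i] = -val
    return vd


def electronic_step(c: np.ndarray, energies_0: np.ndarray, energies_1: np.ndarray,
                    vd_0: np.ndarray, vd_1: np.ndarray, dt_au: float,
                    n_substeps: int = DEFAULT_SUBSTEPS) -> np.ndarray:
    """Unitary propagation of the coefficients across one nuclear step.

    Energies and coupling matrices are interpolated linearly between the
    step endpoints; each substep applies the exact matrix exponential of
    the frozen propagator, so the norm is preserved to machine precision.
    """
    if n_substeps < 1:
        raise InvalidInputError("n_substeps must be >= 1")
    c = np.asarray(c, dtype=complex).copy()
    ddt = dt_au / n_substeps
    for k in range(n_substeps):
        f = (k + 0.5) / n_substeps
        E = (1 - f) * energies_0 + f * energies_1
        vd = (1 - f) * vd_0 + f * vd_1
        A = -1j * np.diag(E) * ddt - vd * ddt
        c = expm(A) @ c
    return c


def hop_probabilities(c: np.ndarray, vd: np.ndarray, dt_au: float,
                      active: int) -> np.ndarray:
    """Fewest-switches hop probabilities out of the active state.

    Probabilities are clipped to [0, 1]; if their sum exceeds 1 they are
    renormalized down.  A numerically depleted active coefficient yields
    all-zero probabilities.
    """
    s = len(c)
    g = np.zeros(s)
    pop_a = float(np.abs(c[active]) ** 2)
    if pop_a < COEFF_FLOOR:
        return g
    for j in range(s):
        if j == active:
            continue
        flux = 2.0 * dt_au * vd[active, j] * np.real(np.conj(c[active]) * c[j])
        g[j] = max(0.0, flux / pop_a)
    g = np.clip(g, 0.0, 1.0)
    total = g.sum()
    if total > 1.0:
        g /= total
    return g


def rescale_velocity(velocities: np.ndarray, masses_au: np.ndarray,
                     delta_e: float, direction: np.ndarray | None = None
                     ) -> np.ndarray | None:
    """Rescale velocities so kinetic energy changes by -delta_e.

    With ``direction=None`` the full velocity vector is scaled uniformly;
    otherwise only the component along ``direction`` (e.g. the NAC vector)
    is adjusted.  Returns None when the kinetic energy along the relevant
    direction cannot absorb the jump (frustrated hop).
    """
    ke = 0.5 * np.sum(masses_au[:, None] * velocities ** 2)
    if direction is None:
        if delta_e > ke:
            return None
        if ke <= 0.0:
            return None if delta_e > 0 else velocities.copy()
        return velocities * np.sqrt(1.0 - delta_e / ke)
    u = direction / np.linalg.norm(direction)
    a = 0.5 * np.sum(masses_au[:, None] * u ** 2)
    b = np.sum(masses_au[:, None] * u * velocities)
    disc = b * b - 4.0 * a * delta_e
    if disc < 0.0:
        return None
    roots = ((-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a))
    gamma = min(roots, key=abs)
    return velocities + gamma * u


def attempt_hop(state: TrajectoryState, probabilities: np.ndarray,
                energies: np.ndarray, props: ElectronicProperties,
                rescale: str = "full") -> HopEvent | None:
    """Draw against the hop probabilities and execute an accepted hop.

    The target is selected by cumulative comparison of a single uniform
    draw; an energetically forbidden hop is recorded as frustrated and the
    active state kept (velocities unchanged).
    """
    r = float(state.rng.uniform())
    cum = 0.0
    target = None
    for j in range(len(probabilities)):
        if j == state.active:
            continue
        cum += probabilities[j]
        if r < cum:
            target = j
            break
    if target is None:
        return None
    delta_e = float(energies[target] - energies[state.active])
    direction = None
    if rescale == "nac":
        direction = props.nac(state.active, target)
    new_v = rescale_velocity(state.velocities, state.masses_au, delta_e, direction)
    if new_v is None:
        event = HopEvent(state.time_fs, state.active, target,
                         probabilities[target], r, "frustrated")
    else:
        from_state = state.active
        e_before = state.kinetic_energy() + float(energies[from_state])
        state.velocities = new_v
        state.active = target
        e_after = state.kinetic_energy() + float(energies[target])
        event = HopEvent(state.time_fs, from_state, target,
                         probabilities[target], r, "accepted",
                         energy_error=abs(e_after - e_before))
    state.hops.append(event)
    return event


def _align_signs(props: ElectronicProperties,
                 prev: ElectronicProperties) -> ElectronicProperties:
    """Keep the electronic sign convention continuous along a trajectory.

    Providers exposing eigenvectors are aligned by the overlap diagonal;
    otherwise per-state signs are inferred from the continuity of the NAC
    vectors (state 0 fixed positive).  The applied per-state phase keeps
    all off-diagonal properties mutually consistent.
    """
    s = props.n_states
    if props.eigenvectors is not None and prev.eigenvectors is not None:
        p = detect_phases(overlap(prev.eigenvectors, props.eigenvectors), 0.0)
        return apply_phase(props, p)
    signs = np.ones(s)
    for j in range(1, s):
        d_new = props.nac(0, j)
        d_old = prev.nac(0, j)
        dot = float(np.sum(d_new * d_old))
        if dot < 0:
            signs[j] = -1.0
    if np.all(signs == 1.0):
        return props
    return apply_phase(props, PhaseVector(signs, np.ones(s, dtype=bool)))


# ---------------------------------------------------------------------------
# Trajectory driver
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Per-step record of one surface-hopping run."""

    times_fs: np.ndarray
    active: np.ndarray
    energies: np.ndarray            # (T, S)
    populations: np.ndarray         # (T, S) quantum |c_i|^2
    positions: np.ndarray           # (T, N, 3)
    velocities: np.ndarray
    total_energy: np.ndarray
    hops: list
    disagreements: list             # [(time_fs, {property: rmse})], ensemble only
    interrupted: dict | None = None  # set when an adaptive threshold fired
    aborted: str | None = None       # error message if propagation failed

    @property
    def n_steps(self) -> int:
        return len(self.times_fs)


def _evaluate(source, geom):
    """Evaluate a surface source; returns (props, disagreement or None)."""
    if hasattr(source, "evaluate_with_disagreement"):
        return source.evaluate_with_disagreement(geom)
    return source.evaluate(geom), None


def run_trajectory(initial: TrajectoryState, source, dt_fs: float = DEFAULT_DT_FS,
                   t_max_fs: float = 100.0, schedule=None,
                   n_substeps: int = DEFAULT_SUBSTEPS, rescale: str = "full",
                   decoherence: float | None = None) -> Trajectory:
    """Propagate one FSSH trajectory to ``t_max_fs``.

    With an ensemble ``source`` and a threshold ``schedule`` attached, the
    run stops early when any property's ensemble disagreement exceeds its
    threshold, returning a trajectory whose ``interrupted`` field carries
    the offending geometry and disagreements (the adaptive-sampling loop
    then takes over).  ``decoherence`` enables energy-based coefficient
    damping with the given constant (Hartree); default off.
    """
    state = initial
    dt_au = dt_fs * AU_PER_FS
    n_steps = int(round(t_max_fs / dt_fs))
    props, disagreement = _evaluate(source, state.geometry)
    state.props = props

    rec: dict[str, list] = {k: [] for k in
                            ("t", "active", "E", "pop", "x", "v", "etot")}
    disagreements = []
    interrupted = None

    def record():
        rec["t"].append(state.time_fs)
        rec["active"].append(state.active)
        rec["E"].append(state.props.energies.copy())
        rec["pop"].append(np.abs(state.coefficients) ** 2)
        rec["x"].append(state.geometry.coords.copy())
        rec["v"].append(state.velocities.copy())
        rec["etot"].append(state.kinetic_energy()
                           + float(state.props.energies[state.active]))

    def check_schedule(dis):
        nonlocal interrupted
        if dis is not None:
            disagreements.append((state.time_fs, dis))
        if schedule is not None and dis is not None:
            violated = schedule.violated(dis)
            if violated:
                interrupted = {"time_fs": state.time_fs,
                               "geometry": state.geometry,
                               "disagreements": dis,
                               "violated": violated}
                return True
        return False

    record()
    stop = check_schedule(disagreement)
    aborted = None
    for _step in range(n_steps):
        if stop:
            break
        try:
            forces = -state.props.gradients[state.active]
            coords_new, v_half = nuclear_step_positions(state, forces, dt_au)
            geom_new = state.geometry.with_coords(coords_new)
            props_new, dis = _evaluate(source, geom_new)
        except PhotodynError as exc:
            # leave a truncated but valid trajectory record
            aborted = str(exc)
            break
        props_new = _align_signs(props_new, state.props)
        forces_new = -props_new.gradients[state.active]
        v_new = nuclear_step_velocities(v_half, forces_new,
                                        state.masses_au, dt_au)

        vd_0 = coupling_matrix(state.props, state.velocities)
        vd_1 = coupling_matrix(props_new, v_new)
        c = electronic_step(state.coefficients, state.props.energies,
                            props_new.energies, vd_0, vd_1, dt_au, n_substeps)

        state.geometry = geom_new
        state.velocities = v_new
        state.coefficients = c
        state.props = props_new
        state.time_fs += dt_fs

        g = hop_probabilities(c, vd_1, dt_au, state.active)
        attempt_hop(state, g, props_new.energies, props_new, rescale)

        if decoherence is not None:
            _apply_decoherence(state, decoherence, dt_au)

        record()
        stop = check_schedule(dis)

    return Trajectory(
        times_fs=np.array(rec["t"]), active=np.array(rec["active"]),
        energies=np.array(rec["E"]), populations=np.array(rec["pop"]),
        positions=np.array(rec["x"]), velocities=np.array(rec["v"]),
        total_energy=np.array(rec["etot"]), hops=state.hops,
        disagreements=disagreements, interrupted=interrupted,
        aborted=aborted)


def _apply_decoherence(state: TrajectoryState, constant: float, dt_au: float):
    """Energy-based decoherence damping of non-active coefficients."""
    ke = state.kinetic_energy()
    E = state.props.energies
    a = state.active
    c = state.coefficients
    for j in range(len(c)):
        if j == a:
            continue
        gap = abs(E[j] - E[a])
        if gap < 1e-12:
            continue
        tau = (1.0 / gap) * (1.0 + constant / max(ke, 1e-12))
        c[j] *= np.exp(-dt_au / tau)
    norm_other = np.sum(np.abs(np.delete(c, a)) ** 2)
    pop_a = 1.0 - norm_other
    if np.abs(c[a]) > 0:
        c[a] *= np.sqrt(max(pop_a, 0.0)) / np.abs(c[a])
    state.coefficients = c


def run_ensemble_of_trajectories(make_initial, source, n_traj: int,
                                 dt_fs: float = DEFAULT_DT_FS,
                                 t_max_fs: float = 100.0, seed: int = 0,
                                 **kwargs) -> tuple[pd.DataFrame, list]:
    """Run ``n_traj`` trajectories and tabulate classical populations.

    ``make_initial(seed)`` must return a fresh TrajectoryState.  The
    population n_i(t) is the fraction of trajectories whose active state is
    i at time t; a per-time trajectory count column is included (shorter,
    aborted trajectories simply stop contributing).
    """
    if n_traj < 1:
        raise InvalidInputError("n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31, size=n_traj)
    trajs = []
    for s in seeds:
        initial = make_initial(int(s))
        trajs.append(run_trajectory(initial, source, dt_fs, t_max_fs, **kwargs))
    n_states = trajs[0].energies.shape[1]
    n_times = max(t.n_steps for t in trajs)
    times = np.arange(n_times) * dt_fs
    counts = np.zeros(n_times, dtype=int)
    pops = np.zeros((n_times, n_states))
    for t in trajs:
        k = t.n_steps
        counts[:k] += 1
        for i in range(n_states):
            pops[:k, i] += (t.active == i)
    with np.errstate(invalid="ignore"):
        pops = pops / counts[:, None]
    table = pd.DataFrame({"time_fs": times})
    for i in range(n_states):
        table[f"n_{i}"] = pops[:, i]
    table["count"] = counts
    return table, trajs
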