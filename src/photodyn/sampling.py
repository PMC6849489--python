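"""Training-set construction and adaptive sampling.

The initial training set comes from scans along the normal modes of a
reference geometry.  During dynamics, an ensemble of independently seeded
networks trained on the same data provides an error signal: the RMSE
between member predictions of each property is compared to a per-property
threshold.  When any property disagrees too much, the current geometry is
recomputed with the reference provider, phase-corrected against the
training set's reference record, appended, and the ensemble retrained —
the active-learning loop.  While sampling is still running (before the
freeze time) every trigger also tightens all thresholds by a factor of
0.95, so the criterion becomes stricter as the model improves; after the
freeze time (default 10 ps) thresholds are kept at their current value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Geometry
from .dynamics import initialize, run_trajectory
from .errors import InvalidInputError, PhaseTrackingError, PhotodynError
from .io import Dataset, DatasetRecord
from .nn import TrainingSet, train
from .phase import phase_align
from .units import ME_PER_AMU

DECAY_FACTOR = 0.95
FREEZE_TIME_FS = 10_000.0  # 10 ps
SAFETY_FACTOR = 3.0


# ---------------------------------------------------------------------------
# Normal-mode initial set
# ---------------------------------------------------------------------------

def compute_hessian(provider, geom: Geometry, state: int = 0,
                    step: float = 1e-3) -> np.ndarray:
    """Cartesian Hessian of one adiabatic surface by central differences of
    the provider's analytic gradients."""
    n = geom.n_atoms
    H = np.zeros((3 * n, 3 * n))
    for a in range(n):
        for x in range(3):
            cp = geom.coords.copy()
            cp[a, x] += step
            gp = provider.evaluate(geom.with_coords(cp)).gradients[state].ravel()
            cm = geom.coords.copy()
            cm[a, x] -= step
            gm = provider.evaluate(geom.with_coords(cm)).gradients[state].ravel()
            H[3 * a + x] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def normal_modes(geom: Geometry, hessian: np.ndarray,
                 freq_floor: float = 1e-8):
    """Vibrational frequencies and Cartesian mode vectors.

    Diagonalizes the mass-weighted Hessian and drops translations/rotations
    (modes with |omega^2| below the floor) and any imaginary-frequency
    modes.  Returns (omega, modes) with omega in atomic units and modes as
    mass-weighted eigenvectors, shape (3N, n_modes).
    """
    n = geom.n_atoms
    hessian = np.asarray(hessian, dtype=float)
    if hessian.shape != (3 * n, 3 * n):
        raise InvalidInputError("hessian shape does not match geometry")
    m = np.repeat(geom.masses * ME_PER_AMU, 3)
    mw = hessian / np.sqrt(np.outer(m, m))
    w2, vecs = np.linalg.eigh(mw)
    keep = w2 > freq_floor
    if not np.any(keep):
        raise InvalidInputError("no vibrational modes with positive frequency")
    return np.sqrt(w2[keep]), vecs[:, keep]


def normal_mode_scan(geom_eq: Geometry, hessian: np.ndarray,
                     displacement_grid) -> list[Geometry]:
    """Geometries displaced along each vibrational normal mode.

    Displacement amplitudes are dimensionless: amplitude 1 moves one
    harmonic ground-state width sqrt(hbar/omega) along the mode in
    mass-weighted coordinates.  Amplitude 0 contributes the equilibrium
    geometry once (deduplicated).
    """
    omega, modes = normal_modes(geom_eq, hessian)
    m = np.repeat(geom_eq.masses * ME_PER_AMU, 3)
    geoms = []
    seen_equilibrium = False
    for k in range(modes.shape[1]):
        width = 1.0 / np.sqrt(omega[k])
        for a in displacement_grid:
            if a == 0:
                if not seen_equilibrium:
                    geoms.append(geom_eq)
                    seen_equilibrium = True
                continue
            dx = (modes[:, k] * a * width) / np.sqrt(m)
            geoms.append(geom_eq.with_coords(
                geom_eq.coords + dx.reshape(-1, 3)))
    return geoms


# ---------------------------------------------------------------------------
# Ensemble disagreement
# ---------------------------------------------------------------------------

class Ensemble:
    """Two or more networks trained on the same data with different seeds.

    Acts as a surface source for dynamics: the prediction used for
    propagation is the member mean, and every evaluation also yields the
    per-property RMSE between members (the adaptive-sampling error signal).
    """

    def __init__(self, members):
        if len(members) < 2:
            raise InvalidInputError("an ensemble needs at least 2 members")
        self.members = list(members)

    @property
    def n_states(self):
        return self.members[0].n_states

    @property
    def atom_labels(self):
        return self.members[0].atom_labels

    @property
    def masses(self):
        return self.members[0].masses

    def evaluate_with_disagreement(self, geom: Geometry):
        preds = [m.predict(geom) for m in self.members]
        mean = preds[0].copy()
        fields = {"energies": True, "gradients": True, "nacs": True,
                  "dipoles": preds[0].dipoles is not None,
                  "socs": preds[0].socs is not None}
        stacked = {}
        for name, present in fields.items():
            if not present:
                continue
            stacked[name] = np.stack([getattr(p, name) for p in preds])
            setattr(mean, name, stacked[name].mean(axis=0))
        dis = {alias: disagreement(stacked[name]) for name, alias in
               (("energies", "energy"), ("gradients", "force"), ("nacs", "nac"),
                ("dipoles", "dipole"), ("socs", "soc")) if name in stacked}
        return mean, dis

    def evaluate(self, geom: Geometry):
        return self.evaluate_with_disagreement(geom)[0]


def disagreement(member_values: np.ndarray) -> float:
    """Pooled RMSE of member predictions about the member mean.

    ``member_values`` stacks one property over members along axis 0; the
    deviation from the mean is pooled over every component of the property.
    """
    member_values = np.asarray(member_values, dtype=float)
    if member_values.shape[0] < 2:
        raise InvalidInputError("disagreement needs >= 2 member predictions")
    dev = member_values - member_values.mean(axis=0, keepdims=True)
    return float(np.sqrt(np.mean(dev ** 2)))


def ensemble_disagreements(predictions) -> dict[str, float]:
    """Per-property disagreement for a list of ElectronicProperties."""
    if len(predictions) < 2:
        raise InvalidInputError("disagreement needs >= 2 member predictions")
    out = {}
    for name, alias in (("energies", "energy"), ("gradients", "force"),
                        ("nacs", "nac"), ("dipoles", "dipole"), ("socs", "soc")):
        vals = [getattr(p, name) for p in predictions]
        if any(v is None for v in vals):
            continue
        shapes = {np.asarray(v).shape for v in vals}
        if len(shapes) != 1:
            raise InvalidInputError(f"mismatched member shapes for {name}")
        out[alias] = disagreement(np.stack(vals))
    return out


# ---------------------------------------------------------------------------
# Threshold schedule
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSchedule:
    """Per-property RMSE thresholds with multiplicative decay and a freeze.

    After ``freeze_time_fs`` of simulated time a trigger still demands
    retraining but no longer tightens the thresholds.
    """

    thresholds: dict
    decay: float = DECAY_FACTOR
    freeze_time_fs: float = FREEZE_TIME_FS
    decay_all: bool = True  # decay every property's threshold on a trigger
    history: list = field(default_factory=list)

    def __post_init__(self):
        for prop, theta in self.thresholds.items():
            if theta <= 0:
                raise InvalidInputError(f"threshold for {prop} must be positive")

    @classmethod
    def from_ensemble(cls, ensemble: Ensemble,
                      safety_factor=SAFETY_FACTOR, **kw):
        """Initial thresholds from validation errors: the worst member
        validation RMSE per property, times a safety factor.

        ``safety_factor`` may be a scalar or a per-property mapping; a
        larger factor is appropriate for properties whose magnitude varies
        strongly over conformational space (NACs diverge near intersection
        seams, so their far-from-seam validation error understates the
        tolerable disagreement there).
        """
        props = ensemble.members[0].val_rmse.keys()
        if not isinstance(safety_factor, dict):
            safety_factor = {p: safety_factor for p in props}
        thresholds = {
            p: safety_factor.get(p, SAFETY_FACTOR)
            * max(m.val_rmse[p] for m in ensemble.members)
            for p in props}
        return cls(thresholds, **kw)

    def violated(self, disagreements: dict) -> list[str]:
        return [p for p, theta in self.thresholds.items()
                if p in disagreements and disagreements[p] > theta]

    def check_and_adapt(self, disagreements: dict, sim_time_fs: float):
        """Compare disagreements to thresholds; decay on a pre-freeze trigger.

        Returns "trusted" or ("retrain_needed", violated property list).
        """
        violated = self.violated(disagreements)
        if not violated:
            self.history.append((sim_time_fs, None, dict(self.thresholds), False))
            return "trusted", []
        if sim_time_fs < self.freeze_time_fs:
            targets = self.thresholds if self.decay_all else violated
            for p in list(targets):
                self.thresholds[p] *= self.decay
        self.history.append((sim_time_fs, tuple(violated),
                             dict(self.thresholds), True))
        return "retrain_needed", violated


# ---------------------------------------------------------------------------
# Adaptive-sampling loop
# ---------------------------------------------------------------------------

@dataclass
class SamplingConfig:
    n_members: int = 2
    n_trajectories: int = 5
    safety_factor: float | dict = SAFETY_FACTOR
    #: predefined absolute thresholds per property; when set they are used
    #: directly instead of the validation-error-based initialization
    thresholds: dict | None = None
    decay: float = DECAY_FACTOR
    freeze_time_fs: float = FREEZE_TIME_FS
    restart_on_trigger: bool = True   # discard and restart the trajectory
    max_expansions: int = 200
    #: repeat full passes over the trajectory budget until one pass runs
    #: trigger-free (bounded by this many passes)
    max_rounds: int = 5
    val_fraction: float = 0.15


def _train_ensemble(dataset, hyperparams, n_members, val_fraction, rng):
    # members share one train/validation split (the same training set) and
    # differ only in their initialization seed
    ts = TrainingSet.random_split(dataset, val_fraction,
                                  seed=int(rng.integers(2 ** 31)))
    return Ensemble([train(ts, hyperparams, seed=int(rng.integers(2 ** 31)))
                     for _ in range(n_members)])


def adaptive_run(initial_dataset: Dataset, provider, dynamics_config: dict,
                 sampling_config: SamplingConfig | None = None,
                 hyperparams=None, seed: int = 0):
    """Grow a training set by ensemble-disagreement adaptive sampling.

    Repeatedly runs surface-hopping trajectories with the ensemble mean;
    whenever the member disagreement on any property exceeds its threshold
    the offending geometry is recomputed with the reference provider,
    phase-corrected against the dataset's reference record, appended, and
    the ensemble retrained.  Terminates when the configured trajectory
    budget completes (or the expansion budget is exhausted).

    Returns (final dataset, final ensemble, event log, schedule).
    """
    cfg = sampling_config or SamplingConfig()
    rng = np.random.default_rng(seed)
    dataset = initial_dataset.copy()
    ensemble = _train_ensemble(dataset, hyperparams, cfg.n_members,
                               cfg.val_fraction, rng)
    if cfg.thresholds is not None:
        schedule = ThresholdSchedule(dict(cfg.thresholds), decay=cfg.decay,
                                     freeze_time_fs=cfg.freeze_time_fs)
    else:
        schedule = ThresholdSchedule.from_ensemble(
            ensemble, cfg.safety_factor, decay=cfg.decay,
            freeze_time_fs=cfg.freeze_time_fs)
    ref_rec = dataset.records[dataset.phase_reference_index]
    log = []
    n_expansions = 0

    geom_0 = dynamics_config.get("geom_0") or provider.reference_geometry()
    sampling_spec = dict(dynamics_config.get("sampling_spec", {"kind": "fixed"}))
    sampling_spec.setdefault("n_states", provider.n_states)
    initial_state = dynamics_config.get("initial_state", provider.n_states - 1)
    dt_fs = dynamics_config.get("dt_fs", 0.5)
    t_max_fs = dynamics_config.get("t_max_fs", 100.0)

    traj_seeds = [int(rng.integers(2 ** 31)) for _ in range(cfg.n_trajectories)]
    # the freeze clock runs on cumulative simulated time over the whole run:
    # thresholds decay only during the early sampling phase and are then kept
    cumulative_time_fs = 0.0
    # rounds: sweep the whole trajectory budget repeatedly until one pass
    # completes without any threshold trigger (the ensemble then reproduces
    # every trajectory within tolerance), or budgets run out
    for i_round in range(cfg.max_rounds):
        round_triggers = 0
        for i_traj, traj_seed in enumerate(traj_seeds):
            start_geom = geom_0
            while True:
                state = initialize(start_geom, sampling_spec, initial_state,
                                   traj_seed)
                traj = run_trajectory(state, ensemble, dt_fs, t_max_fs,
                                      schedule=schedule)
                cumulative_time_fs += float(traj.times_fs[-1])
                if traj.interrupted is None:
                    log.append({"event": "trajectory_done", "round": i_round,
                                "trajectory": i_traj, "seed": traj_seed,
                                "time_fs": float(traj.times_fs[-1])})
                    break
                if n_expansions >= cfg.max_expansions:
                    log.append({"event": "expansion_budget_exhausted",
                                "round": i_round, "trajectory": i_traj})
                    break
                info = traj.interrupted
                sim_time = cumulative_time_fs
                decision, violated = schedule.check_and_adapt(
                    info["disagreements"], sim_time)
                geom_bad = info["geometry"]
                try:
                    props, phase = phase_align(
                        provider, ref_rec.geometry, geom_bad,
                        eigvecs_ref=ref_rec.properties.eigenvectors)
                except (PhaseTrackingError, PhotodynError) as exc:
                    log.append({"event": "point_skipped", "round": i_round,
                                "trajectory": i_traj, "time_fs": sim_time,
                                "error": str(exc)})
                    break
                dataset.append(DatasetRecord(geom_bad, props,
                                             phase.signs.copy(), "adaptive"))
                n_expansions += 1
                round_triggers += 1
                ensemble = _train_ensemble(dataset, hyperparams, cfg.n_members,
                                           cfg.val_fraction, rng)
                log.append({"event": "point_added", "round": i_round,
                            "trajectory": i_traj, "seed": traj_seed,
                            "time_fs": sim_time, "violated": violated,
                            "n_records": len(dataset),
                            "thresholds": dict(schedule.thresholds)})
                if not cfg.restart_on_trigger:
                    start_geom = geom_bad
                # restart (default): same seed, fresh initial conditions
        if round_triggers == 0 or n_expansions >= cfg.max_expansions:
            break
    return dataset, ensemble, log, schedule
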