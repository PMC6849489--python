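"""End-to-end validation experiments on the bundled analytic models.

Each function runs one self-contained experiment of the pipeline —
phase correction, analytic-force accuracy, energy conservation,
NN-vs-exact dynamics, adaptive sampling, hop-statistics consistency,
conical-intersection optimization, kinetic-constant recovery — and
returns a dictionary of measured quantities.  The same experiments back
the validation test suite and the reproduction script, so every reported
number is recomputed from scratch by running the package.

All randomness is controlled by the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .analysis import fit_time_constants, population_mae, sequential_populations
from .critical import MeciParams, gap_statistics, optimize_meci, optimize_minimum
from .dynamics import (attempt_hop, hop_probabilities, initialize,
                       run_ensemble_of_trajectories, run_trajectory)
from .io import Dataset
from .models import (AvoidedCrossingModel, ConicalIntersectionModel,
                     SequentialDecayModel)
from .nn import Hyperparams, TrainingSet, train
from .phase import phase_correct_dataset
from .sampling import (SamplingConfig, adaptive_run, compute_hessian,
                       normal_mode_scan)
from .units import AU_PER_FS


def _diatomic_scan(model, r_values):
    return [model.make_geometry(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
            for r in r_values]


# ---------------------------------------------------------------------------
# Phase correction
# ---------------------------------------------------------------------------

def phase_correction_experiment(seed: int = 0, n_points: int = 200) -> dict:
    """Smooth scan with randomized eigenvector signs: count raw NAC sign
    discontinuities and measure the corrected curve against the tracked
    deterministic-sign oracle (they must agree up to one global sign)."""
    rs = np.linspace(2.0, 4.5, n_points)
    det = AvoidedCrossingModel()
    rnd = AvoidedCrossingModel(randomize_phase=True, rng_seed=seed)
    geoms = _diatomic_scan(det, rs)
    ds_rnd = Dataset.from_provider(rnd, geoms)
    nac_raw = np.array([r.properties.nacs[0, 0, 0] for r in ds_rnd.records])
    # a sign discontinuity: consecutive points with opposite sign and a jump
    # far exceeding the smooth curve's step-to-step change
    jumps = int(np.sum((np.sign(nac_raw[:-1]) != np.sign(nac_raw[1:]))
                       & (np.abs(np.diff(nac_raw))
                          > 3 * np.median(np.abs(np.diff(np.abs(nac_raw)))))))
    corr = phase_correct_dataset(ds_rnd, 0, rnd)
    oracle = phase_correct_dataset(Dataset.from_provider(det, geoms), 0, det)
    nac_c = np.array([r.properties.nacs[0, 0, 0] for r in corr.records])
    nac_o = np.array([r.properties.nacs[0, 0, 0] for r in oracle.records])
    dev = float(min(np.abs(nac_c - nac_o).max(), np.abs(nac_c + nac_o).max()))
    return {"n": n_points, "raw_sign_discontinuities": jumps,
            "corrected_max_deviation": dev}


# ---------------------------------------------------------------------------
# Trained surrogates (shared by several experiments)
# ---------------------------------------------------------------------------

def train_avoided_crossing_nn(seed: int = 0):
    model = AvoidedCrossingModel()
    ds = Dataset.from_provider(model, _diatomic_scan(model,
                                                     np.linspace(1.6, 4.6, 60)))
    ds = phase_correct_dataset(ds, 0, model)
    ts = TrainingSet.random_split(ds, 0.15, seed=seed)
    return train(ts, Hyperparams(epochs=2000), seed=seed + 1)


def train_conical_intersection_nn(seed: int = 0, n_points: int = 220,
                                  spread: float = 0.25):
    model = ConicalIntersectionModel()
    rng = np.random.default_rng(seed)
    base = model.meci_geometry().coords
    geoms = [model.make_geometry(base + rng.normal(0, spread, base.shape))
             for _ in range(n_points)]
    ds = Dataset.from_provider(model, geoms)
    ts = TrainingSet.random_split(ds, 0.15, seed=seed)
    return train(ts, Hyperparams(hidden=(64, 64), epochs=4000, eval_every=50,
                                 patience=20, learning_rate=3e-3), seed=seed + 1)


def train_sequential_decay_nn(seed: int = 0):
    """Surrogate for the three-state cascade model.

    The scan is densest around the two diabatic crossings where the NAC
    spikes live.  Training restarts from two initializations and keeps the
    one with the better validation error — the coupling heads occasionally
    hit a poor optimization basin from an unlucky init.
    """
    model = SequentialDecayModel()
    rs = np.unique(np.concatenate([np.linspace(1.0, 7.5, 200),
                                   np.linspace(2.5, 4.0, 100)]))
    ds = Dataset.from_provider(model, _diatomic_scan(model, rs))
    # the raw eigenvector sign convention flips at the avoided crossings;
    # without phase correction the coupling targets are unlearnable
    ds = phase_correct_dataset(ds, 0, model)
    ts = TrainingSet.random_split(ds, 0.1, seed=seed)
    hp = Hyperparams(hidden=(80, 80), epochs=10000, eval_every=100,
                     patience=20, learning_rate=3e-3)

    def score(m):
        return sum(hp.loss_weights.get(k, 0.0) * v ** 2
                   for k, v in m.val_rmse.items())

    candidates = [train(ts, hp, seed=seed + offset) for offset in (1, 101)]
    return min(candidates, key=score)


# ---------------------------------------------------------------------------
# Analytic forces
# ---------------------------------------------------------------------------

def force_accuracy_experiment(seed: int = 0, n_geometries: int = 100,
                              nn_model=None) -> dict:
    """NN forces versus centered finite differences of the predicted energy
    at random geometries, plus net-force and net-torque residuals."""
    model = ConicalIntersectionModel()
    nn = nn_model if nn_model is not None else train_conical_intersection_nn(seed)
    rng = np.random.default_rng(seed + 7)
    base = model.meci_geometry().coords
    h = 1e-5
    max_rel = max_net_f = max_torque = 0.0
    for _ in range(n_geometries):
        geom = model.make_geometry(base + rng.normal(0, 0.25, base.shape))
        grads = nn.analytic_forces(geom)
        fd = np.zeros_like(grads)
        for a in range(3):
            for x in range(3):
                cp = geom.coords.copy()
                cp[a, x] += h
                cm = geom.coords.copy()
                cm[a, x] -= h
                fd[:, a, x] = (nn.predict(geom.with_coords(cp)).energies
                               - nn.predict(geom.with_coords(cm)).energies) / (2 * h)
        rel = np.abs(grads - fd).max() / max(np.abs(fd).max(), 1e-12)
        max_rel = max(max_rel, float(rel))
        for s in range(2):
            f = -grads[s]
            max_net_f = max(max_net_f, float(np.abs(f.sum(axis=0)).max()))
            torque = np.cross(geom.coords - geom.coords.mean(axis=0), f).sum(axis=0)
            max_torque = max(max_torque, float(np.abs(torque).max()))
    return {"n": n_geometries, "max_relative_fd_error": max_rel,
            "max_net_force": max_net_f, "max_net_torque": max_torque}


# ---------------------------------------------------------------------------
# Energy conservation
# ---------------------------------------------------------------------------

def energy_conservation_experiment(seed: int = 0, nn_model=None) -> dict:
    """Total-energy drift of a hop-free NN-driven trajectory over 100 fs at
    dt = 0.5 fs, and the drift ratio when the step is halved (Verlet is
    second order, so the ratio should be about 4)."""
    model = AvoidedCrossingModel()
    nn = nn_model if nn_model is not None else train_avoided_crossing_nn(seed)
    g0 = model.reference_geometry()
    hess = compute_hessian(model, g0, state=0)
    spec = {"kind": "wigner", "hessian": hess, "n_states": 2}
    drifts = {}
    for dt in (0.5, 0.25):
        st = initialize(g0, spec, 0, seed=seed + 11)
        traj = run_trajectory(st, nn, dt_fs=dt, t_max_fs=100.0)
        accepted = [h for h in traj.hops if h.outcome == "accepted"]
        if accepted:  # measure between hops only
            bounds = [0] + [int(round(h.time_fs / dt)) for h in accepted] \
                + [traj.n_steps]
            drift = max((traj.total_energy[a + 1:b].max()
                         - traj.total_energy[a + 1:b].min())
                        for a, b in zip(bounds[:-1], bounds[1:]) if b - a > 2)
        else:
            drift = traj.total_energy.max() - traj.total_energy.min()
        drifts[dt] = float(drift)
    return {"n": int(100.0 / 0.5),
            "drift_100fs_dt05_hartree": drifts[0.5],
            "drift_100fs_dt025_hartree": drifts[0.25],
            "drift_ratio_dt_halved": drifts[0.5] / drifts[0.25]}


# ---------------------------------------------------------------------------
# NN-driven vs exact-model-driven populations
# ---------------------------------------------------------------------------

def oracle_equivalence_experiment(seed: int = 0, n_traj: int = 200,
                                  nn_model=None) -> dict:
    """Surface-hopping population dynamics on the three-state cascade model:
    the same trajectory ensemble (paired seeds) driven by the exact model
    and by its NN surrogate, compared as the MAE over all (time, state)
    population cells over 100 fs."""
    model = SequentialDecayModel()
    nn = nn_model if nn_model is not None else train_sequential_decay_nn(seed)
    g0 = model.reference_geometry()
    hess = compute_hessian(model, g0, state=0)
    spec = {"kind": "wigner", "hessian": hess, "n_states": 3}

    def make_initial(s):
        return initialize(g0, spec, 2, s)

    tab_exact, _ = run_ensemble_of_trajectories(make_initial, model,
                                                n_traj=n_traj, seed=seed + 17)
    tab_nn, _ = run_ensemble_of_trajectories(make_initial, nn,
                                             n_traj=n_traj, seed=seed + 17)
    mae = population_mae(tab_exact, tab_nn)
    return {"n": n_traj, "population_mae": float(mae),
            "tables": (tab_exact, tab_nn)}


# ---------------------------------------------------------------------------
# Adaptive sampling
# ---------------------------------------------------------------------------

def adaptive_sampling_experiment(seed: int = 0) -> dict:
    """Active-learning demonstration on the conical-intersection model.

    The initial training set covers the ground-state minimum region; the
    dynamics start between that minimum and the seam on the upper state, so
    expansion points should concentrate near the seam.  Afterwards the
    run's own trajectories are replayed with the final ensemble and the
    fraction of steps whose disagreement still exceeds the final thresholds
    is measured, and the recorded threshold sequence is compared with the
    exact geometric decay law theta0 * 0.95^k.
    """
    model = ConicalIntersectionModel()
    gmin = optimize_minimum(model, 0, model.reference_geometry(),
                            tol=1e-8).geometry
    hess = compute_hessian(model, gmin, state=0)
    geoms = normal_mode_scan(gmin, hess, [-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0])
    rng = np.random.default_rng(seed)
    extra = [gmin.with_coords(gmin.coords + rng.normal(0, 0.2, gmin.coords.shape))
             for _ in range(30)]
    ds = Dataset.from_provider(model, geoms + extra, source="normal_mode")
    meci = model.meci_geometry()
    gfc = meci.with_coords(meci.coords + 0.35 * (gmin.coords - meci.coords))
    hp = Hyperparams(epochs=800, eval_every=50, patience=8,
                     loss_weights={"energy": 1.0, "force": 1.0, "nac": 0.01,
                                   "dipole": 0.1, "soc": 0.1})
    cfg = SamplingConfig(n_trajectories=6,
                         thresholds={"energy": 3e-3, "force": 1e-2, "nac": 5.0},
                         max_expansions=40, freeze_time_fs=40.0, max_rounds=6)
    dyn = {"geom_0": gfc, "t_max_fs": 20.0, "initial_state": 1,
           "sampling_spec": {"kind": "fixed", "n_states": 2}}
    final, ensemble, log, schedule = adaptive_run(ds, model, dyn, cfg, hp,
                                                  seed=seed + 23)

    # threshold sequence versus the exact geometric law
    theta0 = {"energy": 3e-3, "force": 1e-2, "nac": 5.0}
    max_rel_dev = 0.0
    k = 0
    for entry in schedule.history:
        _, _, thresholds, triggered = entry
        if triggered and entry[0] < cfg.freeze_time_fs:
            k += 1
        for prop, theta in thresholds.items():
            expected = theta0[prop] * 0.95 ** k
            max_rel_dev = max(max_rel_dev, abs(theta - expected) / expected)

    def seam_distance(geom):
        c = geom.coords
        return float(np.hypot(np.linalg.norm(c[0] - c[1]) - model.a,
                              np.linalg.norm(c[0] - c[2]) - model.b))

    d_init = [seam_distance(r.geometry) for r in final.records
              if r.source == "normal_mode"]
    d_added = [seam_distance(r.geometry) for r in final.records
               if r.source == "adaptive"]

    seeds = sorted({e["seed"] for e in log if "seed" in e})
    violations = steps = 0
    for s in seeds:
        st = initialize(gfc, dyn["sampling_spec"], 1, seed=s)
        traj = run_trajectory(st, ensemble, dt_fs=0.5, t_max_fs=20.0)
        for _, dis in traj.disagreements:
            steps += 1
            if schedule.violated(dis):
                violations += 1
    return {"n": len(final),
            "n_added": len(d_added),
            "threshold_sequence_max_rel_dev": float(max_rel_dev),
            "replay_violation_fraction": violations / max(steps, 1),
            "median_seam_distance_initial": float(np.median(d_init)),
            "median_seam_distance_added":
                float(np.median(d_added)) if d_added else float("nan"),
            "completed": all(e["event"] != "expansion_budget_exhausted"
                             for e in log)}


# ---------------------------------------------------------------------------
# Fewest-switches internal consistency
# ---------------------------------------------------------------------------

def hop_flux_experiment(seed: int = 0, n_draws: int = 10_000) -> dict:
    """With frozen coefficients and couplings, the realized hop fraction
    over many independent draws must match the fewest-switches probability
    within binomial error; reported as a z-score."""
    model = SequentialDecayModel()
    g = model.reference_geometry()
    dt_au = 0.5 * AU_PER_FS
    c = np.array([np.sqrt(0.2), np.sqrt(0.3), np.sqrt(0.5)], dtype=complex)
    vd = np.zeros((3, 3))
    vd[2, 1], vd[1, 2] = 4e-4, -4e-4
    vd[2, 0], vd[0, 2] = 1e-4, -1e-4
    g_expected = hop_probabilities(c, vd, dt_au, active=2)
    props = model.evaluate(g)
    hops = np.zeros(3)
    frustrated = 0
    rng_master = np.random.default_rng(seed + 29)
    for k in range(n_draws):
        st = initialize(g, {"kind": "fixed", "n_states": 3}, 2,
                        seed=int(rng_master.integers(2 ** 31)))
        st.velocities = np.array([[0.01, 0, 0], [-0.01, 0, 0]])  # ample KE
        st.props = props
        event = attempt_hop(st, g_expected, props.energies, props)
        if event is not None:
            if event.outcome == "accepted":
                hops[event.to_state] += 1
            else:
                frustrated += 1
    p = float(g_expected.sum())
    realized = float(hops.sum() / n_draws)
    sigma = np.sqrt(p * (1 - p) / n_draws)
    return {"n": n_draws, "expected_hop_fraction": p,
            "realized_hop_fraction": realized,
            "z_score": (realized - p) / sigma,
            "frustrated": frustrated}


# ---------------------------------------------------------------------------
# Conical-intersection optimization
# ---------------------------------------------------------------------------

def _grid_seam_minimum(model, n=161, span=0.4):
    """Vectorized brute-force oracle over internal displacements (x, y, z)."""
    s = np.linspace(-span, span, n)
    X, Y, Z = np.meshgrid(s, s, s, indexing="ij")
    gap = 2.0 * np.hypot(model.kappa * X, model.lam * Y)
    mean = 0.5 * model.k * (X ** 2 + Y ** 2 + Z ** 2)
    mean = np.where(gap <= 1e-3, mean, np.inf)
    idx = np.unravel_index(np.argmin(mean), mean.shape)
    return np.array([X[idx], Y[idx], Z[idx]])


def meci_experiment(seed: int = 0, nn_model=None, n_near_seam: int = 300) -> dict:
    """MECI optimization on the exact model (versus a dense grid oracle)
    and on its NN surrogate, plus near-seam gap statistics quantifying the
    surrogate's smoothing-induced gap overestimation."""
    model = ConicalIntersectionModel()
    start = model.reference_geometry()
    res = optimize_meci(model, (0, 1), start)
    xyz_oracle = _grid_seam_minimum(model)
    c = res.geometry.coords
    disp = np.array([np.linalg.norm(c[0] - c[1]) - model.a,
                     np.linalg.norm(c[0] - c[2]) - model.b,
                     np.linalg.norm(c[1] - c[2]) - model.c])
    distance = float(np.abs(disp - xyz_oracle).max())
    gap_exact = float(res.energies[1] - res.energies[0])

    nn = nn_model if nn_model is not None else train_conical_intersection_nn(seed)
    params = MeciParams(gap_tol=2e-2)
    res_nn = optimize_meci(nn, (0, 1), start, params)
    gap_nn = float(res_nn.energies[1] - res_nn.energies[0])

    # sample tightly around the seam: the smoothing-induced overestimation
    # is an apex effect, washed out when flank points dominate
    rng = np.random.default_rng(seed + 31)
    base = model.meci_geometry().coords
    geoms = [model.make_geometry(base + rng.normal(0, 0.01, base.shape))
             for _ in range(n_near_seam)]
    stats = gap_statistics(geoms, model, nn, (0, 1), gap_cut_ev=0.8,
                           seed=seed + 37)
    return {"n": n_near_seam,
            "meci_distance_to_grid_bohr": distance,
            "gap_exact_hartree": gap_exact,
            "gap_nn_hartree": gap_nn,
            "gap_tol_hartree": params.gap_tol,
            "near_seam_gap_overestimation_ev": stats.mean_difference,
            "gap_ci_low_ev": stats.ci_low,
            "gap_ci_high_ev": stats.ci_high,
            "near_seam_count": stats.count}


# ---------------------------------------------------------------------------
# Time-constant recovery
# ---------------------------------------------------------------------------

def time_constant_experiment(seed: int = 0, tau1: float = 25.0,
                             tau2: float = 52.0, n_traj: int = 200) -> dict:
    """Recover sequential-kinetics time constants from noiseless closed-form
    populations and from a binomially sampled 200-trajectory realization."""
    import pandas as pd

    t = np.arange(0.0, 200.5, 0.5)

    def to_table(pops, count=None):
        df = pd.DataFrame({"time_fs": t})
        df["n_0"] = pops[:, 2]
        df["n_1"] = pops[:, 1]
        df["n_2"] = pops[:, 0]
        if count is not None:
            df["count"] = count
        return df

    fit_clean = fit_time_constants(to_table(sequential_populations(t, tau1, tau2)))

    rng = np.random.default_rng(seed + 41)
    t_hop1 = rng.exponential(tau1, n_traj)
    t_hop2 = t_hop1 + rng.exponential(tau2, n_traj)
    pops = np.empty((len(t), 3))
    for k, tk in enumerate(t):
        a = np.sum(t_hop1 > tk)
        ccount = np.sum(t_hop2 <= tk)
        pops[k] = [a, n_traj - a - ccount, ccount]
    fit_noisy = fit_time_constants(to_table(pops / n_traj,
                                            np.full(len(t), n_traj)))
    return {"n": n_traj,
            "tau1_true_fs": tau1, "tau2_true_fs": tau2,
            "tau1_noiseless_fs": fit_clean.tau1,
            "tau2_noiseless_fs": fit_clean.tau2,
            "tau1_sampled_fs": fit_noisy.tau1,
            "tau2_sampled_fs": fit_noisy.tau2,
            "tau1_sampled_stderr_fs": fit_noisy.tau1_stderr,
            "tau2_sampled_stderr_fs": fit_noisy.tau2_stderr}
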