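"""Population analysis: curve comparison and kinetic time constants.

Surface-hopping populations are classical: n_i(t) is the fraction of
trajectories whose active state is i (quantum |c_i|^2 averages are logged
per trajectory but the classical fractions are the reported observable).
Sequential first-order kinetics A -> B -> C has the closed-form solution

    P_A(t) = exp(-t/tau1)
    P_B(t) = tau2/(tau2 - tau1) * (exp(-t/tau2) - exp(-t/tau1))
    P_C(t) = 1 - P_A - P_B

with the degenerate limit P_B = (t/tau) exp(-t/tau) for tau1 = tau2.  Time
constants are estimated by weighted least squares on all state curves
jointly (binomial weights when trajectory counts are available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConvergenceError, InvalidInputError

#: relative tau difference below which the degenerate branch is used
DEGENERATE_RTOL = 1e-9
#: fitted tau above this (fs) is flagged non-decaying
NON_DECAYING_TAU = 1e6


def population_mae(pop_a: pd.DataFrame, pop_b: pd.DataFrame) -> float:
    """Mean absolute population difference over all (time, state) cells."""
    cols_a = [c for c in pop_a.columns if c.startswith("n_")]
    cols_b = [c for c in pop_b.columns if c.startswith("n_")]
    if cols_a != cols_b:
        raise InvalidInputError("population tables have different state columns")
    ta, tb = pop_a["time_fs"].values, pop_b["time_fs"].values
    if len(ta) != len(tb) or not np.allclose(ta, tb):
        raise InvalidInputError(
            "population tables are on different time grids; resample first "
            "(see resample_populations)")
    return float(np.abs(pop_a[cols_a].values - pop_b[cols_b].values).mean())


def resample_populations(table: pd.DataFrame, times_fs: np.ndarray) -> pd.DataFrame:
    """Linear resampling of a population table onto a new time grid."""
    cols = [c for c in table.columns if c.startswith("n_")]
    out = pd.DataFrame({"time_fs": times_fs})
    for c in cols:
        out[c] = np.interp(times_fs, table["time_fs"].values, table[c].values)
    return out


def sequential_populations(t: np.ndarray, tau1: float, tau2: float) -> np.ndarray:
    """Closed-form A -> B -> C populations, shape (len(t), 3), columns (A, B, C)."""
    t = np.asarray(t, dtype=float)
    pa = np.exp(-t / tau1)
    if abs(tau2 - tau1) <= DEGENERATE_RTOL * max(tau1, tau2):
        pb = (t / tau1) * np.exp(-t / tau1)
    else:
        pb = tau2 / (tau2 - tau1) * (np.exp(-t / tau2) - np.exp(-t / tau1))
    pc = 1.0 - pa - pb
    return np.column_stack([pa, pb, pc])


@dataclass
class TimeConstantFit:
    tau1: float
    tau2: float
    tau1_stderr: float
    tau2_stderr: float
    residual_rms: float
    non_decaying: bool


def fit_time_constants(populations: pd.DataFrame,
                       scheme: str = "A->B->C",
                       initial_state: int | None = None,
                       tau_guess: tuple[float, float] = (20.0, 50.0)
                       ) -> TimeConstantFit:
    """Fit sequential-kinetics time constants to a 3-state population table.

    The table's highest state column is A (the initially populated state),
    the middle B, the lowest C, matching internal-conversion cascades
    S2 -> S1 -> S0.  All three curves are fit jointly; binomial weights
    from the ``count`` column are applied when present.

    Raises
    ------
    ConvergenceError
        If the least-squares fit does not converge; residuals attached.
    """
    if scheme not in ("A->B->C", "S2->S1->S0"):
        raise InvalidInputError(f"unsupported kinetic scheme {scheme!r}")
    cols = sorted([c for c in populations.columns if c.startswith("n_")],
                  key=lambda c: int(c.split("_")[1]))
    if len(cols) != 3:
        raise InvalidInputError("sequential fit needs exactly 3 state columns")
    t = populations["time_fs"].values
    # A = highest state, B = middle, C = ground
    data = populations[[cols[2], cols[1], cols[0]]].values
    if "count" in populations.columns:
        w = np.sqrt(np.maximum(populations["count"].values, 1))[:, None]
    else:
        w = np.ones((len(t), 1))

    def residuals(log_taus):
        # clip keeps the optimizer finite when a curve does not decay at all
        tau1, tau2 = np.exp(np.clip(log_taus, -20.0, 40.0))
        return ((sequential_populations(t, tau1, tau2) - data) * w).ravel()

    res = least_squares(residuals, np.log(tau_guess), method="lm",
                        max_nfev=10000)
    if not res.success:
        raise ConvergenceError(
            f"time-constant fit failed: {res.message}; "
            f"residual RMS {np.sqrt(np.mean(res.fun ** 2)):.3g}")
    tau1, tau2 = np.exp(np.clip(res.x, -20.0, 40.0))
    # standard errors via the Jacobian in log space, delta method
    dof = max(res.fun.size - 2, 1)
    s2 = float(np.sum(res.fun ** 2)) / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.diag(cov)) * np.array([tau1, tau2])
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    non_decaying = bool(tau1 > NON_DECAYING_TAU or tau2 > NON_DECAYING_TAU)
    return TimeConstantFit(float(tau1), float(tau2), float(se[0]), float(se[1]),
                           float(np.sqrt(np.mean(res.fun ** 2))), non_decaying)


def population_report(tables: dict, out_prefix=None, log_time: bool = False):
    """Overlay plot, pairwise MAE matrix and time constants for >= 1 runs.

    ``tables`` maps labels to population DataFrames on a common grid.
    Returns (MAE matrix DataFrame, {label: TimeConstantFit or None});
    writes <prefix>_populations.svg and <prefix>_mae.tsv when a prefix is
    given.
    """
    if not tables:
        raise InvalidInputError("no population tables supplied")
    labels = list(tables)
    mae = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            if a != b:
                mae.loc[a, b] = population_mae(tables[a], tables[b])
    fits = {}
    for label, tab in tables.items():
        cols = [c for c in tab.columns if c.startswith("n_")]
        if len(cols) == 3:
            try:
                fits[label] = fit_time_constants(tab)
            except (ConvergenceError, InvalidInputError):
                fits[label] = None
        else:
            fits[label] = None
    if out_prefix is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        styles = ["-", "--", ":", "-."]
        for k, (label, tab) in enumerate(tables.items()):
            cols = [c for c in tab.columns if c.startswith("n_")]
            for c in cols:
                ax.plot(tab["time_fs"], tab[c], styles[k % 4],
                        label=f"{label} S{c.split('_')[1]}")
        if log_time:
            ax.set_xscale("log")
        ax.set_xlabel("time (fs)")
        ax.set_ylabel("population")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(f"{out_prefix}_populations.svg")
        plt.close(fig)
        mae.to_csv(f"{out_prefix}_mae.tsv", sep="\t")
    return mae, fits
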