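"""Feed-forward neural-network potentials for coupled electronic states.

Geometries enter through the inverse-distance descriptor (translationally
and rotationally invariant); a single multi-layer network with a shared
trunk predicts all adiabatic energies plus coupling, dipole and SOC heads.
Forces are never a separate output: they are the exact analytic derivative
of the energy heads through the descriptor, which makes the predicted
force field conservative and lets surface-hopping dynamics conserve
energy.  The force loss is therefore computed through the same analytic
derivative during training.

NAC vectors are predicted covariantly: the network outputs expansion
coefficients c_k per state pair and the Cartesian vector is assembled as
d_ij(R) = sum_k c_k(D) dD_k/dR.  Because dD_k/dR rotates with the
molecule, predicted couplings stay consistent under rigid rotation —
something raw Cartesian-component heads cannot guarantee.  Dipole heads
predict lab-frame components directly (dipoles are trained and carried
along but not consumed by the dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import autodiff as ad
from .core import ElectronicProperties, Geometry, state_pairs
from .errors import InvalidInputError, TrainingDivergedError

R_MIN = 1e-3  # Bohr; atoms closer than this make 1/r meaningless


# ---------------------------------------------------------------------------
# Inverse-distance descriptor
# ---------------------------------------------------------------------------

def descriptor(geom: Geometry) -> np.ndarray:
    """Vector of pairwise inverse distances 1/r_ab, pairs (a < b) lexicographic."""
    coords = geom.coords
    n = coords.shape[0]
    vals = []
    for a in range(n):
        for b in range(a + 1, n):
            r = np.linalg.norm(coords[a] - coords[b])
            if r < R_MIN:
                raise InvalidInputError(
                    f"atoms {a} and {b} nearly coincident (r = {r:.2e} Bohr)")
            vals.append(1.0 / r)
    return np.array(vals)


def descriptor_jacobian(geom: Geometry) -> np.ndarray:
    """Analytic dD/dR, shape (P, N, 3) with P = N(N-1)/2.

    d(1/r_ab)/dR_a = -(R_a - R_b)/r_ab^3.
    """
    coords = geom.coords
    n = coords.shape[0]
    jac = np.zeros((n * (n - 1) // 2, n, 3))
    k = 0
    for a in range(n):
        for b in range(a + 1, n):
            diff = coords[a] - coords[b]
            r = np.linalg.norm(diff)
            if r < R_MIN:
                raise InvalidInputError(
                    f"atoms {a} and {b} nearly coincident (r = {r:.2e} Bohr)")
            g = -diff / r ** 3
            jac[k, a] = g
            jac[k, b] = -g
            k += 1
    return jac


# ---------------------------------------------------------------------------
# Training-set container
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """A dataset plus disjoint train/validation splits."""

    dataset: object  # io.Dataset
    train_indices: np.ndarray
    val_indices: np.ndarray

    def __post_init__(self):
        if len(self.dataset) == 0:
            raise InvalidInputError("training set is empty")
        if len(self.val_indices) == 0:
            raise InvalidInputError("validation split is empty")
        if set(self.train_indices) & set(self.val_indices):
            raise InvalidInputError("train and validation splits overlap")

    @classmethod
    def random_split(cls, dataset, val_fraction: float = 0.1, seed: int = 0):
        n = len(dataset)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        if n_val >= n:
            raise InvalidInputError("dataset too small to split")
        return cls(dataset, np.sort(perm[n_val:]), np.sort(perm[:n_val]))


@dataclass
class Hyperparams:
    hidden: tuple = (50, 50)
    learning_rate: float = 5e-3
    epochs: int = 3000
    eval_every: int = 25
    patience: int = 12          # evaluations without improvement before stopping
    loss_weights: dict = field(default_factory=lambda: {
        "energy": 1.0, "force": 1.0, "nac": 0.1, "dipole": 0.1, "soc": 0.1})

    def replace(self, **kw) -> "Hyperparams":
        return dc_replace(self, **kw)


def _ssp(x):
    return np.logaddexp(0.0, x) - np.log(2.0)


def _sig(x):
    return expit(x)


@dataclass
class NNModel:
    """A trained multi-head feed-forward potential.

    Weights are stored as plain arrays; prediction is deterministic given
    the weights.  ``heads`` records the output layout as slices into the
    network output vector.
    """

    atom_labels: tuple
    masses: np.ndarray
    n_states: int
    hidden_weights: list          # [(W, b), ...] with W (in, out)
    out_weights: tuple            # (W, b)
    x_mean: np.ndarray
    x_std: np.ndarray
    out_mean: np.ndarray
    out_std: np.ndarray
    heads: dict                   # name -> (start, stop)
    hyperparams: Hyperparams
    seed: int
    train_rmse: dict = field(default_factory=dict)
    val_rmse: dict = field(default_factory=dict)

    # -- raw network -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    @property
    def n_pairs(self) -> int:
        return self.n_states * (self.n_states - 1) // 2

    @property
    def n_desc(self) -> int:
        return self.n_atoms * (self.n_atoms - 1) // 2

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list, list]:
        z = (X - self.x_mean) / self.x_std
        sigs, zs = [], [z]
        for W, b in self.hidden_weights:
            a = z @ W + b
            sigs.append(_sig(a))
            z = _ssp(a)
            zs.append(z)
        Wo, bo = self.out_weights
        y = z @ Wo + bo
        return y * self.out_std + self.out_mean, sigs, zs

    def _jacobian(self, sigs: list, rows: slice) -> np.ndarray:
        """d(output rows)/d(raw descriptor), shape (B, n_rows, P)."""
        Wo, _ = self.out_weights
        T = Wo[:, rows].T[np.newaxis, :, :] * sigs[-1][:, np.newaxis, :]
        for (W, _b), s in zip(reversed(self.hidden_weights[1:]), reversed(sigs[:-1])):
            T = (T @ W.T) * s[:, np.newaxis, :]
        T = T @ self.hidden_weights[0][0].T
        scale = self.out_std[rows][:, np.newaxis] / self.x_std[np.newaxis, :]
        return T * scale[np.newaxis, :, :]

    # -- provider-style prediction ----------------------------------------
    def predict(self, geom: Geometry) -> ElectronicProperties:
        """Predict all trained heads at one geometry; forces analytic."""
        d = descriptor(geom)[np.newaxis, :]
        dj = descriptor_jacobian(geom).reshape(self.n_desc, -1)
        y, sigs, _ = self._forward(d)
        y = y[0]
        s0, s1 = self.heads["energy"]
        energies = y[s0:s1]
        JE = self._jacobian(sigs, slice(s0, s1))[0]           # (S, P)
        gradients = (JE @ dj).reshape(self.n_states, self.n_atoms, 3)
        c0, c1 = self.heads["nac"]
        coeffs = y[c0:c1].reshape(self.n_pairs, self.n_desc)
        nacs = (coeffs @ dj).reshape(self.n_pairs, self.n_atoms, 3)
        dipoles = None
        if "dipole" in self.heads:
            d0, d1 = self.heads["dipole"]
            tri = y[d0:d1].reshape(-1, 3)
            dipoles = np.zeros((self.n_states, self.n_states, 3))
            k = 0
            for i in range(self.n_states):
                for j in range(i, self.n_states):
                    dipoles[i, j] = dipoles[j, i] = tri[k]
                    k += 1
        socs = None
        if "soc" in self.heads:
            so0, so1 = self.heads["soc"]
            socs = y[so0:so1]
        return ElectronicProperties(energies=energies, gradients=gradients,
                                    nacs=nacs, dipoles=dipoles, socs=socs)

    # dynamics provider contract
    evaluate = predict

    def analytic_forces(self, geom: Geometry) -> np.ndarray:
        """Per-state energy gradients dE_i/dR, shape (S, N, 3)."""
        return self.predict(geom).gradients

    def save(self, path) -> None:
        Wo, bo = self.out_weights
        arrays = {"x_mean": self.x_mean, "x_std": self.x_std,
                  "out_mean": self.out_mean, "out_std": self.out_std,
                  "Wo": Wo, "bo": bo, "masses": self.masses,
                  "seed": np.array(self.seed),
                  "hidden": np.array(self.hyperparams.hidden),
                  "lr": np.array(self.hyperparams.learning_rate)}
        for k, (W, b) in enumerate(self.hidden_weights):
            arrays[f"W{k}"] = W
            arrays[f"b{k}"] = b
        arrays["head_names"] = np.array(list(self.heads), dtype="U16")
        arrays["head_slices"] = np.array([self.heads[h] for h in self.heads])
        arrays["atom_labels"] = np.array(self.atom_labels, dtype="U4")
        arrays["n_states"] = np.array(self.n_states)
        rk = list(self.val_rmse)
        arrays["rmse_names"] = np.array(rk, dtype="U16")
        arrays["rmse_val"] = np.array([self.val_rmse[k] for k in rk])
        arrays["rmse_train"] = np.array([self.train_rmse.get(k, np.nan) for k in rk])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "NNModel":
        z = np.load(path, allow_pickle=False)
        hidden_weights = []
        k = 0
        while f"W{k}" in z:
            hidden_weights.append((z[f"W{k}"], z[f"b{k}"]))
            k += 1
        heads = {str(n): tuple(int(v) for v in s)
                 for n, s in zip(z["head_names"], z["head_slices"])}
        hp = Hyperparams(hidden=tuple(int(h) for h in z["hidden"]),
                         learning_rate=float(z["lr"]))
        model = cls(atom_labels=tuple(str(s) for s in z["atom_labels"]),
                    masses=z["masses"], n_states=int(z["n_states"]),
                    hidden_weights=hidden_weights, out_weights=(z["Wo"], z["bo"]),
                    x_mean=z["x_mean"], x_std=z["x_std"],
                    out_mean=z["out_mean"], out_std=z["out_std"],
                    heads=heads, hyperparams=hp, seed=int(z["seed"]))
        for name, v, t in zip(z["rmse_names"], z["rmse_val"], z["rmse_train"]):
            model.val_rmse[str(name)] = float(v)
            model.train_rmse[str(name)] = float(t)
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _collect_arrays(dataset):
    """Stack dataset records into training arrays (descriptor space)."""
    n = len(dataset)
    n_atoms = len(dataset.atom_labels)
    n_states = dataset.n_states
    P = n_atoms * (n_atoms - 1) // 2
    X = np.empty((n, P))
    DJ = np.empty((n, P, 3 * n_atoms))
    E = np.empty((n, n_states))
    G = np.empty((n, n_states, 3 * n_atoms))
    pairs = state_pairs(n_states)
    NAC = np.empty((n, len(pairs), 3 * n_atoms))
    has_dip = all(r.properties.dipoles is not None for r in dataset.records)
    has_soc = all(r.properties.socs is not None for r in dataset.records)
    DIP = np.empty((n, n_states * (n_states + 1) // 2 * 3)) if has_dip else None
    SOC = np.empty((n, len(pairs))) if has_soc else None
    for k, rec in enumerate(dataset.records):
        X[k] = descriptor(rec.geometry)
        DJ[k] = descriptor_jacobian(rec.geometry).reshape(P, -1)
        E[k] = rec.properties.energies
        G[k] = rec.properties.gradients.reshape(n_states, -1)
        NAC[k] = rec.properties.nacs.reshape(len(pairs), -1)
        if has_dip:
            tri = [rec.properties.dipoles[i, j]
                   for i in range(n_states) for j in range(i, n_states)]
            DIP[k] = np.concatenate(tri)
        if has_soc:
            SOC[k] = rec.properties.socs
    return X, DJ, E, G, NAC, DIP, SOC


def train(ts: TrainingSet, hyperparams: Hyperparams | None = None,
          seed: int = 0) -> NNModel:
    """Train a multi-head potential on a training set.

    The loss is a weighted sum of mean-square errors per property; the
    force term is computed through the analytic input-Jacobian of the
    energy heads, so minimizing it shapes the *derivative* of the learned
    surface.  Early stopping monitors the validation loss; the best
    weights seen are restored.  Bit-reproducible for a fixed seed.
    """
    hp = hyperparams or Hyperparams()
    ds = ts.dataset
    n_states = ds.n_states
    pairs = state_pairs(n_states)
    X, DJ, E, G, NAC, DIP, SOC = _collect_arrays(ds)
    tr, va = ts.train_indices, ts.val_indices

    P = X.shape[1]
    x_mean = X[tr].mean(axis=0)
    x_std = np.maximum(X[tr].std(axis=0), 1e-8)

    heads = {"energy": (0, n_states)}
    stop = n_states
    heads["nac"] = (stop, stop + len(pairs) * P)
    stop += len(pairs) * P
    if DIP is not None:
        heads["dipole"] = (stop, stop + DIP.shape[1])
        stop += DIP.shape[1]
    if SOC is not None:
        heads["soc"] = (stop, stop + len(pairs))
        stop += len(pairs)
    n_out = stop

    out_mean = np.zeros(n_out)
    out_std = np.ones(n_out)
    e0, e1 = heads["energy"]
    out_mean[e0:e1] = E[tr].mean(axis=0)
    out_std[e0:e1] = np.maximum(E[tr].std(axis=0), 1e-3)
    # NAC coefficient heads: scale so the head outputs are O(1) — the raw
    # expansion coefficients can be large where couplings spike
    c0h, c1h = heads["nac"]
    dj_rms = max(np.sqrt(np.mean(DJ[tr] ** 2)), 1e-8)
    for p in range(len(pairs)):
        s = max(NAC[tr][:, p, :].std(), 1e-6) / dj_rms
        out_std[c0h + p * P: c0h + (p + 1) * P] = s
    if DIP is not None:
        d0, d1 = heads["dipole"]
        out_mean[d0:d1] = DIP[tr].mean(axis=0)
        out_std[d0:d1] = np.maximum(DIP[tr].std(axis=0), 1e-3)

    rng = np.random.default_rng(seed)
    sizes = [P, *hp.hidden]
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        params.append(rng.normal(0, np.sqrt(1.0 / fan_in), (fan_in, fan_out)))
        params.append(np.zeros(fan_out))
    params.append(rng.normal(0, np.sqrt(1.0 / sizes[-1]), (sizes[-1], n_out)))
    params.append(np.zeros(n_out))

    n_hidden = len(hp.hidden)
    w = hp.loss_weights

    def build_loss(idx):
        Xs = (X[idx] - x_mean) / x_std
        pts = [ad.parameter(p) for p in params]
        z = ad.constant(Xs)
        sig_nodes = []
        for layer in range(n_hidden):
            a = ad.add(ad.matmul(z, pts[2 * layer]), pts[2 * layer + 1])
            sig_nodes.append(ad.sigmoid(a))
            z = ad.softplus_shifted(a)
        Wo, bo = pts[-2], pts[-1]
        Y = ad.add(ad.matmul(z, Wo), bo)

        B = len(idx)
        terms = []
        # energies (physical scale)
        Ystd = Y
        Ee = ad.take_last(Ystd, e0, e1)
        Ephys = ad.add(ad.mul(Ee, ad.constant(out_std[e0:e1])),
                       ad.constant(out_mean[e0:e1]))
        terms.append(("energy",
                      ad.scale(ad.sum_squares(ad.sub(Ephys, ad.constant(E[idx]))),
                               1.0 / (B * n_states))))
        # forces via the analytic input-Jacobian of the energy heads
        WoE = ad.take_last(Wo, e0, e1)                    # (H_last, S)
        T = ad.mul(ad.expand_dim(sig_nodes[-1], 1),
                   ad.expand_dim(ad.transpose2d(WoE), 0))  # (B, S, H_last)
        for layer in range(n_hidden - 1, 0, -1):
            T = ad.matmul(T, ad.transpose2d(pts[2 * layer]))
            T = ad.mul(T, ad.expand_dim(sig_nodes[layer - 1], 1))
        J = ad.matmul(T, ad.transpose2d(pts[0]))          # (B, S, P)
        scale_E = out_std[e0:e1][:, np.newaxis] / x_std[np.newaxis, :]
        Jphys = ad.mul(J, ad.constant(scale_E[np.newaxis]))
        Gpred = ad.matmul(Jphys, ad.constant(DJ[idx]))    # (B, S, 3N)
        terms.append(("force",
                      ad.scale(ad.sum_squares(ad.sub(Gpred, ad.constant(G[idx]))),
                               1.0 / (B * G.shape[1] * G.shape[2]))))
        # NAC vectors from covariant coefficients (rescaled to physical)
        c0, c1 = heads["nac"]
        Cstd = ad.take_last(Y, c0, c1)
        Cphys = ad.mul(Cstd, ad.constant(out_std[c0:c1]))
        C = ad.reshape(Cphys, (B, len(pairs), P))
        NACpred = ad.matmul(C, ad.constant(DJ[idx]))
        terms.append(("nac",
                      ad.scale(ad.sum_squares(ad.sub(NACpred, ad.constant(NAC[idx]))),
                               1.0 / (B * NAC.shape[1] * NAC.shape[2]))))
        if DIP is not None:
            d0, d1 = heads["dipole"]
            Dp = ad.add(ad.mul(ad.take_last(Y, d0, d1), ad.constant(out_std[d0:d1])),
                        ad.constant(out_mean[d0:d1]))
            terms.append(("dipole",
                          ad.scale(ad.sum_squares(ad.sub(Dp, ad.constant(DIP[idx]))),
                                   1.0 / (B * DIP.shape[1]))))
        if SOC is not None:
            s0h, s1h = heads["soc"]
            Sp = ad.take_last(Y, s0h, s1h)
            terms.append(("soc",
                          ad.scale(ad.sum_squares(ad.sub(Sp, ad.constant(SOC[idx]))),
                                   1.0 / (B * SOC.shape[1]))))
        total = None
        for name, t in terms:
            wt = ad.scale(t, w.get(name, 0.0))
            total = wt if total is None else ad.add(total, wt)
        return total, pts

    def model_from_params(pvals):
        hw = [(pvals[2 * k], pvals[2 * k + 1]) for k in range(n_hidden)]
        return NNModel(atom_labels=tuple(ds.atom_labels), masses=ds.masses.copy(),
                       n_states=n_states, hidden_weights=hw,
                       out_weights=(pvals[-2], pvals[-1]),
                       x_mean=x_mean, x_std=x_std,
                       out_mean=out_mean, out_std=out_std,
                       heads=heads, hyperparams=hp, seed=seed)

    def rmse_on(model, idx):
        y, sigs, _ = model._forward(X[idx])
        out = {}
        out["energy"] = float(np.sqrt(np.mean((y[:, e0:e1] - E[idx]) ** 2)))
        JE = model._jacobian(sigs, slice(e0, e1))
        Gp = np.matmul(JE, DJ[idx])
        out["force"] = float(np.sqrt(np.mean((Gp - G[idx]) ** 2)))
        c0, c1 = heads["nac"]
        C = y[:, c0:c1].reshape(len(idx), len(pairs), P)
        out["nac"] = float(np.sqrt(np.mean((np.matmul(C, DJ[idx]) - NAC[idx]) ** 2)))
        if DIP is not None:
            d0, d1 = heads["dipole"]
            out["dipole"] = float(np.sqrt(np.mean((y[:, d0:d1] - DIP[idx]) ** 2)))
        if SOC is not None:
            s0h, s1h = heads["soc"]
            out["soc"] = float(np.sqrt(np.mean((y[:, s0h:s1h] - SOC[idx]) ** 2)))
        return out

    # Adam
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_val = np.inf
    best_params = [p.copy() for p in params]
    bad_evals = 0
    for epoch in range(1, hp.epochs + 1):
        loss, pts = build_loss(tr)
        if not np.isfinite(loss.value):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
        loss.backward()
        lr = hp.learning_rate
        for k, pt in enumerate(pts):
            g = pt.grad
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * g * g
            mh = m[k] / (1 - beta1 ** epoch)
            vh = v[k] / (1 - beta2 ** epoch)
            params[k] = params[k] - lr * mh / (np.sqrt(vh) + eps)
        if epoch % hp.eval_every == 0 or epoch == hp.epochs:
            model = model_from_params(params)
            vr = rmse_on(model, va)
            val_score = sum(w.get(name, 0.0) * vr[name] ** 2 for name in vr)
            if val_score < best_val - 1e-14:
                best_val = val_score
                best_params = [p.copy() for p in params]
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= hp.patience:
                    break

    model = model_from_params(best_params)
    model.train_rmse = rmse_on(model, tr)
    model.val_rmse = rmse_on(model, va)
    return model


def random_grid_search(ts: TrainingSet, search_space: dict, n_trials: int,
                       seed: int = 0) -> tuple[Hyperparams, pd.DataFrame]:
    """Random search over a declared hyperparameter grid.

    Samples combinations uniformly (with replacement) from ``search_space``
    (a mapping of Hyperparams field names to candidate lists), trains each
    on the training split, and ranks by validation RMSE with energy first
    (energy RMSE is the primary key; the weighted sum of the remaining
    property RMSEs breaks ties).  Returns the best hyperparameters and the
    full trial table.
    """
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise InvalidInputError("search space is empty")
    bad = set(search_space) - {f for f in Hyperparams.__dataclass_fields__}
    if bad:
        raise InvalidInputError(f"unknown hyperparameter(s): {sorted(bad)}")
    rng = np.random.default_rng(seed)
    rows = []
    best = None
    for trial in range(n_trials):
        choice = {k: v[rng.integers(len(v))] for k, v in search_space.items()}
        hp = Hyperparams().replace(**choice)
        model = train(ts, hp, seed=int(rng.integers(2 ** 31)))
        vr = model.val_rmse
        secondary = sum(val for name, val in vr.items() if name != "energy")
        key = (vr["energy"], secondary)
        rows.append({"trial": trial, **{k: str(v) for k, v in choice.items()},
                     **{f"val_{name}": val for name, val in vr.items()}})
        if best is None or key < best[0]:
            best = (key, hp)
    return best[1], pd.DataFrame(rows)
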