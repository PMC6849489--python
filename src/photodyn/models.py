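"""Analytic diabatic model Hamiltonians used as the electronic-structure
reference provider.

Each model defines a smooth, symmetric diabatic potential matrix H(R) with
analytic Cartesian derivatives.  Diagonalizing H yields adiabatic energies,
Hellmann-Feynman gradients and nonadiabatic coupling (NAC) vectors:

    E_i, U        from  H U = U diag(E)
    G_i           =  U_i^T (dH/dR) U_i
    d_ij          =  U_i^T (dH/dR) U_j / (E_j - E_i)

With ``randomize_phase=True`` every evaluation multiplies each eigenvector
by an independent random sign, exactly the arbitrary-global-phase behaviour
of real quantum-chemistry codes that makes raw off-diagonal properties
(NACs, transition dipoles, SOCs) discontinuous between neighbouring
geometries and hence unlearnable without phase correction.

Three models are bundled, chosen so every downstream component has a ground
truth with the right surface topology:

* :class:`AvoidedCrossingModel` - a diatomic with two harmonic diabats and a
  Gaussian coupling: a single avoided crossing where the NAC peaks.
* :class:`ConicalIntersectionModel` - a triatomic two-state model whose
  diabatic coupling vanishes on a one-dimensional seam, giving a true
  conical intersection with a well-defined minimum-energy crossing point.
* :class:`SequentialDecayModel` - a diatomic with three coupled states
  arranged so that a wavepacket started on S2 decays S2 -> S1 -> S0 within
  ~100 fs, mimicking ultrafast internal conversion cascades.
"""

from __future__ import annotations

import numpy as np

from .core import ElectronicProperties, Geometry, state_pairs
from .errors import InvalidInputError

#: states closer than this (Hartree) are treated as degenerate when
#: dividing by the energy gap in the NAC formula
DEGENERACY_FLOOR = 1e-8


def adiabatize(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Diagonalize a symmetric Hamiltonian into adiabatic states.

    Returns ascending energies and an eigenvector matrix with a
    deterministic sign convention: the largest-magnitude component of each
    column is positive.

    Raises
    ------
    InvalidInputError
        If H is not symmetric or contains non-finite entries.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise InvalidInputError(f"H must be square, got shape {H.shape}")
    if not np.all(np.isfinite(H)):
        raise InvalidInputError("H contains non-finite entries")
    if not np.allclose(H, H.T, atol=1e-12 * max(1.0, np.abs(H).max())):
        raise InvalidInputError("H is not symmetric")
    energies, U = np.linalg.eigh(H)
    # deterministic sign: largest-|component| of each eigenvector positive
    for k in range(U.shape[1]):
        lead = np.argmax(np.abs(U[:, k]))
        if U[lead, k] < 0:
            U[:, k] = -U[:, k]
    return energies, U


def _dist(coords: np.ndarray, a: int, b: int) -> tuple[float, np.ndarray]:
    """Distance r_ab and its gradient dr/dR, shape (N, 3)."""
    d = coords[a] - coords[b]
    r = float(np.linalg.norm(d))
    g = np.zeros_like(coords)
    g[a] = d / r
    g[b] = -d / r
    return r, g


class DiabaticModel:
    """Base class for analytic diabatic models.

    Subclasses implement :meth:`diabatic` returning (H, dH/dR) and may
    implement property operators in the diabatic basis.  All subclasses fix
    an atom composition; geometries passed to :meth:`evaluate` must match.
    """

    n_states: int
    atom_labels: tuple[str, ...]
    masses: np.ndarray

    def __init__(self, randomize_phase: bool = False, rng_seed: int = 0,
                 degeneracy_floor: float = DEGENERACY_FLOOR):
        self.randomize_phase = randomize_phase
        # phase randomization uses its own stream, independent of any
        # dynamics RNG, so phase-correction tests are reproducible
        self._phase_rng = np.random.default_rng(rng_seed)
        self.degeneracy_floor = degeneracy_floor

    # -- interface for subclasses ------------------------------------------
    def diabatic(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (H, dH) with H (S, S) and dH (S, S, N, 3)."""
        raise NotImplementedError

    def dipole_op(self, coords: np.ndarray) -> np.ndarray | None:
        """Diabatic dipole operator (S, S, 3), or None."""
        return None

    def soc_op(self, coords: np.ndarray) -> np.ndarray | None:
        """Diabatic spin-orbit operator (S, S), or None."""
        return None

    def reference_geometry(self) -> Geometry:
        """A sensible starting geometry (near the ground-state minimum)."""
        raise NotImplementedError

    # -- provider contract --------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def make_geometry(self, coords: np.ndarray) -> Geometry:
        return Geometry(self.atom_labels, coords, self.masses)

    def evaluate(self, geom: Geometry) -> ElectronicProperties:
        """Adiabatic energies, gradients, NACs and properties at a geometry."""
        if geom.n_atoms != self.n_atoms:
            raise InvalidInputError(
                f"model expects {self.n_atoms} atoms, geometry has {geom.n_atoms}")
        H, dH = self.diabatic(geom.coords)
        energies, U = adiabatize(H)
        if self.randomize_phase:
            signs = self._phase_rng.choice([-1.0, 1.0], size=self.n_states)
            U = U * signs[np.newaxis, :]

        # Hellmann-Feynman: F_ij = U_i^T dH U_j, shape (S, S, N, 3)
        F = np.einsum("ki,klxy,lj->ijxy", U, dH, U)
        gradients = np.einsum("iixy->ixy", F)

        pairs = state_pairs(self.n_states)
        nacs = np.zeros((len(pairs), self.n_atoms, 3))
        warnings = []
        for p, (i, j) in enumerate(pairs):
            gap = energies[j] - energies[i]
            if abs(gap) < self.degeneracy_floor:
                nacs[p] = F[i, j] / self.degeneracy_floor
                warnings.append((i, j))
            else:
                nacs[p] = F[i, j] / gap

        dip_d = self.dipole_op(geom.coords)
        dipoles = None
        if dip_d is not None:
            dipoles = np.einsum("ki,klx,lj->ijx", U, dip_d, U)

        soc_d = self.soc_op(geom.coords)
        socs = None
        if soc_d is not None:
            soc_a = U.T @ soc_d @ U
            socs = np.array([soc_a[i, j] for (i, j) in pairs])

        return ElectronicProperties(
            energies=energies, gradients=gradients, nacs=nacs,
            dipoles=dipoles, socs=socs, eigenvectors=U,
            nac_warnings=tuple(warnings),
        )


class AvoidedCrossingModel(DiabaticModel):
    """Diatomic two-state model with a single avoided crossing.

    Diabats are harmonic wells displaced in the bond length r, coupled by a
    Gaussian centred at their crossing point:

        H11 = k1/2 (r - r1)^2
        H22 = k2/2 (r - r2)^2 + e2
        H12 = c exp(-(r - rx)^2 / (2 w^2))

    With the defaults the diabats cross at rx = 3.25 Bohr, where the
    adiabatic gap is 2c = 0.01 Hartree and the NAC peaks sharply.
    """

    n_states = 2
    atom_labels = ("H", "H")

    def __init__(self, k1=0.02, r1=2.0, k2=0.02, r2=3.0, e2=0.015,
                 coupling=0.005, rx=3.25, width=0.5, **kw):
        super().__init__(**kw)
        self.masses = np.array([1.00782503207, 1.00782503207])
        self.k1, self.r1 = k1, r1
        self.k2, self.r2, self.e2 = k2, r2, e2
        self.coupling, self.rx, self.width = coupling, rx, width

    def diabatic(self, coords):
        r, dr = _dist(coords, 0, 1)
        H = np.empty((2, 2))
        H[0, 0] = 0.5 * self.k1 * (r - self.r1) ** 2
        H[1, 1] = 0.5 * self.k2 * (r - self.r2) ** 2 + self.e2
        g = self.coupling * np.exp(-((r - self.rx) ** 2) / (2 * self.width ** 2))
        H[0, 1] = H[1, 0] = g
        dHdr = np.empty((2, 2))
        dHdr[0, 0] = self.k1 * (r - self.r1)
        dHdr[1, 1] = self.k2 * (r - self.r2)
        dHdr[0, 1] = dHdr[1, 0] = -g * (r - self.rx) / self.width ** 2
        dH = dHdr[:, :, np.newaxis, np.newaxis] * dr[np.newaxis, np.newaxis]
        return H, dH

    def dipole_op(self, coords):
        r, _ = _dist(coords, 0, 1)
        axis = (coords[0] - coords[1]) / r
        mag = np.array([
            [0.5 + 0.1 * (r - self.r1), 0.3 * np.exp(-((r - self.rx) ** 2))],
            [0.3 * np.exp(-((r - self.rx) ** 2)), -0.2 + 0.05 * (r - self.r2)],
        ])
        return mag[:, :, np.newaxis] * axis[np.newaxis, np.newaxis, :]

    def soc_op(self, coords):
        r, _ = _dist(coords, 0, 1)
        s = 1e-3 * np.exp(-((r - self.rx) ** 2) / 2.0)
        return np.array([[0.0, s], [s, 0.0]])

    def reference_geometry(self) -> Geometry:
        return self.make_geometry(np.array([[0.0, 0.0, 0.0], [self.r1, 0.0, 0.0]]))


class ConicalIntersectionModel(DiabaticModel):
    """Triatomic two-state model with a true conical intersection.

    In the bond-displacement coordinates x = r12 - a, y = r13 - b,
    z = r23 - c the Hamiltonian is a linear vibronic coupling model inside a
    common harmonic confinement:

        H = k/2 (x^2 + y^2 + z^2) I + [[kappa x, lam y], [lam y, -kappa x]]

    The coupling vanishes on the one-dimensional seam x = y = 0 (z free),
    where the two adiabatic surfaces touch; the minimum-energy conical
    intersection sits at x = y = z = 0, i.e. r12 = a, r13 = b, r23 = c.
    """

    n_states = 2
    atom_labels = ("X", "X", "X")

    def __init__(self, k=0.02, kappa=0.03, lam=0.03, a=2.0, b=2.0, c=3.0, **kw):
        super().__init__(**kw)
        self.masses = np.array([1.0, 1.0, 1.0])
        self.k, self.kappa, self.lam = k, kappa, lam
        self.a, self.b, self.c = a, b, c

    def diabatic(self, coords):
        r12, g12 = _dist(coords, 0, 1)
        r13, g13 = _dist(coords, 0, 2)
        r23, g23 = _dist(coords, 1, 2)
        x, y, z = r12 - self.a, r13 - self.b, r23 - self.c
        v0 = 0.5 * self.k * (x * x + y * y + z * z)
        H = np.array([
            [v0 + self.kappa * x, self.lam * y],
            [self.lam * y, v0 - self.kappa * x],
        ])
        dv0 = self.k * (x * g12 + y * g13 + z * g23)
        dH = np.empty((2, 2, self.n_atoms, 3))
        dH[0, 0] = dv0 + self.kappa * g12
        dH[1, 1] = dv0 - self.kappa * g12
        dH[0, 1] = dH[1, 0] = self.lam * g13
        return H, dH

    def meci_geometry(self) -> Geometry:
        """The exact minimum-energy conical intersection (analytic)."""
        coords = np.array([
            [0.0, 0.0, 0.0],
            [self.a, 0.0, 0.0],
            [-0.25, np.sqrt(self.b ** 2 - 0.0625), 0.0],
        ])
        return self.make_geometry(coords)

    def reference_geometry(self) -> Geometry:
        # displaced off the seam so the ground state is non-degenerate
        g = self.meci_geometry()
        coords = g.coords.copy()
        coords[1, 0] += 0.4
        return self.make_geometry(coords)


class SequentialDecayModel(DiabaticModel):
    """Diatomic three-state model with sequential S2 -> S1 -> S0 decay.

    All three diabats share a harmonic confinement K/2 (r - r0)^2 and differ
    by linear terms with different slopes, so the S2 and S1 diabats cross at
    one bond length and the S1 and S0 diabats at another.  Gaussian
    couplings sit at the crossings; the direct S0-S2 coupling is zero, so
    population flows strictly sequentially.  A trajectory started near the
    compressed ground-state minimum on S2 accelerates outward, crosses the
    S2/S1 and then S1/S0 intersections repeatedly as it oscillates, and
    relaxes to S0 on a tens-of-femtoseconds time scale.
    """

    n_states = 3
    atom_labels = ("X", "X")

    def __init__(self, K=0.02, r0=2.2, s1=0.02, s2=0.01, e1=0.025,
                 s3=0.03, e2=0.05, c12=0.002, c23=0.002, w=0.25, **kw):
        super().__init__(**kw)
        self.masses = np.array([1.0, 1.0])
        self.K, self.r0 = K, r0
        self.s1, self.s2, self.e1 = s1, s2, e1
        self.s3, self.e2 = s3, e2
        self.c12, self.c23, self.w = c12, c23, w
        # diabat crossing points (from the linear terms)
        self.r12x = r0 + e1 / (s1 + s2)
        self.r23x = r0 + (e2 - e1) / (s3 - s2)

    def diabatic(self, coords):
        r, dr = _dist(coords, 0, 1)
        d = r - self.r0
        vc = 0.5 * self.K * d * d
        g12 = self.c12 * np.exp(-((r - self.r12x) ** 2) / (2 * self.w ** 2))
        g23 = self.c23 * np.exp(-((r - self.r23x) ** 2) / (2 * self.w ** 2))
        H = np.array([
            [vc + self.s1 * d, g12, 0.0],
            [g12, vc + self.e1 - self.s2 * d, g23],
            [0.0, g23, vc + self.e2 - self.s3 * d],
        ])
        dHdr = np.array([
            [self.K * d + self.s1,
             -g12 * (r - self.r12x) / self.w ** 2, 0.0],
            [-g12 * (r - self.r12x) / self.w ** 2,
             self.K * d - self.s2,
             -g23 * (r - self.r23x) / self.w ** 2],
            [0.0, -g23 * (r - self.r23x) / self.w ** 2,
             self.K * d - self.s3],
        ])
        dH = dHdr[:, :, np.newaxis, np.newaxis] * dr[np.newaxis, np.newaxis]
        return H, dH

    def dipole_op(self, coords):
        r, _ = _dist(coords, 0, 1)
        axis = (coords[0] - coords[1]) / r
        mag = np.array([
            [0.2 * (r - self.r0), 0.1, 0.0],
            [0.1, 0.5, 0.2],
            [0.0, 0.2, -0.3],
        ])
        return mag[:, :, np.newaxis] * axis[np.newaxis, np.newaxis, :]

    def ground_state_minimum_r(self) -> float:
        """Bond length of the S0 minimum (analytic, coupling neglected)."""
        return self.r0 - self.s1 / self.K

    def reference_geometry(self) -> Geometry:
        r = self.ground_state_minimum_r()
        return self.make_geometry(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))


BUNDLED_MODELS = {
    "avoided_crossing": AvoidedCrossingModel,
    "conical_intersection": ConicalIntersectionModel,
    "sequential_decay": SequentialDecayModel,
}


def make_model(name: str, **params) -> DiabaticModel:
    """Instantiate a bundled model by name with parameter overrides."""
    try:
        cls = BUNDLED_MODELS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown model {name!r}; available: {sorted(BUNDLED_MODELS)}")
    return cls(**params)
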