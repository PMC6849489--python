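"""Core domain containers: molecular geometries and per-geometry electronic
properties of a manifold of coupled electronic states.

Conventions
-----------
* Coordinates are Cartesian, in Bohr.  Masses are in unified atomic mass
  units (amu) and converted to electron masses inside the dynamics code.
* Adiabatic states are 0-indexed and ordered by ascending energy
  (S0, S1, S2 ... at the user interface).
* Off-diagonal state pairs (i, j) with i < j are stored once, in
  lexicographic order; ``pair_index`` maps (i, j) to the storage slot.
  Nonadiabatic coupling vectors obey d_ji = -d_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError

#: default atomic masses (amu) for the elements the bundled models use
ATOMIC_MASSES = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "He": 4.002602,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "F": 18.99840322,
    "X": 1.0,  # generic model particle
}


def state_pairs(n_states: int) -> list[tuple[int, int]]:
    """Ordered list of state pairs (i, j), i < j, lexicographic."""
    return [(i, j) for i in range(n_states) for j in range(i + 1, n_states)]


def pair_index(i: int, j: int, n_states: int) -> int:
    """Storage slot of the ordered pair (i, j), i < j."""
    if not (0 <= i < j < n_states):
        raise InvalidInputError(f"invalid state pair ({i}, {j}) for {n_states} states")
    return i * n_states - i * (i + 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry: element labels, Cartesian coordinates, masses.

    Parameters
    ----------
    atom_labels : tuple of str
        Element symbols, length N >= 2.
    coords : (N, 3) ndarray
        Cartesian positions in Bohr.
    masses : (N,) ndarray
        Atomic masses in amu, all positive.
    """

    atom_labels: tuple[str, ...]
    coords: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidInputError(f"coords must be (N, 3), got {coords.shape}")
        n = coords.shape[0]
        if n < 2:
            raise InvalidInputError("a geometry needs at least 2 atoms")
        if len(self.atom_labels) != n:
            raise InvalidInputError("atom_labels length does not match coords")
        masses = np.asarray(self.masses, dtype=float)
        if masses.shape != (n,):
            raise InvalidInputError("masses shape does not match atom count")
        if not np.all(np.isfinite(coords)):
            raise InvalidInputError("coords contain non-finite values")
        if not np.all(masses > 0):
            raise InvalidInputError("all masses must be positive")
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "masses", masses)

    @classmethod
    def from_labels(cls, atom_labels, coords) -> "Geometry":
        """Build a geometry looking masses up from the element table."""
        try:
            masses = np.array([ATOMIC_MASSES[s] for s in atom_labels])
        except KeyError as exc:
            raise InvalidInputError(f"unknown element symbol {exc.args[0]!r}") from exc
        return cls(tuple(atom_labels), np.asarray(coords, dtype=float), masses)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class ElectronicProperties:
    """Per-geometry adiabatic electronic properties.

    Attributes
    ----------
    energies : (n_states,) ndarray
        Adiabatic energies in Hartree, ascending.
    gradients : (n_states, N, 3) ndarray
        Energy gradients dE_i/dR in Hartree/Bohr.
    nacs : (n_pairs, N, 3) ndarray
        Nonadiabatic coupling vectors d_ij for pairs i < j, in 1/Bohr.
    dipoles : (n_states, n_states, 3) ndarray or None
        Permanent (i = j) and transition (i != j) dipole moments, symmetric
        in (i, j), atomic units.
    socs : (n_pairs,) ndarray or None
        Scalar spin-orbit couplings for pairs i < j, Hartree.
    eigenvectors : (n_states, n_states) ndarray or None
        Columns U_i of the diabatic-to-adiabatic transform; only available
        from analytic model providers.
    nac_warnings : tuple
        Pairs whose NAC was capped because the states were quasi-degenerate.
    """

    energies: np.ndarray
    gradients: np.ndarray
    nacs: np.ndarray
    dipoles: np.ndarray | None = None
    socs: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    nac_warnings: tuple = field(default_factory=tuple)

    @property
    def n_states(self) -> int:
        return len(self.energies)

    def nac(self, i: int, j: int) -> np.ndarray:
        """Coupling vector d_ij for any i != j (antisymmetry applied)."""
        if i < j:
            return self.nacs[pair_index(i, j, self.n_states)]
        return -self.nacs[pair_index(j, i, self.n_states)]

    def copy(self) -> "ElectronicProperties":
        return ElectronicProperties(
            energies=self.energies.copy(),
            gradients=self.gradients.copy(),
            nacs=self.nacs.copy(),
            dipoles=None if self.dipoles is None else self.dipoles.copy(),
            socs=None if self.socs is None else self.socs.copy(),
            eigenvectors=None if self.eigenvectors is None else self.eigenvectors.copy(),
            nac_warnings=self.nac_warnings,
        )
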