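"""Wavefunction phase tracking and correction.

Electronic-structure codes return adiabatic wavefunctions only up to an
arbitrary sign per state, so off-diagonal properties (NAC vectors,
transition dipoles, SOCs) of neighbouring geometries can differ by random
signs.  This module restores a consistent ("virtual global") sign
convention across a dataset by computing overlaps between the electronic
eigenvectors of adjacent geometries, reading per-state signs off the
overlap diagonal, and — when two geometries are too far apart for the
diagonal to be decisive — recursively bisecting the straight-line path
between them and chaining the per-segment signs.

Diagonal observables (energies, gradients, permanent dipoles) involve each
wavefunction twice, so any sign squares away and they are left untouched;
every off-diagonal element (i, j) is multiplied by p_i * p_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ElectronicProperties, Geometry, state_pairs
from .errors import InvalidInputError, PhaseTrackingError

DEFAULT_DECISION_THRESHOLD = 0.5
DEFAULT_MAX_BISECTIONS = 10


@dataclass
class PhaseVector:
    """Per-state signs p_i in {-1, +1} with a decided flag per state."""

    signs: np.ndarray
    decided: np.ndarray

    @classmethod
    def undecided(cls, n_states: int) -> "PhaseVector":
        return cls(np.ones(n_states), np.zeros(n_states, dtype=bool))

    @classmethod
    def identity(cls, n_states: int) -> "PhaseVector":
        return cls(np.ones(n_states), np.ones(n_states, dtype=bool))

    @property
    def all_decided(self) -> bool:
        return bool(np.all(self.decided))

    def compose(self, other: "PhaseVector") -> "PhaseVector":
        """Elementwise product; decided only where both are decided."""
        return PhaseVector(self.signs * other.signs, self.decided & other.decided)


def overlap(eigvecs_a: np.ndarray, eigvecs_b: np.ndarray) -> np.ndarray:
    """Overlap matrix S_kl = <U_a,k | U_b,l> between two eigenvector sets."""
    Ua = np.asarray(eigvecs_a, dtype=float)
    Ub = np.asarray(eigvecs_b, dtype=float)
    if Ua.shape != Ub.shape or Ua.ndim != 2:
        raise InvalidInputError(
            f"eigenvector sets must have equal 2-D shapes, got {Ua.shape} vs {Ub.shape}")
    return Ua.T @ Ub


def detect_phases(S: np.ndarray, decision_threshold: float = DEFAULT_DECISION_THRESHOLD
                  ) -> PhaseVector:
    """Read per-state signs off the overlap diagonal.

    State k is decided with sign(S_kk) iff |S_kk| >= decision_threshold;
    otherwise it stays undecided (a valid outcome, triggering bisection
    upstream).
    """
    diag = np.diagonal(np.asarray(S, dtype=float))
    decided = np.abs(diag) >= decision_threshold
    signs = np.where(np.sign(diag) < 0, -1.0, 1.0)
    signs = np.where(decided, signs, 1.0)
    return PhaseVector(signs, decided)


def apply_phase(props: ElectronicProperties, p: PhaseVector) -> ElectronicProperties:
    """Multiply every off-diagonal property element (i, j) by p_i * p_j.

    Energies, gradients and permanent dipoles are untouched.  Applying the
    same phase vector twice is the identity, since (p_i p_j)^2 = 1.
    """
    if not p.all_decided:
        undecided = tuple(int(i) for i in np.flatnonzero(~p.decided))
        raise PhaseTrackingError(
            f"cannot apply phases with undecided states {undecided}", undecided)
    out = props.copy()
    pairs = state_pairs(props.n_states)
    factors = np.array([p.signs[i] * p.signs[j] for (i, j) in pairs])
    out.nacs = out.nacs * factors[:, np.newaxis, np.newaxis]
    if out.socs is not None:
        out.socs = out.socs * factors
    if out.dipoles is not None:
        pp = np.outer(p.signs, p.signs)
        out.dipoles = out.dipoles * pp[:, :, np.newaxis]
    if out.eigenvectors is not None:
        out.eigenvectors = out.eigenvectors * p.signs[np.newaxis, :]
    return out


def track_phases(geom_ref: Geometry, geom_new: Geometry, provider,
                 decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
                 max_bisections: int = DEFAULT_MAX_BISECTIONS,
                 eigvecs_ref: np.ndarray | None = None,
                 eigvecs_new: np.ndarray | None = None) -> PhaseVector:
    """Phase vector carrying the reference sign convention to a new geometry.

    If the direct overlap between the two eigenvector sets decides every
    state, it is returned immediately.  Otherwise the straight-line path in
    Cartesian coordinates is bisected recursively; per-segment phase vectors
    chain by elementwise product (any random sign of an intermediate
    evaluation appears in both adjacent segments and cancels).

    Pre-computed endpoint eigenvectors may be supplied so the correction is
    applied to properties from the same provider call.
    """
    if eigvecs_ref is None:
        eigvecs_ref = provider.evaluate(geom_ref).eigenvectors
    if eigvecs_new is None:
        eigvecs_new = provider.evaluate(geom_new).eigenvectors
    if eigvecs_ref is None or eigvecs_new is None:
        raise InvalidInputError("provider does not expose eigenvectors")

    def segment(coords_a, Ua, coords_b, Ub, depth) -> PhaseVector:
        p = detect_phases(overlap(Ua, Ub), decision_threshold)
        if p.all_decided:
            return p
        if depth >= max_bisections:
            undecided = tuple(int(i) for i in np.flatnonzero(~p.decided))
            raise PhaseTrackingError(
                f"phase tracking failed after {max_bisections} bisection levels; "
                f"undecided states: {undecided}", undecided)
        mid = 0.5 * (coords_a + coords_b)
        Um = provider.evaluate(geom_ref.with_coords(mid)).eigenvectors
        left = segment(coords_a, Ua, mid, Um, depth + 1)
        right = segment(mid, Um, coords_b, Ub, depth + 1)
        return left.compose(right)

    return segment(geom_ref.coords, eigvecs_ref, geom_new.coords, eigvecs_new, 0)


def phase_align(provider, geom_ref: Geometry, geom_new: Geometry,
                eigvecs_ref: np.ndarray | None = None,
                decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
                max_bisections: int = DEFAULT_MAX_BISECTIONS,
                ) -> tuple[ElectronicProperties, PhaseVector]:
    """Evaluate the provider at ``geom_new`` and return phase-corrected
    properties consistent with the reference geometry's sign convention."""
    props = provider.evaluate(geom_new)
    p = track_phases(geom_ref, geom_new, provider, decision_threshold,
                     max_bisections, eigvecs_ref=eigvecs_ref,
                     eigvecs_new=props.eigenvectors)
    return apply_phase(props, p), p


def phase_correct_dataset(dataset, reference_index: int = 0, provider=None,
                          decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
                          max_bisections: int = DEFAULT_MAX_BISECTIONS):
    """Correct every record of a dataset relative to a single reference record.

    Phases are tracked from the reference geometry to each record's geometry
    (bisecting with fresh provider calls where needed) and the record's
    off-diagonal properties are sign-corrected in place on a copied dataset.
    A per-record phase log is stored on the returned dataset.

    Raises
    ------
    PhaseTrackingError
        Re-raised with the offending record index attached.
    """
    records = dataset.records
    if not records:
        raise InvalidInputError("dataset is empty")
    if not (0 <= reference_index < len(records)):
        raise InvalidInputError(f"reference index {reference_index} out of range")
    ref = records[reference_index]
    out = dataset.copy()
    phase_log = []
    for idx, rec in enumerate(out.records):
        try:
            p = track_phases(ref.geometry, rec.geometry, provider,
                             decision_threshold, max_bisections,
                             eigvecs_ref=ref.properties.eigenvectors,
                             eigvecs_new=rec.properties.eigenvectors)
        except PhaseTrackingError as exc:
            raise PhaseTrackingError(
                f"record {idx}: {exc}", exc.undecided_states) from exc
        rec.properties = apply_phase(rec.properties, p)
        rec.phase = p.signs.copy()
        phase_log.append(p.signs.copy())
    out.phase_reference_index = reference_index
    out.phase_log = np.array(phase_log)
    return out
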