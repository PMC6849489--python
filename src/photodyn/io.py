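"""File formats: XYZ geometries, the HDF5 training-set container, and
delimited population tables.

The dataset container stores a header (atom labels, masses, state count,
units, phase-reference index, provenance) and per-record arrays (geometry,
electronic properties, phase log, source tag).  All numerics are stored
losslessly; a SHA-256 checksum over the numeric payload is verified on
load so a truncated or corrupted file never partially loads.

XYZ files are in Angstrom (the package works in Bohr internally).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ATOMIC_MASSES, ElectronicProperties, Geometry, state_pairs
from .errors import InvalidInputError, ParseError
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

SCHEMA_VERSION = 1
SOURCE_TAGS = ("normal_mode", "adaptive", "manual")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path) -> list[Geometry]:
    """Read a (multi-frame) XYZ file; coordinates converted Angstrom -> Bohr."""
    lines = Path(path).read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"empty XYZ file: {path}")
    geoms = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"malformed atom-count line {lines[i]!r}", line=i + 1)
        if i + 1 + n >= len(lines) + 1 and n > 0 and i + 2 + n > len(lines) + 1:
            raise ParseError("truncated XYZ frame", line=i + 1)
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ParseError("truncated XYZ frame", line=i + 1)
        labels, coords = [], []
        for k, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"malformed atom line {row!r}", line=i + 3 + k)
            if parts[0] not in ATOMIC_MASSES:
                raise ParseError(f"unknown element {parts[0]!r}", line=i + 3 + k)
            labels.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        geoms.append(Geometry.from_labels(labels, np.array(coords) * BOHR_PER_ANGSTROM))
        i += 2 + n
    return geoms


def write_xyz(path, geoms, comments=None) -> None:
    """Write geometries (Bohr internally) to a multi-frame XYZ file in Angstrom."""
    if isinstance(geoms, Geometry):
        geoms = [geoms]
    out = []
    for f, g in enumerate(geoms):
        comment = comments[f] if comments else ""
        out.append(f"{g.n_atoms}\n{comment}")
        ang = g.coords * ANGSTROM_PER_BOHR
        for label, (x, y, z) in zip(g.atom_labels, ang):
            out.append(f"{label:4s} {x: 18.10f} {y: 18.10f} {z: 18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class DatasetRecord:
    geometry: Geometry
    properties: ElectronicProperties
    phase: np.ndarray | None = None
    source: str = "manual"

    def __post_init__(self):
        if self.source not in SOURCE_TAGS:
            raise InvalidInputError(
                f"unknown source tag {self.source!r}; expected one of {SOURCE_TAGS}")


@dataclass
class Dataset:
    """An in-memory training set: header plus homogeneous records."""

    atom_labels: tuple[str, ...]
    masses: np.ndarray
    n_states: int
    records: list[DatasetRecord] = field(default_factory=list)
    phase_reference_index: int = 0
    provenance: str = ""
    phase_log: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def append(self, record: DatasetRecord) -> None:
        g = record.geometry
        if tuple(g.atom_labels) != tuple(self.atom_labels):
            raise InvalidInputError("record atom labels do not match dataset header")
        if record.properties.n_states != self.n_states:
            raise InvalidInputError("record state count does not match dataset header")
        self.records.append(record)

    def copy(self) -> "Dataset":
        return Dataset(
            atom_labels=self.atom_labels,
            masses=self.masses.copy(),
            n_states=self.n_states,
            records=[
                DatasetRecord(r.geometry, r.properties.copy(),
                              None if r.phase is None else r.phase.copy(), r.source)
                for r in self.records
            ],
            phase_reference_index=self.phase_reference_index,
            provenance=self.provenance,
            phase_log=None if self.phase_log is None else self.phase_log.copy(),
        )

    @classmethod
    def from_provider(cls, provider, geometries, source: str = "manual",
                      provenance: str = "") -> "Dataset":
        """Evaluate a provider on a list of geometries and collect records."""
        ds = cls(atom_labels=tuple(provider.atom_labels),
                 masses=np.asarray(provider.masses, dtype=float),
                 n_states=provider.n_states, provenance=provenance)
        for g in geometries:
            ds.append(DatasetRecord(g, provider.evaluate(g), source=source))
        return ds


def _dataset_arrays(ds: Dataset) -> dict[str, np.ndarray]:
    n = len(ds)
    n_atoms = len(ds.atom_labels)
    pairs = state_pairs(ds.n_states)
    coords = np.array([r.geometry.coords for r in ds.records]).reshape(n, n_atoms, 3)
    energies = np.array([r.properties.energies for r in ds.records])
    gradients = np.array([r.properties.gradients for r in ds.records])
    nacs = np.array([r.properties.nacs for r in ds.records])
    arrays = {"coords": coords, "energies": energies,
              "gradients": gradients, "nacs": nacs}
    if all(r.properties.dipoles is not None for r in ds.records) and n:
        arrays["dipoles"] = np.array([r.properties.dipoles for r in ds.records])
    if all(r.properties.socs is not None for r in ds.records) and n:
        arrays["socs"] = np.array([r.properties.socs for r in ds.records])
    if all(r.properties.eigenvectors is not None for r in ds.records) and n:
        arrays["eigenvectors"] = np.array([r.properties.eigenvectors for r in ds.records])
    if all(r.phase is not None for r in ds.records) and n:
        arrays["phases"] = np.array([r.phase for r in ds.records])
    assert len(pairs) == nacs.shape[1] if n else True
    return arrays


def _checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def write_dataset(path, ds: Dataset) -> None:
    """Write a dataset to an HDF5 container with a payload checksum."""
    arrays = _dataset_arrays(ds)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["atom_labels"] = list(ds.atom_labels)
        f.attrs["masses"] = ds.masses
        f.attrs["n_states"] = ds.n_states
        f.attrs["units"] = "hartree,bohr,atomic"
        f.attrs["phase_reference_index"] = ds.phase_reference_index
        f.attrs["provenance"] = ds.provenance
        f.attrs["sources"] = [r.source for r in ds.records]
        f.attrs["checksum"] = _checksum(arrays)
        for key, arr in arrays.items():
            f.create_dataset(key, data=arr)


def read_dataset(path) -> Dataset:
    """Load a dataset, verifying schema version and payload checksum."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version > SCHEMA_VERSION:
            raise InvalidInputError(
                f"dataset schema version {version} is newer than supported {SCHEMA_VERSION}")
        arrays = {key: f[key][...] for key in f.keys()}
        if _checksum(arrays) != f.attrs["checksum"]:
            raise InvalidInputError(f"checksum mismatch in {path}; file corrupted")
        labels = tuple(str(s) for s in f.attrs["atom_labels"])
        masses = np.asarray(f.attrs["masses"], dtype=float)
        n_states = int(f.attrs["n_states"])
        sources = [str(s) for s in f.attrs["sources"]]
        ds = Dataset(atom_labels=labels, masses=masses, n_states=n_states,
                     phase_reference_index=int(f.attrs["phase_reference_index"]),
                     provenance=str(f.attrs["provenance"]))
        n = arrays["coords"].shape[0] if "coords" in arrays else 0
        for k in range(n):
            props = ElectronicProperties(
                energies=arrays["energies"][k],
                gradients=arrays["gradients"][k],
                nacs=arrays["nacs"][k],
                dipoles=arrays["dipoles"][k] if "dipoles" in arrays else None,
                socs=arrays["socs"][k] if "socs" in arrays else None,
                eigenvectors=arrays["eigenvectors"][k] if "eigenvectors" in arrays else None,
            )
            phase = arrays["phases"][k] if "phases" in arrays else None
            ds.append(DatasetRecord(Geometry(labels, arrays["coords"][k], masses),
                                    props, phase, sources[k]))
        return ds


# ---------------------------------------------------------------------------
# Population tables
# ---------------------------------------------------------------------------

def write_population_table(path, table: pd.DataFrame) -> None:
    """Write a population table (time_fs, n_0..n_k, count) as TSV."""
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_population_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "time_fs" not in df.columns:
        raise InvalidInputError(f"{path} is not a population table (no time_fs column)")
    return df
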