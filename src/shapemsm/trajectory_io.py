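"""Trajectory, energy-table, feature-matrix and discrete-trajectory I/O.

Coordinate data comes in through :mod:`mdtraj` (DCD/XTC with a PDB
topology); everything else is small, hand-editable text: two-column
energy tables, CSV feature matrices with a metadata header, and
one-integer-per-line discrete trajectories.

Conventions used throughout the package:

* frame indices are 0-based,
* lag times are expressed in frames; conversion to picoseconds via
  ``frame_interval`` happens only at reporting time,
* multiple trajectories are kept as separate values and never
  concatenated, so no spurious transitions appear across boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StructureFrame",
    "Trajectory",
    "EnergyTable",
    "read_trajectory",
    "read_energy_table",
    "write_energy_table",
    "write_features",
    "read_features",
    "write_dtraj",
    "read_dtraj",
]


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


@dataclass(frozen=True)
class StructureFrame:
    """One 3D conformation: ``n_atoms x 3`` coordinates in Angstrom."""

    coords: np.ndarray
    atom_names: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError(f"coords must be (n_atoms, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if len(self.atom_names) != coords.shape[0]:
            raise ValueError("atom_names length must match n_atoms")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered sequence of frames sharing one topology.

    Parameters
    ----------
    frames
        Frames in temporal order; all must share atom count and ordering.
    frame_interval
        Time between consecutive stored frames, in ps.
    trajectory_id
        Free-form label used to keep independent runs apart.
    """

    frames: list[StructureFrame]
    frame_interval: float
    trajectory_id: str = "traj"

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        n = self.frames[0].n_atoms
        names = self.frames[0].atom_names
        for f in self.frames:
            if f.n_atoms != n or f.atom_names != names:
                raise FormatError("all frames must share atom count and ordering")

    def __len__(self) -> int:
        return len(self.frames)

    def stride(self, s: int) -> "Trajectory":
        """Keep every ``s``-th frame; ``frame_interval`` is multiplied by ``s``."""
        if s < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(self.frames[::s], self.frame_interval * s, self.trajectory_id)

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an ``(n_frames, n_atoms, 3)`` array."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class EnergyTable:
    """Per-frame potential energies recorded at a stride.

    ``entries`` maps 0-based frame index to energy (kcal/mol).  Real
    datasets often evaluate an expensive implicit-solvent energy only on
    a subsample of frames (e.g. every 32nd); the stride records that
    spacing and is inferred from the index gaps when read from disk.
    """

    frame_indices: np.ndarray
    energies: np.ndarray
    stride: int = 1

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_indices, dtype=int)
        en = np.asarray(self.energies, dtype=float)
        if idx.ndim != 1 or en.shape != idx.shape:
            raise ValueError("frame_indices and energies must be 1-d and equal length")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if np.any(idx < 0):
            raise ValueError("frame indices must be nonnegative")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        self.frame_indices = idx
        self.energies = en

    def __len__(self) -> int:
        return self.frame_indices.size

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.frame_indices.tolist(), self.energies.tolist()))


def read_trajectory(
    topology_path: str | Path,
    trajectory_path: str | Path,
    stride: int = 1,
    frame_interval: float = 2.0,
    trajectory_id: str | None = None,
) -> Trajectory:
    """Load a DCD/XTC trajectory with a PDB topology, keeping every
    ``stride``-th frame.

    Parameters
    ----------
    topology_path, trajectory_path
        PDB topology and DCD or XTC coordinate file.
    stride
        Keep every ``stride``-th frame (stride 2 on a 2 ps save interval
        yields 4 ps spacing).
    frame_interval
        Save interval of the source trajectory in ps; DCD headers do not
        carry reliable time, so this is supplied by the caller.

    Returns
    -------
    Trajectory
        Frames in temporal order with ``frame_interval * stride`` spacing
        and coordinates in Angstrom.
    """
    import mdtraj as md

    topology_path = Path(topology_path)
    trajectory_path = Path(trajectory_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    if not trajectory_path.exists():
        raise FileNotFoundError(trajectory_path)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    try:
        traj = md.load(str(trajectory_path), top=str(topology_path), stride=stride)
    except Exception as exc:  # mdtraj raises assorted types on mismatch
        raise FormatError(f"failed to read {trajectory_path.name}: {exc}") from exc
    if traj.n_frames == 0:
        raise FormatError(f"{trajectory_path.name} contains no frames")
    names = tuple(a.name for a in traj.topology.atoms)
    coords_ang = traj.xyz * 10.0  # mdtraj stores nm
    frames = [StructureFrame(coords_ang[i], names) for i in range(traj.n_frames)]
    return Trajectory(
        frames,
        frame_interval=frame_interval * stride,
        trajectory_id=trajectory_id or trajectory_path.stem,
    )


def write_trajectory(traj: Trajectory, topology_path: str | Path, trajectory_path: str | Path) -> None:
    """Write a trajectory as PDB topology + DCD coordinates."""
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    res = top.add_residue("GLY", chain)
    carbon = md.element.carbon
    for name in traj.frames[0].atom_names:
        top.add_atom(name, carbon, res)
    xyz = traj.coords_array() / 10.0  # to nm
    m = md.Trajectory(xyz, top)
    m[0].save_pdb(str(topology_path))
    m.save_dcd(str(trajectory_path))


def read_energy_table(path: str | Path) -> EnergyTable:
    """Parse a two-column (frame_index, energy) text table.

    Whitespace- or comma-delimited; lines starting with ``#`` are
    comments.  The stride is inferred as the GCD of consecutive index
    gaps (a single row yields stride 1 by convention).
    """
    path = Path(path)
    indices: list[int] = []
    energies: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise FormatError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                idx = int(parts[0])
                en = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric row: {line!r}") from exc
            indices.append(idx)
            energies.append(en)
    if not indices:
        raise FormatError(f"{path.name}: empty energy table")
    gaps = np.diff(indices)
    stride = int(math.gcd(*gaps.tolist())) if gaps.size else 1
    return EnergyTable(np.array(indices), np.array(energies), stride=max(stride, 1))


def write_energy_table(table: EnergyTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# frame_index energy_kcal_mol\n")
        for i, e in zip(table.frame_indices, table.energies):
            fh.write(f"{int(i)} {e:.10g}\n")


# --- feature matrices ----------------------------------------------------

_FEATURE_HEADER = "# shapemsm-features"


def write_features(features, path: str | Path) -> None:
    """Write a feature matrix as CSV with a metadata header.

    The header records the feature kind, frame interval and source id so
    that a read round-trips to an identical :class:`FeatureTrajectory`.
    """
    matrix = np.asarray(features.matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("refusing to write an empty feature matrix")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_FEATURE_HEADER} kind={features.kind}")
        fh.write(f" frame_interval={features.frame_interval!r}")
        fh.write(f" source_id={features.source_id}")
        fh.write(f" n_frames={matrix.shape[0]} n_features={matrix.shape[1]}\n")
        np.savetxt(fh, matrix, delimiter=",", fmt="%.17g")


def read_features(path: str | Path):
    """Read a feature matrix written by :func:`write_features`."""
    from .featurize import FeatureTrajectory

    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith(_FEATURE_HEADER):
            raise FormatError(f"{path.name}: missing feature header")
        meta: dict[str, str] = {}
        for tok in header[len(_FEATURE_HEADER):].split():
            key, _, val = tok.partition("=")
            meta[key] = val
        matrix = np.loadtxt(fh, delimiter=",", ndmin=2)
    expected = (int(meta["n_frames"]), int(meta["n_features"]))
    if matrix.shape != expected:
        raise FormatError(
            f"{path.name}: shape {matrix.shape} does not match header {expected}"
        )
    return FeatureTrajectory(
        matrix=matrix,
        kind=meta["kind"],
        frame_interval=float(meta["frame_interval"]),
        source_id=meta.get("source_id", "unknown"),
    )


# --- discrete trajectories ------------------------------------------------


def write_dtraj(labels: Sequence[int], path: str | Path) -> None:
    """Write 0-based state labels, one integer per line.

    Labels are written verbatim (no relabeling), so gaps in the label set
    survive a round-trip.
    """
    arr = np.asarray(labels, dtype=int)
    if arr.ndim != 1:
        raise ValueError("labels must be a 1-d sequence")
    if arr.size and arr.min() < 0:
        raise ValueError("state labels must be nonnegative")
    np.savetxt(Path(path), arr, fmt="%d")


def read_dtraj(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        arr = np.loadtxt(path, dtype=int, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-integer dtraj entry: {exc}") from exc
    if arr.size and arr.min() < 0:
        raise FormatError(f"{path.name}: negative state label")
    return arr
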