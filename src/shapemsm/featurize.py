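"""Fixed-length featurization of 3D structures.

Two featurizers are provided:

* **USR** (ultrafast shape recognition): four reference points are
  located on the structure — the molecular centroid (ctd), the atom
  closest to it (cst), the atom furthest from it (fct) and the atom
  furthest from fct (ftf).  The distribution of distances from *all*
  atoms to each reference point is summarized by its first three moments
  (mean, variance, skewness), giving a 12-vector that is invariant under
  rigid motion and atom reordering.  It is not invariant under mirror
  reflection in general, since an enantiomer can present the same four
  distance distributions only in special geometries; no canonicalization
  is attempted.
* **CA-skip**: the Cartesian coordinates of a strided subset of the
  alpha-carbon atoms (take one, skip ``skip``), the coarse baseline
  representation that requires Kabsch superposition + RMSD as its
  distance.

Moment conventions: population (biased) moments throughout; skewness is
the third standardized central moment ``mu3 / sigma**3`` and defined as 0
when the distance distribution is degenerate (sigma = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import StructureFrame, Trajectory

__all__ = [
    "FeatureTrajectory",
    "UsrReferencePoints",
    "usr_features",
    "usr_feature_matrix",
    "usr_reference_points",
    "ca_skip_features",
    "kabsch_superpose",
    "pairwise_distance",
    "featurize_trajectory",
    "select_atoms",
]

FEATURE_KINDS = ("usr", "ca_skip")


@dataclass
class FeatureTrajectory:
    """An ``n_frames x d`` feature matrix with frame-spacing metadata."""

    matrix: np.ndarray
    kind: str
    frame_interval: float
    source_id: str = "traj"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-d")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}")
        if self.kind == "usr" and self.matrix.shape[1] != 12:
            raise ValueError("USR features must have 12 columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature rows must be finite")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class UsrReferencePoints:
    """The four USR reference points for one frame.

    ``ctd`` is a 3-vector (centroid, not an atom); the other three are
    atom indices.  Ties are broken toward the lowest atom index.
    """

    ctd: np.ndarray
    cst_index: int
    fct_index: int
    ftf_index: int


def select_atoms(frame: StructureFrame, selection: str = "all") -> np.ndarray:
    """Return coordinates of the selected atom subset.

    ``all`` keeps every atom, ``heavy`` drops hydrogens (names starting
    with H), ``ca`` keeps alpha carbons only.
    """
    if selection == "all":
        return frame.coords
    if selection == "heavy":
        mask = [not n.upper().startswith("H") for n in frame.atom_names]
    elif selection == "ca":
        mask = [n.upper() == "CA" for n in frame.atom_names]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    coords = frame.coords[np.asarray(mask, dtype=bool)]
    if coords.shape[0] == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return coords


def usr_reference_points(frame: StructureFrame, selection: str = "all") -> UsrReferencePoints:
    coords = select_atoms(frame, selection)
    ctd = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - ctd, axis=1)
    cst = int(np.argmin(d_ctd))  # argmin/argmax take the first index on ties
    fct = int(np.argmax(d_ctd))
    d_fct = np.linalg.norm(coords - coords[fct], axis=1)
    ftf = int(np.argmax(d_fct))
    return UsrReferencePoints(ctd=ctd, cst_index=cst, fct_index=fct, ftf_index=ftf)


def _moments(d: np.ndarray, axis: int = -1) -> np.ndarray:
    """(mean, population variance, standardized skewness) along ``axis``."""
    mean = d.mean(axis=axis)
    centered = d - np.expand_dims(mean, axis)
    var = (centered**2).mean(axis=axis)
    mu3 = (centered**3).mean(axis=axis)
    sigma3 = var ** 1.5
    skew = np.divide(mu3, sigma3, out=np.zeros_like(mu3), where=sigma3 > 0)
    return np.stack([mean, var, skew], axis=-1)


def usr_feature_matrix(coords: np.ndarray) -> np.ndarray:
    """Vectorized USR featurization of an ``(n_frames, n_atoms, 3)`` stack.

    Returns an ``(n_frames, 12)`` matrix with moment triples concatenated
    in reference-point order ctd, cst, fct, ftf.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must be (n_frames, n_atoms, 3)")
    n_frames = coords.shape[0]
    ctd = coords.mean(axis=1, keepdims=True)  # (F,1,3)
    d_ctd = np.linalg.norm(coords - ctd, axis=2)  # (F,N)
    cst_idx = np.argmin(d_ctd, axis=1)
    fct_idx = np.argmax(d_ctd, axis=1)
    rows = np.arange(n_frames)
    cst_pt = coords[rows, cst_idx][:, None, :]
    fct_pt = coords[rows, fct_idx][:, None, :]
    d_cst = np.linalg.norm(coords - cst_pt, axis=2)
    d_fct = np.linalg.norm(coords - fct_pt, axis=2)
    ftf_idx = np.argmax(d_fct, axis=1)
    ftf_pt = coords[rows, ftf_idx][:, None, :]
    d_ftf = np.linalg.norm(coords - ftf_pt, axis=2)
    blocks = [_moments(d) for d in (d_ctd, d_cst, d_fct, d_ftf)]
    return np.concatenate(blocks, axis=1)


def usr_features(frame: StructureFrame, selection: str = "all") -> np.ndarray:
    """Compute the 12-dimensional USR descriptor of one frame."""
    coords = select_atoms(frame, selection)
    return usr_feature_matrix(coords[None])[0]


def ca_skip_features(frame: StructureFrame, skip: int = 4) -> np.ndarray:
    """Concatenated (x, y, z) of every ``(skip+1)``-th alpha carbon.

    The take-one-skip-``skip`` pattern keeps CA indices 0, skip+1,
    2(skip+1), ...; ``skip=0`` keeps every CA, and ``skip >= n_CA`` keeps
    only the first.
    """
    if skip < 0:
        raise ValueError("skip must be >= 0")
    ca = select_atoms(frame, "ca")
    return ca[:: skip + 1].ravel()


def kabsch_superpose(
    a: StructureFrame | np.ndarray, b: StructureFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD rigid superposition of ``b`` onto ``a`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``b @ rotation + translation`` best superposes onto ``a``.  The
    rotation is proper (determinant +1); reflections are not allowed.
    """
    pa = a.coords if isinstance(a, StructureFrame) else np.asarray(a, dtype=float)
    pb = b.coords if isinstance(b, StructureFrame) else np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError(f"atom-count mismatch: {pa.shape} vs {pb.shape}")
    if pa.shape[0] < 3:
        raise ValueError("need at least 3 atoms for a well-defined superposition")
    ca_, cb = pa.mean(axis=0), pb.mean(axis=0)
    qa, qb = pa - ca_, pb - cb
    h = qb.T @ qa
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    trans = ca_ - cb @ rot
    rmsd = float(np.sqrt(np.mean(np.sum((qb @ rot - qa) ** 2, axis=1))))
    return rot, trans, rmsd


def pairwise_distance(u: np.ndarray, v: np.ndarray, kind: str = "usr") -> float:
    """Distance between two feature vectors.

    Euclidean for ``usr``; for ``ca_skip`` the vectors are unflattened to
    point clouds and the minimum superposed RMSD is returned.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("feature vectors must have equal length")
    if kind == "usr":
        return float(np.linalg.norm(u - v))
    if kind == "ca_skip":
        pu = u.reshape(-1, 3)
        pv = v.reshape(-1, 3)
        return kabsch_superpose(pu, pv)[2]
    raise ValueError(f"unknown feature kind {kind!r}")


def featurize_trajectory(
    traj: Trajectory,
    kind: str = "usr",
    skip: int = 4,
    selection: str = "all",
) -> FeatureTrajectory:
    """Featurize every frame of a trajectory into one matrix."""
    if kind == "usr":
        if selection == "all":
            matrix = usr_feature_matrix(traj.coords_array())
        else:
            matrix = np.stack([usr_features(f, selection) for f in traj.frames])
    elif kind == "ca_skip":
        matrix = np.stack([ca_skip_features(f, skip) for f in traj.frames])
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return FeatureTrajectory(
        matrix=matrix,
        kind=kind,
        frame_interval=traj.frame_interval,
        source_id=traj.trajectory_id,
    )
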