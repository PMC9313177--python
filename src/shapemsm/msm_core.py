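"""Transition-matrix estimation and state summaries.

Transitions are counted with a sliding window at lag ``tau`` frames
within each discrete trajectory — never across trajectory boundaries —
and row-normalized into a maximum-likelihood (non-reversible) transition
matrix.  Before normalization the counts are restricted to the largest
strongly connected component of the count graph so that a stationary
distribution is well defined; the stationary vector is the left
eigenvector with eigenvalue 1.  Detailed balance is NOT assumed, so the
spectrum may be complex; downstream timescale computations use
eigenvalue magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "DiscreteTrajectory",
    "CountMatrix",
    "TransitionModel",
    "count_transitions",
    "estimate_transition_matrix",
    "state_summary",
    "pca_embed",
]


@dataclass
class DiscreteTrajectory:
    """Ordered 0-based macrostate labels for one trajectory."""

    labels: np.ndarray
    frame_interval: float = 1.0
    trajectory_id: str = "traj"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a nonempty 1-d sequence")
        if self.labels.min() < 0:
            raise ValueError("state labels must be nonnegative")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class CountMatrix:
    """Sliding-window transition counts at lag ``lag_frames``.

    ``active_states[i]`` is the original label of row/column ``i``.
    """

    counts: np.ndarray
    lag_frames: int
    active_states: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.active_states = np.asarray(self.active_states, dtype=int)
        s = self.counts.shape
        if len(s) != 2 or s[0] != s[1] or s[0] != self.active_states.size:
            raise ValueError("counts must be square and match active_states")
        if self.lag_frames < 1:
            raise ValueError("lag must be >= 1 frame")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix at lag ``lag_frames`` with its
    stationary distribution over ``active_states``."""

    transition_matrix: np.ndarray
    stationary: np.ndarray
    active_states: np.ndarray
    lag_frames: int
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.stationary, dtype=float)
        if np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows must sum to 1 within 1e-12")
        if np.any(pi < -1e-14) or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("stationary must be a probability vector")
        if np.max(np.abs(pi @ t - pi)) > 1e-10:
            raise ValueError("stationary must satisfy pi T = pi within 1e-10")
        self.transition_matrix = t
        self.stationary = np.clip(pi, 0.0, None)
        self.active_states = np.asarray(self.active_states, dtype=int)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def lag_time(self) -> float:
        """Lag in physical time (ps)."""
        return self.lag_frames * self.frame_interval

    def state_index(self, label: int) -> int:
        """Row index of an original state label (KeyError if inactive)."""
        hits = np.flatnonzero(self.active_states == label)
        if hits.size == 0:
            raise KeyError(f"state {label} is not in the active set")
        return int(hits[0])


def count_transitions(
    dtrajs: Sequence[DiscreteTrajectory] | Sequence[np.ndarray],
    lag_frames: int,
) -> CountMatrix:
    """Sliding-window transition counts pooled over trajectories.

    Every within-trajectory pair ``(t, t + lag)`` increments one count;
    trajectories shorter than ``lag + 1`` contribute nothing, and at
    least one must be long enough.
    """
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    arrays = [d.labels if isinstance(d, DiscreteTrajectory) else np.asarray(d, int) for d in dtrajs]
    if not arrays:
        raise ValueError("need at least one discrete trajectory")
    if all(a.size <= lag_frames for a in arrays):
        raise ValueError(f"no trajectory is longer than the lag ({lag_frames})")
    active = np.unique(np.concatenate(arrays))
    index = {int(s): i for i, s in enumerate(active)}
    n = active.size
    counts = np.zeros((n, n), dtype=np.int64)
    lookup = np.full(active.max() + 1, -1, dtype=int)
    lookup[active] = np.arange(n)
    for a in arrays:
        if a.size <= lag_frames:
            continue
        i = lookup[a[:-lag_frames]]
        j = lookup[a[lag_frames:]]
        np.add.at(counts, (i, j), 1)
    return CountMatrix(counts=counts, lag_frames=lag_frames, active_states=active)


def _largest_scc(counts: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected component of the count
    graph (edges where counts are positive); ties go to the component
    holding more total counts, then to the one containing the smallest
    state index."""
    n = counts.shape[0]
    graph = scipy.sparse.csr_matrix((counts > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    best, best_key = None, None
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        mass = counts[np.ix_(members, members)].sum()
        key = (members.size, mass, -members.min())
        if best_key is None or key > best_key:
            best, best_key = members, key
    return best


def estimate_transition_matrix(
    c: CountMatrix,
    connectivity: bool = True,
    reversible: bool = False,
    frame_interval: float = 1.0,
) -> TransitionModel:
    """Row-normalize counts into a transition matrix and solve for the
    stationary distribution.

    With ``connectivity`` (default) the counts are first restricted to the
    largest strongly connected component, which guarantees every row has
    mass and the unit eigenvalue is unique.  ``reversible`` symmetrizes
    the counts as (C + C^T)/2 before normalizing — a comparison mode, not
    the default maximum-likelihood estimate.
    """
    counts = np.asarray(c.counts, dtype=float)
    active = c.active_states
    if reversible:
        counts = 0.5 * (counts + counts.T)
    if connectivity:
        keep = _largest_scc(counts)
        counts = counts[np.ix_(keep, keep)]
        active = active[keep]
    rowsum = counts.sum(axis=1)
    if np.any(rowsum == 0):
        raise ValueError("zero count row; enable connectivity restriction")
    t = counts / rowsum[:, None]
    t /= t.sum(axis=1, keepdims=True)  # exact row-stochasticity
    pi = stationary_distribution(t)
    return TransitionModel(
        transition_matrix=t,
        stationary=pi,
        active_states=active,
        lag_frames=c.lag_frames,
        frame_interval=frame_interval,
    )


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Left eigenvector of the eigenvalue closest to 1, normalized to a
    probability vector."""
    evals, evecs = scipy.linalg.eig(t, left=True, right=False)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def state_summary(m: TransitionModel, top_m: int = 6) -> pd.DataFrame:
    """Stationary populations sorted descending, with the ``top_m`` most
    populous states itemized and the remainder pooled into row ``S*``.

    Columns: ``state`` (original label, or -1 for the pooled row),
    ``population``, ``self_transition``, ``out_of_state`` (= 1 - self).
    Populations, including S*, sum to 1.
    """
    order = np.argsort(-m.stationary, kind="stable")
    rows = []
    for rank, i in enumerate(order):
        if rank >= top_m:
            break
        rows.append(
            {
                "state": int(m.active_states[i]),
                "population": float(m.stationary[i]),
                "self_transition": float(m.transition_matrix[i, i]),
                "out_of_state": float(1.0 - m.transition_matrix[i, i]),
            }
        )
    rest = order[top_m:]
    if rest.size:
        rows.append(
            {
                "state": -1,
                "population": float(m.stationary[rest].sum()),
                "self_transition": np.nan,
                "out_of_state": np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["pooled_label"] = "S*"
    return df


def pca_embed(features, stride: int = 1, n_components: int = 2):
    """Mean-centered PCA embedding of (strided) feature rows.

    Returns ``(embedding, explained_variance_ratio)``; the ratios are
    nonincreasing and sum to at most 1.
    """
    from sklearn.decomposition import PCA

    from .featurize import FeatureTrajectory

    if isinstance(features, FeatureTrajectory):
        x = features.matrix
    elif isinstance(features, (list, tuple)):
        x = np.vstack([f.matrix if isinstance(f, FeatureTrajectory) else f for f in features])
    else:
        x = np.asarray(features, dtype=float)
    x = x[::stride]
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(x)
    return emb, pca.explained_variance_ratio_
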