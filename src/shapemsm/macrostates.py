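"""Macrostate discovery by k-medoids clustering with knee-based model selection.

The clustering is alternating k-medoids under the squared-Euclidean
cost: frames are assigned to their nearest medoid, then each cluster's
medoid is replaced by the member minimizing the within-cluster sum of
squared distances (SSE).  Because the cost is squared Euclidean, the
exact medoid update decomposes as

    cost(m) = n_c * |x_m|^2 - 2 x_m . sum_i x_i + sum_i |x_i|^2,

which is O(n_c d) per cluster instead of O(n_c^2) — exact k-medoids
stays practical on hundreds of thousands of 12-d USR rows without ever
materializing a distance matrix.  Seeding is k-medoids++ (squared
-distance weighted), with multiple restarts keeping the lowest-SSE run.

The number of macrostates is chosen by locating the knee of the SSE
profile over a k range: the k whose point lies furthest below the chord
joining the profile's endpoints (ties to the smallest k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featurize import FeatureTrajectory
from .landscape import BasinDecomposition
from .msm_core import DiscreteTrajectory

__all__ = [
    "MedoidModel",
    "KneeProfile",
    "kmedoids",
    "knee_select",
    "assign_states",
]


@dataclass
class MedoidModel:
    """A fitted k-medoids clustering.

    ``medoid_frame_indices`` index rows of the feature matrix the model
    was fit on; ``medoids`` holds the corresponding feature vectors so
    that out-of-sample frames can be labeled without the training data.
    """

    medoid_frame_indices: np.ndarray
    medoids: np.ndarray
    sse: float
    rng_seed: int

    def __post_init__(self) -> None:
        self.medoid_frame_indices = np.asarray(self.medoid_frame_indices, dtype=int)
        self.medoids = np.asarray(self.medoids, dtype=float)
        if len(set(self.medoid_frame_indices.tolist())) != self.k:
            raise ValueError("medoids must be distinct data points")
        if not np.isfinite(self.sse):
            raise ValueError("sse must be finite")

    @property
    def k(self) -> int:
        return self.medoid_frame_indices.size


@dataclass
class KneeProfile:
    """SSE-vs-k profile with the selected knee."""

    k_values: np.ndarray
    sse_values: np.ndarray
    knee_k: int
    models: dict[int, MedoidModel] | None = None

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.sse_values = np.asarray(self.sse_values, dtype=float)
        if self.k_values.size < 2:
            raise ValueError("need at least two k values for a knee")
        if int(self.knee_k) not in self.k_values:
            raise ValueError("knee_k must be one of k_values")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureTrajectory):
        return features.matrix
    return np.asarray(features, dtype=float)


def _assign(x: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-medoid labels and squared distances (ties to lower label)."""
    # |x - m|^2 = |x|^2 - 2 x.m + |m|^2 ; argmin over medoids
    cross = x @ medoids.T
    d2 = (x * x).sum(1)[:, None] - 2.0 * cross + (medoids * medoids).sum(1)[None, :]
    np.maximum(d2, 0.0, out=d2)
    labels = np.argmin(d2, axis=1)  # argmin takes the first index on ties
    return labels, d2[np.arange(x.shape[0]), labels]


def _exact_medoid(x: np.ndarray) -> int:
    """Index (into x) of the member minimizing total squared distance."""
    sq = (x * x).sum(1)
    cost = x.shape[0] * sq - 2.0 * (x @ x.sum(0)) + sq.sum()
    return int(np.argmin(cost))


def _plusplus_seed(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-medoids++ seeding: iteratively sample points with probability
    proportional to squared distance from the chosen set."""
    n = x.shape[0]
    chosen = [int(rng.integers(n))]
    d2 = ((x - x[chosen[0]]) ** 2).sum(1)
    while len(chosen) < k:
        total = d2.sum()
        if total <= 0:  # fewer distinct points than k is rejected upstream
            probs = np.full(n, 1.0 / n)
        else:
            probs = d2 / total
        nxt = int(rng.choice(n, p=probs))
        chosen.append(nxt)
        d2 = np.minimum(d2, ((x - x[nxt]) ** 2).sum(1))
    return np.array(chosen, dtype=int)


def kmedoids(
    features,
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 300,
) -> MedoidModel:
    """Fit alternating k-medoids and return the best of ``n_restarts`` runs.

    Deterministic for a fixed seed.  SSE is nonincreasing across
    iterations within a run (each half-step cannot raise the cost).
    """
    x = _as_matrix(features)
    n = x.shape[0]
    distinct = np.unique(x, axis=0).shape[0]
    if k > distinct:
        raise ValueError(f"k={k} exceeds the number of distinct points ({distinct})")
    rng = np.random.default_rng(seed)
    best: MedoidModel | None = None
    for _ in range(n_restarts):
        med_idx = _plusplus_seed(x, k, rng)
        for _ in range(max_iter):
            labels, d2 = _assign(x, x[med_idx])
            new_idx = med_idx.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    continue  # keep the old medoid for an emptied cluster
                new_idx[c] = members[_exact_medoid(x[members])]
            if np.array_equal(new_idx, med_idx):
                break
            med_idx = new_idx
        labels, d2 = _assign(x, x[med_idx])
        sse = float(d2.sum())
        if best is None or sse < best.sse:
            order = np.argsort(med_idx)  # canonical medoid order for stable labels
            best = MedoidModel(
                medoid_frame_indices=med_idx[order],
                medoids=x[med_idx[order]],
                sse=sse,
                rng_seed=seed,
            )
    assert best is not None
    return best


def knee_of_profile(k_values: np.ndarray, sse_values: np.ndarray) -> int:
    """The k furthest below the chord joining the profile endpoints.

    Distances are measured perpendicular to the chord in the raw (k, sse)
    plane; ties break to the smallest k.
    """
    k_values = np.asarray(k_values, dtype=float)
    sse_values = np.asarray(sse_values, dtype=float)
    p0 = np.array([k_values[0], sse_values[0]])
    p1 = np.array([k_values[-1], sse_values[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return int(k_values[0])
    # signed cross product; positive where the curve dips below the chord
    rel_k = k_values - p0[0]
    rel_s = sse_values - p0[1]
    signed = (chord[1] * rel_k - chord[0] * rel_s) / norm
    best = int(np.argmax(signed))
    return int(k_values[best])


def knee_select(
    features,
    k_range=range(2, 26),
    seed: int = 0,
    n_restarts: int = 5,
    keep_models: bool = True,
) -> KneeProfile:
    """Run k-medoids over ``k_range`` and select the SSE-profile knee."""
    ks = np.array(sorted(set(int(k) for k in k_range)))
    models: dict[int, MedoidModel] = {}
    sses = []
    for k in ks:
        m = kmedoids(features, int(k), seed=seed, n_restarts=n_restarts)
        sses.append(m.sse)
        if keep_models:
            models[int(k)] = m
    knee_k = knee_of_profile(ks, np.array(sses))
    return KneeProfile(
        k_values=ks,
        sse_values=np.array(sses),
        knee_k=knee_k,
        models=models if keep_models else None,
    )


def assign_states(
    features,
    model: MedoidModel | BasinDecomposition,
) -> DiscreteTrajectory | list[DiscreteTrajectory]:
    """Label every frame with its macrostate.

    For a :class:`MedoidModel` each frame gets its nearest medoid's label
    (ties to the lower label).  For a :class:`BasinDecomposition` each
    frame gets the basin of its nearest graph vertex, which reduces to
    the frame's own basin when the frame is a vertex.  Accepts a single
    :class:`FeatureTrajectory` or a list of them; labeling is
    per-frame, hence idempotent and independent of frame order.
    """
    if isinstance(features, (list, tuple)):
        return [assign_states(f, model) for f in features]
    x = _as_matrix(features)
    if isinstance(model, MedoidModel):
        labels, _ = _assign(x, model.medoids)
    elif isinstance(model, BasinDecomposition):
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=1).fit(model.vertex_features)
        _, idx = nn.kneighbors(x)
        labels = model.assignment[idx[:, 0]]
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    if isinstance(features, FeatureTrajectory):
        return DiscreteTrajectory(
            labels=labels,
            frame_interval=features.frame_interval,
            trajectory_id=features.source_id,
        )
    return DiscreteTrajectory(labels=labels, frame_interval=1.0)
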