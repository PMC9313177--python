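"""Energy-landscape basin decomposition over a nearest-neighbor graph.

Conformation-energy samples are organized into an undirected k-NN graph
whose vertices carry energies.  Local minima (vertices at least as low
as every neighbor) anchor basins; every other vertex follows, step by
step, the incident edge maximizing the descent ratio
``[e(u) - e(v)] / d(u, v)`` until it reaches a minimum, and vertices
draining to the same minimum form one basin.  Because each move strictly
decreases energy, descent terminates in at most ``n`` steps.

Tie rules (deterministic, order-stable):

* among equal best descent ratios the lower-energy neighbor wins, then
  the lower vertex index;
* a vertex whose neighbors all have energy >= its own is a local
  minimum and terminates descent at itself, so adjacent equal-energy
  minima each anchor their own (singleton or larger) basin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .featurize import FeatureTrajectory
from .trajectory_io import EnergyTable

__all__ = [
    "NeighborGraph",
    "BasinDecomposition",
    "build_knn_graph",
    "find_local_minima",
    "assign_basins",
]

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Undirected conformation-energy graph.

    ``neighbors[u]`` lists the vertices adjacent to ``u`` and
    ``distances[u]`` the matching edge lengths; the representation is
    symmetric (v appears in neighbors[u] iff u appears in neighbors[v]).
    Duplicate input points are merged into one vertex, with the original
    row indices kept in ``vertex_members`` and the merged count in
    ``multiplicity``.
    """

    energies: np.ndarray
    neighbors: list[np.ndarray]
    distances: list[np.ndarray]
    vertex_features: np.ndarray
    vertex_members: list[np.ndarray]

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        n = self.energies.size
        if len(self.neighbors) != n or len(self.distances) != n:
            raise ValueError("neighbors/distances must have one entry per vertex")
        for u, (nb, di) in enumerate(zip(self.neighbors, self.distances)):
            if nb.size != di.size:
                raise ValueError("neighbor and distance lists must align")
            if np.any(nb == u):
                raise ValueError("self-loops are not allowed")
            if np.any(di <= 0):
                raise ValueError("edge distances must be positive")
            if n > 1 and nb.size == 0:
                raise ValueError(f"vertex {u} has no neighbors")

    @property
    def n_vertices(self) -> int:
        return self.energies.size

    @property
    def multiplicity(self) -> np.ndarray:
        return np.array([m.size for m in self.vertex_members])


@dataclass
class BasinDecomposition:
    """Partition of graph vertices into basins, one focal minimum each.

    ``assignment[u]`` is the basin id of vertex ``u``; ``minima[b]`` is
    the focal-minimum vertex of basin ``b``.  Basin ids are contiguous,
    ordered by focal-minimum vertex index.  ``frame_assignment`` carries
    the same labels expanded back to the original input rows (duplicates
    included), and ``vertex_features`` allows nearest-vertex labeling of
    frames that never entered the graph.
    """

    assignment: np.ndarray
    minima: np.ndarray
    vertex_features: np.ndarray
    frame_assignment: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.minima = np.asarray(self.minima, dtype=int)
        for b, m in enumerate(self.minima):
            if self.assignment[m] != b:
                raise ValueError("each focal minimum must belong to its own basin")
        if self.frame_assignment is None:
            self.frame_assignment = self.assignment

    @property
    def n_basins(self) -> int:
        return self.minima.size


def build_knn_graph(
    features: FeatureTrajectory | np.ndarray,
    energies: EnergyTable | np.ndarray,
    k: int = 10,
    metric: str = "euclidean",
) -> NeighborGraph:
    """Build the symmetrized union k-NN graph over energy-bearing frames.

    Parameters
    ----------
    features
        Feature matrix covering all frames (rows are frame indices).
    energies
        Energy table whose frame indices select the rows that become
        vertices; frames without an energy are dropped (logged).  A bare
        array is taken as one energy per feature row.
    k
        Neighbors per vertex before union symmetrization (an edge is kept
        if either endpoint lists the other).
    metric
        ``euclidean`` for USR features, or ``rmsd`` for flattened
        Cartesian features (superposed RMSD; quadratic cost, intended for
        the small energy-bearing subsets it is used on).
    """
    matrix = features.matrix if isinstance(features, FeatureTrajectory) else np.asarray(features, float)
    if isinstance(energies, EnergyTable):
        keep = energies.frame_indices[energies.frame_indices < matrix.shape[0]]
        if keep.size < len(energies):
            raise ValueError("energy table refers to frames beyond the feature matrix")
        dropped = matrix.shape[0] - keep.size
        if dropped:
            logger.info("dropping %d frames without energies", dropped)
        points = matrix[keep]
        evals = energies.energies
    else:
        evals = np.asarray(energies, dtype=float)
        if evals.shape[0] != matrix.shape[0]:
            raise ValueError("need one energy per feature row")
        points = matrix

    # merge duplicate points so all edge distances are positive
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    n = uniq.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of distinct points ({n})")
    members = [np.flatnonzero(inverse == u) for u in range(n)]
    # merged vertex energy: minimum over duplicates (the basin-relevant depth)
    venergy = np.array([evals[m].min() for m in members])

    if metric == "euclidean":
        nn = NearestNeighbors(n_neighbors=k + 1).fit(uniq)
        dist, idx = nn.kneighbors(uniq)
    elif metric == "rmsd":
        from .featurize import pairwise_distance

        full = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                full[i, j] = full[j, i] = pairwise_distance(uniq[i], uniq[j], kind="ca_skip")
        idx = np.argsort(full, axis=1, kind="stable")[:, : k + 1]
        dist = np.take_along_axis(full, idx, axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    adjacency: list[dict[int, float]] = [dict() for _ in range(n)]
    for u in range(n):
        for j, v in enumerate(idx[u]):
            if v == u:
                continue
            d = float(dist[u, j])
            if d <= 0:  # distinct points at zero distance cannot occur post-merge
                continue
            adjacency[u][int(v)] = d
            adjacency[int(v)][u] = d  # union symmetrization
    neighbors = [np.array(sorted(a), dtype=int) for a in adjacency]
    distances = [np.array([adjacency[u][v] for v in neighbors[u]]) for u in range(n)]
    return NeighborGraph(
        energies=venergy,
        neighbors=neighbors,
        distances=distances,
        vertex_features=uniq,
        vertex_members=members,
    )


def find_local_minima(g: NeighborGraph) -> np.ndarray:
    """Vertices whose energy is <= every neighbor's energy (non-strict)."""
    out = []
    for u in range(g.n_vertices):
        nb = g.neighbors[u]
        if nb.size == 0 or np.all(g.energies[u] <= g.energies[nb]):
            out.append(u)
    return np.array(out, dtype=int)


def _descent_step(g: NeighborGraph, u: int) -> int:
    """Next vertex along the steepest descent ratio, or ``u`` if a minimum."""
    nb = g.neighbors[u]
    lower = nb[g.energies[nb] < g.energies[u]]
    if lower.size == 0:
        return u
    ratios = (g.energies[u] - g.energies[lower]) / np.array(
        [g.distances[u][np.searchsorted(g.neighbors[u], v)] for v in lower]
    )
    cand = lower[ratios == ratios.max()]
    if cand.size > 1:  # ties: lower energy, then lower index
        emin = g.energies[cand].min()
        cand = cand[g.energies[cand] == emin]
    return int(cand.min())


def assign_basins(g: NeighborGraph) -> BasinDecomposition:
    """Assign every vertex to the basin of the minimum its descent reaches.

    Uses path memoization: once a vertex's destination minimum is known,
    any later descent hitting that vertex stops immediately, so the whole
    decomposition runs in near-linear time.
    """
    n = g.n_vertices
    dest = np.full(n, -1, dtype=int)  # destination minimum per vertex
    for start in range(n):
        if dest[start] >= 0:
            continue
        path = []
        u = start
        while dest[u] < 0:
            path.append(u)
            v = _descent_step(g, u)
            if v == u:  # local minimum
                dest[u] = u
                break
            u = v
        for p in path:
            dest[p] = dest[u]
    minima = np.unique(dest)
    basin_of_min = {int(m): b for b, m in enumerate(minima)}
    assignment = np.array([basin_of_min[int(d)] for d in dest], dtype=int)
    n_rows = sum(m.size for m in g.vertex_members)
    frame_assignment = np.empty(n_rows, dtype=int)
    for u, rows in enumerate(g.vertex_members):
        frame_assignment[rows] = assignment[u]
    return BasinDecomposition(
        assignment=assignment,
        minima=minima,
        vertex_features=g.vertex_features,
        frame_assignment=frame_assignment,
    )
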