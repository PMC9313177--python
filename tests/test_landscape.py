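import numpy as np
import pytest

from shapemsm.landscape import (
    NeighborGraph,
    assign_basins,
    build_knn_graph,
    find_local_minima,
)


def path_graph(energies, distances=None):
    """A path graph 0-1-2-...-n with given vertex energies."""
    n = len(energies)
    neighbors, dists = [], []
    for u in range(n):
        nb = [v for v in (u - 1, u + 1) if 0 <= v < n]
        neighbors.append(np.array(nb, dtype=int))
        if distances is None:
            dists.append(np.ones(len(nb)))
        else:
            dists.append(np.array([distances[min(u, v)] for v in nb]))
    return NeighborGraph(
        energies=np.asarray(energies, float),
        neighbors=neighbors,
        distances=dists,
        vertex_features=np.arange(n, dtype=float)[:, None],
        vertex_members=[np.array([u]) for u in range(n)],
    )


def brute_force_basins(g):
    """Independent oracle: plain-Python steepest-ratio descent per vertex."""
    def descend(u):
        while True:
            best_v, best_ratio = None, None
            for j, v in enumerate(g.neighbors[u]):
                if g.energies[v] >= g.energies[u]:
                    continue
                ratio = (g.energies[u] - g.energies[v]) / g.distances[u][j]
                key = (ratio, -g.energies[v], -v)  # ratio, then lower e, then lower idx
                if best_ratio is None or key > best_ratio:
                    best_ratio, best_v = key, v
            if best_v is None:
                return u
            u = best_v

    return np.array([descend(u) for u in range(g.n_vertices)])


class TestBuildGraph:
    def test_collinear_points_union_symmetrized(self):
        feats = np.array([[0.0], [1.0], [2.1]])
        g = build_knn_graph(feats, np.zeros(3), k=1)
        # vertex 2's nearest is 1; union symmetrization keeps (1,2)
        assert set(map(tuple, [(0, 1), (1, 2)])) == {
            (u, int(v)) for u in range(3) for v in g.neighbors[u] if u < v
        }

    def test_k_equals_n_minus_one_is_complete(self, rng):
        pts = rng.normal(size=(6, 3))
        g = build_knn_graph(pts, np.zeros(6), k=5)
        assert all(g.neighbors[u].size == 5 for u in range(6))

    def test_duplicates_merged_with_multiplicity(self):
        feats = np.array([[0.0], [0.0], [1.0], [2.0]])
        g = build_knn_graph(feats, np.array([1.0, 2.0, 0.5, 0.7]), k=1)
        assert g.n_vertices == 3
        assert sorted(g.multiplicity.tolist()) == [1, 1, 2]
        # merged vertex keeps the lower energy of its duplicates
        assert g.energies[0] == 1.0
        assert all(np.all(d > 0) for d in g.distances)

    def test_k_too_large_rejected(self, rng):
        pts = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            build_knn_graph(pts, np.zeros(4), k=4)


class TestLocalMinima:
    def test_path_example(self):
        g = path_graph([1.0, 0.0, 2.0, 0.5, 1.0])
        np.testing.assert_array_equal(find_local_minima(g), [1, 3])

    def test_monotone_path_single_minimum(self):
        g = path_graph([5.0, 4.0, 3.0, 2.0, 1.0])
        np.testing.assert_array_equal(find_local_minima(g), [4])

    def test_plateau_every_vertex_is_minimum(self):
        g = path_graph([1.0, 1.0, 1.0])
        np.testing.assert_array_equal(find_local_minima(g), [0, 1, 2])


class TestAssignBasins:
    def test_path_example_two_basins(self):
        g = path_graph([1.0, 0.0, 2.0, 0.5, 1.0])
        b = assign_basins(g)
        # vertex 2 compares ratios 2.0 (toward 1) vs 1.5 (toward 3)
        np.testing.assert_array_equal(b.assignment, [0, 0, 0, 1, 1])
        np.testing.assert_array_equal(b.minima, [1, 3])

    def test_monotone_path_single_basin(self):
        g = path_graph([5.0, 4.0, 3.0, 2.0, 1.0])
        b = assign_basins(g)
        assert b.n_basins == 1
        assert set(b.assignment.tolist()) == {0}

    def test_basin_count_equals_minima_count(self, rng):
        pts = rng.normal(size=(40, 3))
        g = build_knn_graph(pts, rng.normal(size=40), k=4)
        b = assign_basins(g)
        assert b.n_basins == find_local_minima(g).size

    def test_matches_brute_force_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 50))
            k = int(rng.integers(2, min(6, n)))
            pts = rng.normal(size=(n, int(rng.integers(1, 5))))
            energies = rng.normal(size=n)
            g = build_knn_graph(pts, energies, k=k)
            b = assign_basins(g)
            dest = brute_force_basins(g)
            # same partition: destination minimum determines the basin
            got = {tuple(np.flatnonzero(b.assignment == c).tolist()) for c in range(b.n_basins)}
            want = {tuple(np.flatnonzero(dest == m).tolist()) for m in np.unique(dest)}
            assert got == want

    def test_partition_invariant_under_vertex_permutation(self, rng):
        n = 25
        pts = rng.normal(size=(n, 2))
        energies = rng.normal(size=n)
        perm = rng.permutation(n)
        b1 = assign_basins(build_knn_graph(pts, energies, k=3))
        b2 = assign_basins(build_knn_graph(pts[perm], energies[perm], k=3))
        blocks1 = {
            frozenset(np.flatnonzero(b1.frame_assignment == c).tolist())
            for c in range(b1.n_basins)
        }
        blocks2 = {
            frozenset(int(perm[r]) for r in np.flatnonzero(b2.frame_assignment == c))
            for c in range(b2.n_basins)
        }
        assert blocks1 == blocks2

    def test_descent_terminates_on_plateau(self):
        g = path_graph([1.0, 1.0, 1.0, 1.0])
        b = assign_basins(g)  # every plateau vertex anchors its own basin
        assert b.n_basins == 4
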