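import numpy as np
import pytest

from shapemsm.msm_core import (
    CountMatrix,
    count_transitions,
    estimate_transition_matrix,
    pca_embed,
    state_summary,
)
from shapemsm.synthetic import sample_dtrajs, uniform_chain


class TestCountTransitions:
    def test_pair_enumeration(self):
        c = count_transitions([np.array([0, 0, 1, 1, 0])], 1)
        np.testing.assert_array_equal(c.counts, [[1, 1], [1, 1]])

    def test_single_state_long_lag(self):
        c = count_transitions([np.zeros(5, int)], 2)
        np.testing.assert_array_equal(c.counts, [[3]])

    def test_no_counting_across_trajectory_boundaries(self):
        c = count_transitions([np.array([0, 1]), np.array([1, 0])], 1)
        np.testing.assert_array_equal(c.counts, [[0, 1], [1, 0]])

    def test_total_counts_is_sliding_window_size(self, rng):
        dtrajs = [rng.integers(0, 3, size=n) for n in (50, 30, 7)]
        for lag in (1, 5, 10):
            c = count_transitions(dtrajs, lag)
            expected = sum(max(0, n - lag) for n in (50, 30, 7))
            assert c.counts.sum() == expected

    def test_all_trajectories_too_short(self):
        with pytest.raises(ValueError):
            count_transitions([np.array([0, 1])], 5)


class TestEstimateTransitionMatrix:
    def test_symmetric_counts(self):
        c = CountMatrix(np.array([[1, 1], [1, 1]]), 1, np.array([0, 1]))
        m = estimate_transition_matrix(c)
        np.testing.assert_allclose(m.transition_matrix, [[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(m.stationary, [0.5, 0.5])

    def test_metastable_symmetric_chain(self):
        c = CountMatrix(np.array([[9, 1], [1, 9]]), 1, np.array([0, 1]))
        m = estimate_transition_matrix(c)
        np.testing.assert_allclose(m.transition_matrix, [[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(m.stationary, [0.5, 0.5])

    def test_asymmetric_counts_stationary_by_hand(self):
        # T = [[0.8, 0.2], [0.1, 0.9]]; pi solves 0.2 pi0 = 0.1 pi1
        c = CountMatrix(np.array([[8, 2], [1, 9]]), 1, np.array([0, 1]))
        m = estimate_transition_matrix(c)
        np.testing.assert_allclose(m.stationary, [1.0 / 3.0, 2.0 / 3.0], atol=1e-12)

    def test_spectral_radius_is_one(self, rng):
        dtrajs = sample_dtrajs(uniform_chain(4, 0.8), 3, 500, seed=5)
        m = estimate_transition_matrix(count_transitions(dtrajs, 2))
        assert np.max(np.abs(m.transition_matrix.sum(1) - 1)) <= 1e-12
        assert abs(np.max(np.abs(np.linalg.eigvals(m.transition_matrix))) - 1) <= 1e-10

    def test_scc_restriction_drops_transient_state(self):
        # state 2 is entered never / left always -> not in the largest SCC
        d = np.array([2, 0, 1, 0, 1, 0, 1, 0])
        m = estimate_transition_matrix(count_transitions([d], 1))
        assert set(m.active_states.tolist()) == {0, 1}

    def test_reversible_mode_symmetrizes(self):
        c = CountMatrix(np.array([[5, 3], [1, 7]]), 1, np.array([0, 1]))
        m = estimate_transition_matrix(c, reversible=True)
        pi = m.stationary
        t = m.transition_matrix
        # detailed balance: pi_i T_ij = pi_j T_ji
        assert pi[0] * t[0, 1] == pytest.approx(pi[1] * t[1, 0], rel=1e-10)

    def test_estimator_converges_to_truth(self):
        t_true = uniform_chain(6, 0.9)
        dtrajs = sample_dtrajs(t_true, 12, 10000, seed=3)
        m = estimate_transition_matrix(count_transitions(dtrajs, 1))
        tv = 0.5 * np.abs(m.transition_matrix - t_true).sum(axis=1).max()
        assert tv <= 0.05


class TestStateSummary:
    def _model(self, t):
        n = t.shape[0]
        c = CountMatrix((t * 1000).astype(int), 1, np.arange(n))
        return estimate_transition_matrix(c)

    def test_two_state_top_one_pools_smaller(self):
        m = self._model(np.array([[0.8, 0.2], [0.1, 0.9]]))
        df = state_summary(m, top_m=1)
        pooled = df[df.state == -1]
        assert pooled.population.iloc[0] == pytest.approx(min(m.stationary))

    def test_populations_sum_to_one_with_pool(self):
        m = self._model(np.array([[0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.3, 0.3, 0.4]]))
        df = state_summary(m, top_m=2)
        assert df.population.sum() == pytest.approx(1.0)

    def test_self_and_out_probabilities_read_off(self):
        m = self._model(np.array([[0.9, 0.1], [0.1, 0.9]]))
        df = state_summary(m, top_m=2)
        np.testing.assert_allclose(df.self_transition, [0.9, 0.9])
        np.testing.assert_allclose(df.out_of_state, [0.1, 0.1])


class TestPcaEmbed:
    def test_line_explains_everything(self, rng):
        direction = rng.normal(size=12)
        x = np.outer(rng.normal(size=100), direction)
        _, ratios = pca_embed(x)
        assert ratios[0] == pytest.approx(1.0)

    def test_ratios_nonincreasing_and_bounded(self, rng):
        x = rng.normal(size=(200, 6))
        _, ratios = pca_embed(x, n_components=4)
        assert np.all(np.diff(ratios) <= 1e-12)
        assert np.all(ratios <= 1.0)

    def test_isotropic_gaussian_splits_variance_evenly(self, rng):
        x = rng.normal(size=(20000, 3))
        _, ratios = pca_embed(x)
        np.testing.assert_allclose(ratios, [1 / 3, 1 / 3], atol=0.02)

    def test_stride_reduces_rows(self, rng):
        x = rng.normal(size=(64, 4))
        emb, _ = pca_embed(x, stride=16)
        assert emb.shape[0] == 4
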