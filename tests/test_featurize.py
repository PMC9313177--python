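import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapemsm.featurize import (
    ca_skip_features,
    kabsch_superpose,
    pairwise_distance,
    usr_feature_matrix,
    usr_features,
    usr_reference_points,
)
from shapemsm.trajectory_io import StructureFrame

from conftest import random_rigid_motion


def population_moments(d):
    """Independent oracle: plain population moments of a 1-d sample."""
    d = np.asarray(d, float)
    m = d.mean()
    var = ((d - m) ** 2).mean()
    mu3 = ((d - m) ** 3).mean()
    skew = 0.0 if var == 0 else mu3 / var**1.5
    return m, var, skew


class TestUsrFeatures:
    def test_coincident_atoms_give_all_zero(self):
        f = StructureFrame(np.ones((4, 3)) * 2.5, ("A", "B", "C", "D"))
        np.testing.assert_array_equal(usr_features(f), np.zeros(12))

    def test_collinear_oracle_all_blocks(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        f = StructureFrame(coords, ("A", "B", "C"))
        got = usr_features(f)
        # reference points by inspection: ctd=(1,0,0); cst=atom1;
        # fct=atom0 (first of the two equidistant extremes); ftf=atom2
        refs = usr_reference_points(f)
        assert refs.cst_index == 1 and refs.fct_index == 0 and refs.ftf_index == 2
        expected = []
        for point in [np.array([1.0, 0, 0]), coords[1], coords[0], coords[2]]:
            d = np.linalg.norm(coords - point, axis=1)
            expected.extend(population_moments(d))
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # the ctd block matches the hand-computed values
        np.testing.assert_allclose(
            got[:3], [2.0 / 3.0, 2.0 / 9.0, -1.0 / np.sqrt(2.0)], atol=1e-10
        )

    def test_always_twelve_values(self, rng):
        for n in (1, 2, 7, 100):
            f = StructureFrame(rng.normal(size=(n, 3)), tuple("A" * 1 for _ in range(n)))
            assert usr_features(f).shape == (12,)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(30, 3), scale=5.0)
        names = tuple(f"A{i}" for i in range(30))
        base = usr_features(StructureFrame(coords, names))
        for _ in range(25):
            rot, trans = random_rigid_motion(rng)
            moved = coords @ rot.T + trans
            np.testing.assert_allclose(
                usr_features(StructureFrame(moved, names)), base, atol=1e-8
            )

    def test_atom_reordering_invariance(self, rng):
        coords = rng.normal(size=(20, 3))
        names = tuple(f"A{i}" for i in range(20))
        perm = rng.permutation(20)
        a = usr_features(StructureFrame(coords, names))
        b = usr_features(StructureFrame(coords[perm], tuple(names[i] for i in perm)))
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_vectorized_matches_single_frame(self, rng):
        stack = rng.normal(size=(8, 15, 3))
        mat = usr_feature_matrix(stack)
        for i in range(8):
            f = StructureFrame(stack[i], tuple(f"A{j}" for j in range(15)))
            np.testing.assert_allclose(mat[i], usr_features(f), atol=1e-12)


class TestCaSkip:
    def _frame_with_cas(self, n_ca, rng):
        coords = rng.normal(size=(n_ca, 3))
        return StructureFrame(coords, tuple("CA" for _ in range(n_ca))), coords

    def test_take_one_skip_four(self, rng):
        f, coords = self._frame_with_cas(10, rng)
        out = ca_skip_features(f, skip=4)
        assert out.size == 6  # CA indices {0, 5}
        np.testing.assert_array_equal(out, coords[[0, 5]].ravel())

    def test_skip_zero_keeps_all(self, rng):
        f, coords = self._frame_with_cas(7, rng)
        np.testing.assert_array_equal(ca_skip_features(f, skip=0), coords.ravel())

    def test_skip_beyond_count_keeps_first(self, rng):
        f, coords = self._frame_with_cas(4, rng)
        np.testing.assert_array_equal(ca_skip_features(f, skip=10), coords[0])

    def test_no_ca_atoms_is_an_error(self, rng):
        f = StructureFrame(rng.normal(size=(3, 3)), ("N", "C", "O"))
        with pytest.raises(ValueError, match="no atoms"):
            ca_skip_features(f)


def quaternion_rmsd(a, b):
    """Independent minimum-RMSD oracle via the quaternion key matrix."""
    a = a - a.mean(0)
    b = b - b.mean(0)
    r = b.T @ a
    f = np.array(
        [
            [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1], r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
            [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2], r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
            [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0], -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
            [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0], r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(f).max()
    msd = max(((a * a).sum() + (b * b).sum() - 2.0 * lam) / a.shape[0], 0.0)
    return np.sqrt(msd)


class TestKabsch:
    def test_self_superposition(self, rng):
        a = rng.normal(size=(8, 3))
        rot, trans, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_recovers_rigid_motion(self, rng):
        a = rng.normal(size=(12, 3), scale=4.0)
        r, t = random_rigid_motion(rng)
        b = a @ r.T + t
        rot, trans, rmsd = kabsch_superpose(a, b)
        assert rmsd <= 1e-8
        np.testing.assert_allclose(b @ rot + trans, a, atol=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            _, _, rmsd = kabsch_superpose(a, b)
            assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)

    def test_atom_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestPairwiseDistance:
    def test_identity_symmetry_unit(self, rng):
        u = rng.normal(size=12)
        v = rng.normal(size=12)
        assert pairwise_distance(u, u) == 0.0
        assert pairwise_distance(u, v) == pytest.approx(pairwise_distance(v, u))
        e = np.zeros(12)
        e1 = np.zeros(12)
        e1[0] = 1.0
        assert pairwise_distance(e, e1) == pytest.approx(1.0)

    def test_ca_skip_distance_is_superposed_rmsd(self, rng):
        a = rng.normal(size=(6, 3))
        r, t = random_rigid_motion(rng)
        b = a @ r.T + t
        assert pairwise_distance(a.ravel(), b.ravel(), kind="ca_skip") <= 1e-8

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_usr_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        u, v, w = r.normal(size=(3, 12))
        duw = pairwise_distance(u, w)
        assert duw <= pairwise_distance(u, v) + pairwise_distance(v, w) + 1e-12
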