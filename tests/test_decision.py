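import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sliceforest import (
    DecisionVectors,
    LesionMask,
    common_region,
    diagnose,
    intersect_mask,
    run_filter,
)

binary_vectors = st.lists(st.integers(0, 1), min_size=1, max_size=16).map(np.array)


def brute_force_filter(v, k):
    """Independent oracle: enumerate maximal runs by scanning."""
    v = list(v)
    out = [0] * len(v)
    runs = []
    i = 0
    while i < len(v):
        if v[i] == 1:
            j = i
            while j < len(v) and v[j] == 1:
                j += 1
            if j - i >= k:
                runs.append((i, j - i))
                for t in range(i, j):
                    out[t] = 1
            i = j
        else:
            i += 1
    return out, runs


class TestRunFilter:
    def test_known_example(self):
        r = run_filter([1, 1, 1, 0, 1, 1], 3)
        np.testing.assert_array_equal(r.filtered, [1, 1, 1, 0, 0, 0])
        assert r.runs == [(0, 3)]

    def test_all_zeros(self):
        r = run_filter(np.zeros(9, dtype=int), 4)
        assert not r.filtered.any() and r.runs == []

    @given(v=binary_vectors)
    @settings(max_examples=100, deadline=None)
    def test_k1_is_identity(self, v):
        np.testing.assert_array_equal(run_filter(v, 1).filtered, v)

    @given(v=binary_vectors, k=st.integers(1, 5))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, v, k):
        r = run_filter(v, k)
        expected_filtered, expected_runs = brute_force_filter(v, k)
        np.testing.assert_array_equal(r.filtered, expected_filtered)
        assert r.runs == expected_runs

    @given(v=binary_vectors, k=st.integers(1, 5))
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, v, k):
        once = run_filter(v, k)
        twice = run_filter(once.filtered, k)
        np.testing.assert_array_equal(once.filtered, twice.filtered)
        assert once.runs == twice.runs

    @given(v=binary_vectors, k=st.integers(1, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_k(self, v, k):
        tighter = run_filter(v, k + 1).filtered
        looser = run_filter(v, k).filtered
        assert (tighter <= looser).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            run_filter([0, 2, 1], 2)

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            run_filter([1, 0], 0)


class TestIntersectMask:
    def test_all_ones_full_mask(self):
        mask = intersect_mask(np.ones(2, int), np.ones(2, int), np.ones(2, int))
        assert mask.n_voxels == 8

    def test_any_zero_direction_empties_mask(self):
        mask = intersect_mask(np.ones(3, int), np.zeros(4, int), np.ones(2, int))
        assert mask.is_empty()

    def test_known_outer_product(self):
        mask = intersect_mask(
            np.array([0, 1, 1]), np.array([1, 0]), np.array([1, 1])
        )
        assert mask.n_voxels == 4
        expected = {(1, 0, 0), (1, 0, 1), (2, 0, 0), (2, 0, 1)}
        assert set(map(tuple, np.argwhere(mask.data))) == expected

    def test_agrees_with_triple_loop(self, rng):
        for _ in range(25):
            f = [rng.integers(0, 2, rng.integers(1, 8)) for _ in range(3)]
            mask = intersect_mask(*f).data
            for a in range(len(f[0])):
                for b in range(len(f[1])):
                    for c in range(len(f[2])):
                        assert mask[a, b, c] == f[0][a] * f[1][b] * f[2][c]


class TestDiagnose:
    def _dv(self, runs1, runs2, runs3, lengths=(10, 12, 10)):
        vecs = []
        for runs, n in zip((runs1, runs2, runs3), lengths):
            v = np.zeros(n, dtype=int)
            for start, length in runs:
                v[start : start + length] = 1
            vecs.append(v)
        return DecisionVectors(*vecs)

    def test_runs_of_three_everywhere_positive_at_k3(self):
        dv = self._dv([(0, 3)], [(4, 3)], [(7, 3)])
        assert diagnose(dv, 3) == 1

    def test_one_short_direction_negative(self):
        dv = self._dv([(0, 3)], [(4, 3)], [(7, 2)])
        assert diagnose(dv, 3) == 0

    def test_all_zero_vectors_negative(self):
        dv = self._dv([], [], [])
        for k in (1, 2, 3):
            assert diagnose(dv, k) == 0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_monotone_non_increasing_in_k(self, seed):
        rng = np.random.default_rng(seed)
        dv = DecisionVectors(*(rng.integers(0, 2, n) for n in (8, 10, 9)))
        values = [diagnose(dv, k) for k in range(1, 6)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestCommonRegion:
    def test_single_mask_identity(self, rng):
        m = LesionMask((rng.random((3, 4, 3)) > 0.5).astype(np.uint8))
        np.testing.assert_array_equal(common_region([m]).data, m.data)

    def test_empty_mask_absorbs(self, rng):
        m = LesionMask((rng.random((3, 3, 3)) > 0.3).astype(np.uint8))
        empty = LesionMask.empty((3, 3, 3))
        assert common_region([m, empty]).is_empty()

    def test_matches_voxelwise_minimum(self, rng):
        a = LesionMask((rng.random((4, 4, 4)) > 0.5).astype(np.uint8))
        b = LesionMask((rng.random((4, 4, 4)) > 0.5).astype(np.uint8))
        out = common_region([a, b]).data
        for idx in np.ndindex(4, 4, 4):
            assert out[idx] == min(a.data[idx], b.data[idx])

    def test_commutative_and_shrinking(self, rng):
        masks = [
            LesionMask((rng.random((3, 3, 3)) > 0.4).astype(np.uint8)) for _ in range(3)
        ]
        fwd = common_region(masks)
        rev = common_region(masks[::-1])
        np.testing.assert_array_equal(fwd.data, rev.data)
        partial = common_region(masks[:2])
        assert fwd.n_voxels <= partial.n_voxels

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            common_region([LesionMask.empty((2, 2, 2)), LesionMask.empty((3, 2, 2))])
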