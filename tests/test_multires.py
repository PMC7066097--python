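"""Multiresolution decomposition tests: partitions, nesting, transfer maps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import cdist

from ramus import (
    build_decomposition,
    build_source_space,
    partition_nearest,
    prolongate,
    restrict_estimate,
    restrict_leadfield,
)
from ramus.errors import ParameterError
from ramus.multires import MultiresolutionDecomposition


@pytest.fixture(scope="module")
def space_1k():
    return build_source_space(1000, 0.0, 80.0, seed=21)


class TestPartitionNearest:
    def test_all_positions_as_centers_gives_singletons(self, space_1k):
        labels = partition_nearest(space_1k.positions, space_1k.positions)
        np.testing.assert_array_equal(labels, np.arange(space_1k.n_positions))

    def test_single_center(self, space_1k):
        labels = partition_nearest(space_1k.positions, space_1k.positions[:1])
        assert np.all(labels == 0)

    @given(st.integers(min_value=0, max_value=500))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((6, 3))
        centers = pts[rng.choice(6, size=2, replace=False)]
        got = partition_nearest(pts, centers)
        want = np.argmin(cdist(pts, centers), axis=1)
        np.testing.assert_array_equal(got, want)

    def test_empty_centers_raises(self, space_1k):
        with pytest.raises(ParameterError):
            partition_nearest(space_1k.positions, np.empty((0, 3)))


class TestBuildDecomposition:
    def test_level_counts_match_sparsity_rule(self):
        space = build_source_space(10000, 0.0, 85.0, seed=2)
        dec = build_decomposition(space, 3, 8.0, seed=0)
        assert [lvl.n_centers for lvl in dec.levels] == [156, 1250, 10000]

    def test_partition_and_nesting_invariants(self, space_1k):
        dec = build_decomposition(space_1k, 3, 8.0, seed=5)
        K = space_1k.n_positions
        for lvl in dec.levels:
            # disjoint cover: every fine position gets exactly one label
            assert lvl.assignment.shape == (K,)
            assert lvl.assignment.min() >= 0
            assert lvl.assignment.max() < lvl.n_centers
            assert lvl.subset_sizes().sum() == K
            # each center belongs to its own subset
            np.testing.assert_array_equal(
                lvl.assignment[lvl.center_indices], np.arange(lvl.n_centers)
            )
        for lo, hi in zip(dec.levels[:-1], dec.levels[1:]):
            assert set(lo.center_indices) <= set(hi.center_indices)

    def test_finest_level_is_identity(self, space_1k):
        dec = build_decomposition(space_1k, 2, 4.0, seed=1)
        assert dec.levels[-1].is_identity

    def test_single_level_is_full_space(self, space_1k):
        dec = build_decomposition(space_1k, 1, 8.0, seed=3)
        assert dec.n_levels == 1 and dec.levels[0].is_identity

    def test_sparsity_one_degenerates(self, space_1k):
        dec = build_decomposition(space_1k, 3, 1.0, seed=4)
        assert all(lvl.is_identity for lvl in dec.levels)

    def test_mean_subset_size_tracks_sparsity(self, space_1k):
        dec = build_decomposition(space_1k, 3, 8.0, seed=6)
        for lvl, expect in zip(dec.levels, [64.0, 8.0, 1.0]):
            mean_size = lvl.subset_sizes().mean()
            assert abs(mean_size - expect) <= 0.2 * expect + 1e-9

    def test_too_coarse_raises(self, space_1k):
        with pytest.raises(ParameterError):
            build_decomposition(space_1k, 6, 8.0, seed=0)

    def test_json_round_trip(self, space_1k):
        dec = build_decomposition(space_1k, 3, 8.0, seed=9)
        replay = MultiresolutionDecomposition.from_json(dec.to_json(), space_1k)
        for a, b in zip(dec.levels, replay.levels):
            np.testing.assert_array_equal(a.center_indices, b.center_indices)
            np.testing.assert_array_equal(a.assignment, b.assignment)


@pytest.fixture(scope="module")
def level(space_1k):
    return build_decomposition(space_1k, 3, 8.0, seed=11).levels[0]


class TestTransferMaps:

    def test_prolongate_constant_preserved(self, level):
        x_c = np.tile([1.5, -2.0, 0.5], level.n_centers)
        x_f = prolongate(x_c, level)
        np.testing.assert_array_equal(x_f.reshape(-1, 3)[0], [1.5, -2.0, 0.5])
        assert np.unique(x_f.reshape(-1, 3), axis=0).shape[0] == 1

    def test_restrict_is_left_inverse_of_prolongate(self, level):
        rng = np.random.default_rng(0)
        x_c = rng.standard_normal(3 * level.n_centers)
        np.testing.assert_allclose(
            restrict_estimate(prolongate(x_c, level), level), x_c, rtol=1e-12
        )

    def test_restrict_is_subset_mean(self, space_1k):
        lvl = build_decomposition(space_1k, 2, 8.0, seed=2).levels[0]
        j = int(np.argmax(lvl.subset_sizes()))
        members = np.where(lvl.assignment == j)[0]
        assert members.size >= 2
        # values 1 and 3 plus a background of 2 average to exactly 2
        x_f = np.zeros(3 * space_1k.n_positions)
        x_f[3 * members] = 2.0
        x_f[3 * members[0]] = 1.0
        x_f[3 * members[1]] = 3.0
        x_c = restrict_estimate(x_f, lvl)
        assert x_c[3 * j] == pytest.approx(2.0)

    def test_leadfield_restriction_consistency(self, level):
        # sum-mode identity: L_coarse x_c = L_fine P(x_c); mean mode is the
        # same matrix with columns divided by the subset sizes
        rng = np.random.default_rng(5)
        L_fine = rng.standard_normal((7, 3 * level.n_fine))
        x_c = rng.standard_normal(3 * level.n_centers)
        L_sum = restrict_leadfield(L_fine, level, mode="sum")
        np.testing.assert_allclose(
            L_sum @ x_c, L_fine @ prolongate(x_c, level), rtol=1e-12
        )
        L_mean = restrict_leadfield(L_fine, level, mode="mean")
        sizes = np.repeat(level.subset_sizes(), 3)
        np.testing.assert_allclose(L_mean * sizes[None, :], L_sum, rtol=1e-12)

    def test_column_mass_conservation(self, level):
        rng = np.random.default_rng(6)
        L_fine = rng.standard_normal((5, 3 * level.n_fine))
        L_sum = restrict_leadfield(L_fine, level, mode="sum")
        for c in range(3):
            np.testing.assert_allclose(
                L_sum[:, c::3].sum(axis=1), L_fine[:, c::3].sum(axis=1), rtol=1e-10
            )

    def test_adjoint_consistency(self, level):
        # <P x_c, x_f> = <x_c, |B| restrict(x_f)> componentwise
        rng = np.random.default_rng(7)
        x_c = rng.standard_normal(3 * level.n_centers)
        x_f = rng.standard_normal(3 * level.n_fine)
        lhs = prolongate(x_c, level) @ x_f
        sizes = np.repeat(level.subset_sizes(), 3)
        rhs = x_c @ (sizes * restrict_estimate(x_f, level))
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_identity_level_round_trips(self, space_1k):
        lvl = build_decomposition(space_1k, 1, 2.0, seed=0).levels[0]
        rng = np.random.default_rng(1)
        x = rng.standard_normal(3 * space_1k.n_positions)
        np.testing.assert_array_equal(prolongate(x, lvl), x)
        np.testing.assert_array_equal(restrict_estimate(x, lvl), x)
        L = rng.standard_normal((4, x.size))
        np.testing.assert_array_equal(restrict_leadfield(L, lvl), L)
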