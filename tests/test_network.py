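"""Network construction: Pearson matrices, significance thresholding,
Fisher averaging, backbone extraction and seed maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fconn.network import (
    ConnectivityMatrix,
    WeightedNetwork,
    bonferroni_edge_threshold,
    extract_backbone,
    group_mean_network,
    pearson_connectivity,
    seed_connectivity_map,
    threshold_to_weighted_network,
)


class TestPearson:
    def test_identical_columns_r_one(self, rng):
        x = rng.standard_normal(50)
        cm = pearson_connectivity(np.column_stack([x, x]))
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_negated_column_r_minus_one(self, rng):
        x = rng.standard_normal(50)
        cm = pearson_connectivity(np.column_stack([x, -x]))
        assert cm.r[0, 1] == pytest.approx(-1.0)

    def test_quadrature_sinusoids_uncorrelated(self):
        t = np.arange(120)
        ts = np.column_stack([np.sin(2 * np.pi * 5 * t / 120),
                              np.cos(2 * np.pi * 5 * t / 120)])
        assert abs(pearson_connectivity(ts).r[0, 1]) < 1e-10

    def test_nan_input_rejected(self):
        ts = np.ones((20, 3))
        ts[4, 1] = np.nan
        with pytest.raises(ValueError):
            pearson_connectivity(ts)

    def test_constant_column_warns_and_zeroes(self, rng):
        ts = np.column_stack([rng.standard_normal(30), np.full(30, 2.0)])
        with pytest.warns(UserWarning):
            cm = pearson_connectivity(ts)
        assert cm.r[0, 1] == 0.0


class TestThresholding:
    def test_bonferroni_arithmetic_at_1024(self):
        assert bonferroni_edge_threshold(1024) == pytest.approx(
            0.05 / 523_776, rel=1e-12)
        assert 1024 * 1023 // 2 == 523_776

    def test_zero_matrix_gives_empty_network(self):
        cm = ConnectivityMatrix(np.eye(8), 100)
        net = threshold_to_weighted_network(cm)
        assert net.k == 0

    def test_strong_negative_correlation_excluded(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = -0.99
        r[0, 2] = r[2, 0] = 0.99
        net = threshold_to_weighted_network(ConnectivityMatrix(r, 100))
        assert list(zip(net.i, net.j)) == [(0, 2)]

    def test_insufficient_df_rejected(self):
        cm = ConnectivityMatrix(np.eye(4), 4)
        with pytest.raises(ValueError):
            threshold_to_weighted_network(cm)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.001, 0.2), st.floats(0.2, 0.9))
    def test_monotone_in_alpha(self, seed, a1, a2):
        rng = np.random.default_rng(seed)
        ts = rng.standard_normal((40, 10))
        cm = pearson_connectivity(ts)
        small = threshold_to_weighted_network(cm, alpha=min(a1, a2))
        large = threshold_to_weighted_network(cm, alpha=max(a1, a2))
        small_set = set(zip(small.i.tolist(), small.j.tolist()))
        large_set = set(zip(large.i.tolist(), large.j.tolist()))
        assert small_set <= large_set


class TestGroupAveraging:
    def test_single_matrix_identity(self, rng):
        ts = rng.standard_normal((60, 6))
        cm = pearson_connectivity(ts)
        out = group_mean_network([cm])
        assert np.allclose(out.r, cm.r, atol=1e-12)

    def test_equal_matrices_average_to_same(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.5
        cm = ConnectivityMatrix(r, 50)
        out = group_mean_network([cm, cm])
        assert out.r[0, 1] == pytest.approx(0.5)

    def test_z_averaging_differs_from_r_averaging(self):
        r1, r2 = np.eye(2), np.eye(2)
        r1[0, 1] = r1[1, 0] = 0.2
        r2[0, 1] = r2[1, 0] = 0.6
        out = group_mean_network(
            [ConnectivityMatrix(r1, 50), ConnectivityMatrix(r2, 50)])
        expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.6)) / 2)
        assert out.r[0, 1] == pytest.approx(expected, abs=1e-12)
        assert out.r[0, 1] != pytest.approx(0.4, abs=1e-3)


def exhaustive_backbone_oracle(a, alpha):
    """Independent re-derivation of the strict-rank retention rule."""
    n = a.shape[0]
    kept = set()
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j] <= 0:
                continue
            for node, other in ((i, j), (j, i)):
                inc = a[node][a[node] > 0]
                p = np.sum(inc > a[i, j]) / inc.size
                if p <= alpha:
                    kept.add((i, j))
    return kept


class TestBackbone:
    def test_star_edges_all_retained(self):
        a = np.zeros((6, 6))
        a[0, 1:] = a[1:, 0] = [0.9, 0.8, 0.7, 0.6, 0.5]
        net = extract_backbone(ConnectivityMatrix(a + np.eye(6), 100))
        # each leaf's only edge is its top edge -> kept through the leaf
        assert net.k == 5

    def test_two_scale_planted_structure(self):
        # two 5-cliques (w=0.8), two connector nodes bridging them (w=0.2),
        # cross-clique noise edges (w=0.05)
        n = 12
        a = np.zeros((n, n))
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i < j:
                        a[i, j] = a[j, i] = 0.8
        for c, (x, y) in ((10, (0, 5)), (11, (1, 6))):
            a[c, x] = a[x, c] = 0.2
            a[c, y] = a[y, c] = 0.2
        a[2, 7] = a[7, 2] = 0.05
        a[3, 8] = a[8, 3] = 0.05
        cm = ConnectivityMatrix(a + np.eye(n), 100)
        net = extract_backbone(cm, local_alpha=0.05)
        kept = set(zip(net.i.tolist(), net.j.tolist()))
        oracle = exhaustive_backbone_oracle(a, 0.05)
        assert kept == oracle
        assert all(e in kept for e in [(0, 10), (5, 10), (1, 11), (6, 11)])
        assert (2, 7) not in kept and (3, 8) not in kept

    def test_all_negative_matrix_rejected(self):
        r = -0.5 * np.ones((4, 4)) + 1.5 * np.eye(4)
        with pytest.raises(ValueError):
            extract_backbone(ConnectivityMatrix(r, 100))


class TestSeedMap:
    def test_self_correlation_one_and_matches_matrix_row(self, rng):
        ts = rng.standard_normal((80, 6))
        r_map = seed_connectivity_map(ts, 2)
        assert r_map[2] == pytest.approx(1.0)
        cm = pearson_connectivity(ts)
        assert np.allclose(r_map, cm.r[2], atol=1e-10)

    def test_constant_seed_rejected(self, rng):
        ts = rng.standard_normal((30, 3))
        ts[:, 0] = 5.0
        with pytest.raises(ValueError):
            seed_connectivity_map(ts, 0)
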