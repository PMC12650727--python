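import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynetsim.core import AlignmentError, DynamicNetwork, ValidationError
from dynetsim.indices import (
    ZeroVarianceError,
    corr_norm,
    dice,
    dnes,
    dns,
    jaccard,
    pearson_corr,
    sd_decomposition,
    spectral_similarity,
    traditional_dynamic_similarity,
)

from conftest import net_from_edges, random_net, single_edge_net


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_corr([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_anti_correlation(self):
        assert pearson_corr([1, 2], [2, 1]) == pytest.approx(-1.0)

    def test_hand_value(self):
        # means 2.5/2.5, cross products sum 4, each variance sum 5 -> 0.8
        assert pearson_corr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson_corr([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 2], [1, 2, 3])


class TestDNS:
    def test_self_similarity(self, rng):
        net = random_net(rng, 4, 3)
        assert dns(net, net).value == pytest.approx(1.0)

    def test_amplitude_halving(self):
        a = single_edge_net([1.0, 2.0])
        b = single_edge_net([2.0, 4.0])
        iv = dns(a, b)
        assert iv.value == pytest.approx(0.75)
        assert iv.components["corr_term"] == pytest.approx(1.0)
        assert iv.components["sd_ratio"] == pytest.approx(0.5)

    def test_anti_correlated(self):
        assert dns(single_edge_net([1.0, 2.0]), single_edge_net([2.0, 1.0])).value == pytest.approx(0.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(AlignmentError):
            dns(random_net(rng, 3, 2), random_net(rng, 4, 2))

    def test_strict_labels(self, rng):
        a = random_net(rng, 3, 2)
        b = DynamicNetwork(a.weights.copy(), node_labels=["x", "y", "z"])
        dns(a, b)  # positional alignment fine
        with pytest.raises(AlignmentError):
            dns(a, b, strict_labels=True)

    def test_both_constant_equal(self):
        a = single_edge_net([1.0, 1.0])
        assert dns(a, a).value == pytest.approx(1.0)

    def test_both_constant_unequal(self):
        assert dns(single_edge_net([1.0, 1.0]), single_edge_net([2.0, 2.0])).value == pytest.approx(0.5)

    def test_one_constant(self):
        assert dns(single_edge_net([1.0, 1.0]), single_edge_net([1.0, 2.0])).value == pytest.approx(0.5)

    @pytest.mark.parametrize("c", [0.2, 0.5, 1.0, 2.0, 7.5])
    def test_amplitude_law(self, rng, c):
        # DNS(A, cA) = (1 + min(c, 1/c)) / 2 exactly
        net = random_net(rng, 5, 4)
        scaled = net.with_weights(c * net.weights)
        expected = 0.5 * (1.0 + min(c, 1.0 / c))
        assert dns(net, scaled).value == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_naive_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        T = int(rng.integers(1, 6))
        if T * n * (n - 1) // 2 < 2:
            T = 2  # avoid the degenerate length-1 long vector
        a, b = random_net(rng, n, T), random_net(rng, n, T)

        def naive_dns(x, y):
            va, vb = [], []
            for t in range(T):
                for i in range(n):
                    for j in range(i + 1, n):
                        va.append(x.weights[t, i, j])
                        vb.append(y.weights[t, i, j])
            va, vb = np.array(va), np.array(vb)
            corr = np.corrcoef(va, vb)[0, 1]
            ratio = min(va.std(), vb.std()) / max(va.std(), vb.std())
            return 0.5 * (corr * ratio + 1.0)

        assert dns(a, b).value == pytest.approx(naive_dns(a, b), abs=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_full_matrix_vectorization_equivalent(self, seed):
        # duplicating each edge (lower triangle) leaves DNS unchanged
        rng = np.random.default_rng(seed)
        a, b = random_net(rng, 4, 3), random_net(rng, 4, 3)
        iu, ju = np.tril_indices(4, k=-1)
        va = np.concatenate([a.weights[:, iu, ju].ravel(), a.weights[:, ju, iu].ravel()])
        vb = np.concatenate([b.weights[:, iu, ju].ravel(), b.weights[:, ju, iu].ravel()])
        corr = np.corrcoef(va, vb)[0, 1]
        ratio = min(va.std(), vb.std()) / max(va.std(), vb.std())
        assert dns(a, b).value == pytest.approx(0.5 * (corr * ratio + 1.0), abs=1e-10)


class TestSDDecomposition:
    def test_static_network_no_between(self, rng):
        net = random_net(rng, 4, 1)
        rep = net.with_weights(np.repeat(net.weights, 3, axis=0))
        within, between, total = sd_decomposition(rep)
        assert between == pytest.approx(0.0, abs=1e-12)
        assert within == pytest.approx(total, abs=1e-12)

    def test_uniform_snapshots_no_within(self):
        # each timepoint a constant matrix c_t * ones
        net = net_from_edges(np.array([[1.0, 1, 1], [2, 2, 2], [5, 5, 5]]), 3)
        within, between, total = sd_decomposition(net)
        assert within == pytest.approx(0.0, abs=1e-12)
        assert between == pytest.approx(total, abs=1e-12)

    def test_single_edge_hand_value(self):
        within, between, total = sd_decomposition(single_edge_net([1.0, 3.0]))
        assert within == pytest.approx(0.0, abs=1e-12)
        assert between == pytest.approx(1.0)
        assert total == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_conserves_total_variance(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, int(rng.integers(2, 7)), int(rng.integers(1, 8)))
        within, between, total = sd_decomposition(net)
        from dynetsim.core import flatten_long_vector

        assert within + between == pytest.approx(total, abs=1e-10)
        assert total == pytest.approx(np.var(flatten_long_vector(net).values), abs=1e-10)


class TestDNES:
    def test_self_similarity(self, rng):
        net = random_net(rng, 4, 5)
        assert dnes(net, net).value == pytest.approx(1.0)

    def test_single_edge_amplitude(self):
        iv = dnes(single_edge_net([1.0, 2.0, 3.0]), single_edge_net([2.0, 4.0, 6.0]))
        assert iv.value == pytest.approx(0.75)
        np.testing.assert_allclose(iv.components["per_edge_S_i"], [0.5])

    def test_mixed_edges(self):
        # edge (0,1) identical (S=1), edge (0,2) anti-phase equal sd
        # (S=-1); restricted to those two edges, DNES = (0 + 1)/2
        a = net_from_edges(np.array([[1.0, 1.0, 0], [2, 2, 0], [3, 3, 0]]), 3)
        b = net_from_edges(np.array([[1.0, 3.0, 0], [2, 2, 0], [3, 1, 0]]), 3)
        assert dnes(a, b, edges=[(0, 1), (0, 2)]).value == pytest.approx(0.5)

    def test_edge_subset_restriction(self, rng):
        a, b = random_net(rng, 4, 5), random_net(rng, 4, 5)
        full = dnes(a, b).value
        sub = dnes(a, b, edges=[(0, 1)]).value
        s1 = dnes(a, b).components["per_edge_S_i"][0]
        assert sub == pytest.approx(0.5 * (s1 + 1.0))
        assert sub != pytest.approx(full)

    def test_single_timepoint_rejected(self, rng):
        net = random_net(rng, 3, 1)
        with pytest.raises(ValidationError, match="2 timepoints"):
            dnes(net, net)

    def test_t2_allowed(self, rng):
        a, b = random_net(rng, 3, 2), random_net(rng, 3, 2)
        v = dnes(a, b).value
        assert 0.0 <= v <= 1.0

    def test_node_relabeling_invariance(self, rng):
        a, b = random_net(rng, 5, 4), random_net(rng, 5, 4)
        perm = rng.permutation(5)
        ap = a.with_weights(a.weights[:, perm][:, :, perm])
        bp = b.with_weights(b.weights[:, perm][:, :, perm])
        assert dnes(ap, bp).value == pytest.approx(dnes(a, b).value, abs=1e-12)
        assert dns(ap, bp).value == pytest.approx(dns(a, b).value, abs=1e-12)


class TestTemporalPermutation:
    def test_same_permutation_invariant(self, rng):
        # Pearson and sigma are order-free, hence shuffling only one
        # network (experiment 6) is what breaks similarity.
        a, b = random_net(rng, 4, 6), random_net(rng, 4, 6)
        perm = rng.permutation(6)
        ap, bp = a.with_weights(a.weights[perm]), b.with_weights(b.weights[perm])
        assert dns(ap, bp).value == pytest.approx(dns(a, b).value, abs=1e-12)
        assert dnes(ap, bp).value == pytest.approx(dnes(a, b).value, abs=1e-12)


def _bin_snap(rng, n, p=0.5):
    mat = (rng.random((n, n)) < p).astype(float)
    mat = np.triu(mat, k=1)
    return mat + mat.T


class TestBinaryIndices:
    def test_identical(self, rng):
        snap = _bin_snap(rng, 6)
        assert dice(snap, snap) == pytest.approx(1.0)
        assert jaccard(snap, snap) == pytest.approx(1.0)

    def test_hand_values(self):
        # E_A = {e1, e2}, E_B = {e2, e3} over 4 nodes
        a = np.zeros((4, 4)); b = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1; a[0, 2] = a[2, 0] = 1
        b[0, 2] = b[2, 0] = 1; b[0, 3] = b[3, 0] = 1
        assert dice(a, b) == pytest.approx(0.5)
        assert jaccard(a, b) == pytest.approx(1.0 / 3.0)

    def test_disjoint(self):
        a = np.zeros((3, 3)); b = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1
        b[1, 2] = b[2, 1] = 1
        assert dice(a, b) == pytest.approx(0.0)
        assert jaccard(a, b) == pytest.approx(0.0)

    def test_both_empty(self):
        empty = np.zeros((3, 3))
        assert dice(empty, empty) == 1.0
        assert jaccard(empty, empty) == 1.0

    def test_non_binary_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        with pytest.raises(ValidationError, match="binary"):
            dice(a, a)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_jaccard_dice_identity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _bin_snap(rng, 6), _bin_snap(rng, 6)
        dsc = dice(a, b)
        assert jaccard(a, b) == pytest.approx(dsc / (2.0 - dsc), abs=1e-12)


class TestSpectral:
    def test_identical(self, rng):
        snap = _bin_snap(rng, 5)
        assert spectral_similarity(snap, snap) == pytest.approx(1.0)

    def test_single_edge_vs_empty(self):
        # spectra {0, 2} vs {0, 0}: distance 2, norm 2 -> similarity 0
        edge = np.array([[0.0, 1], [1, 0]])
        assert spectral_similarity(edge, np.zeros((2, 2))) == pytest.approx(0.0)

    def test_isomorphic_graphs(self, rng):
        snap = _bin_snap(rng, 6)
        perm = rng.permutation(6)
        assert spectral_similarity(snap, snap[perm][:, perm]) == pytest.approx(1.0, abs=1e-9)

    def test_both_empty(self):
        assert spectral_similarity(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_normalized_laplacian_spectrum_range(self, rng):
        from dynetsim.indices import normalized_laplacian

        for _ in range(10):
            snap = _bin_snap(rng, 7)
            ev = np.linalg.eigvalsh(normalized_laplacian(snap))
            assert ev.min() >= -1e-9 and ev.max() <= 2.0 + 1e-9


class TestCorrNorm:
    def test_identical(self, rng):
        snap = _bin_snap(rng, 5)
        assert corr_norm(snap, snap) == pytest.approx(1.0)

    def test_anti_correlated(self):
        a = np.zeros((3, 3)); a[0, 1] = a[1, 0] = 1.0
        b = 1.0 - a; np.fill_diagonal(b, 0.0)
        assert corr_norm(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # upper triangles [1,2,3,4] vs [1,3,2,4]: corr 0.8 -> 0.9
        def snap(vals):
            m = np.zeros((4, 4))
            iu, ju = np.triu_indices(4, k=1)
            m[iu[:4], ju[:4]] = vals
            m[ju[:4], iu[:4]] = vals
            return m

        a = snap([1, 2, 3, 4]); b = snap([1, 3, 2, 4])
        iu, ju = np.triu_indices(4, k=1)
        corr = np.corrcoef(a[iu, ju], b[iu, ju])[0, 1]
        assert corr_norm(a, b) == pytest.approx(0.5 * (1 + corr))


class TestTraditionalDynamic:
    def test_t1_equals_snapshot(self, rng):
        a, b = random_net(rng, 4, 1), random_net(rng, 4, 1)
        assert traditional_dynamic_similarity(a, b, "corr") == pytest.approx(
            corr_norm(a.snapshot(0), b.snapshot(0))
        )

    def test_identical_networks(self, rng):
        series = (random_net(rng, 4, 3).weights > 1.0).astype(float)
        net = DynamicNetwork(series)
        for name in ("dice", "jaccard", "spectral", "corr"):
            assert traditional_dynamic_similarity(net, net, name) == pytest.approx(1.0)

    def test_mean_over_timepoints(self):
        # per-timepoint dice {1.0, 0.5} -> 0.75
        a = np.zeros((2, 4, 4)); b = np.zeros((2, 4, 4))
        for t in range(2):
            a[t, 0, 1] = a[t, 1, 0] = 1
            a[t, 0, 2] = a[t, 2, 0] = 1
        b[0] = a[0]
        b[1, 0, 1] = b[1, 1, 0] = 1
        b[1, 0, 3] = b[1, 3, 0] = 1
        na, nb = DynamicNetwork(a), DynamicNetwork(b)
        assert traditional_dynamic_similarity(na, nb, "dice") == pytest.approx(0.75)

    def test_unknown_index(self, rng):
        with pytest.raises(ValueError, match="unknown snapshot index"):
            traditional_dynamic_similarity(random_net(rng, 3, 2), random_net(rng, 3, 2), "cosine")


class TestSymmetryAndRange:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_net(rng, 4, 4), random_net(rng, 4, 4)
        ab, ba = dns(a, b).value, dns(b, a).value
        assert ab == pytest.approx(ba, abs=1e-12) and 0.0 <= ab <= 1.0
        ab, ba = dnes(a, b).value, dnes(b, a).value
        assert ab == pytest.approx(ba, abs=1e-12) and 0.0 <= ab <= 1.0
        sa = (a.weights[0] > 1.0).astype(float)
        sb = (b.weights[0] > 1.0).astype(float)
        for fn in (dice, jaccard, spectral_similarity):
            assert fn(sa, sb) == pytest.approx(fn(sb, sa), abs=1e-12)
            assert 0.0 <= fn(sa, sb) <= 1.0
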