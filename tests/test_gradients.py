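import logging

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from connectograd.gradients import (GradientMap, align_sign, build_graph,
                                    compute_fingerprints,
                                    connectopic_gradients, eta_squared,
                                    group_gradient, laplacian_eigenmaps,
                                    orient_to_axis, similarity_matrix)
from connectograd.io import BoldData
from conftest import raw_fingerprints


def shape_cos(a, b):
    """|cos angle| between mean-centered vectors (normalization-free)."""
    a = a - a.mean()
    b = b - b.mean()
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


class TestEtaSquared:
    def test_identical_vectors_give_one(self, rng):
        a = rng.standard_normal(10)
        assert eta_squared(a, a) == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        # pair means (0.5, 0.5), grand mean 0.5 -> numerator == denominator
        assert eta_squared([0.0, 1.0], [1.0, 0.0]) == pytest.approx(0.0)

    def test_symmetric_and_bounded_over_random_pairs(self, rng):
        for _ in range(1000):
            a, b = rng.standard_normal((2, 6))
            s = eta_squared(a, b)
            assert 0.0 <= s <= 1.0
            assert s == pytest.approx(eta_squared(b, a), abs=1e-12)

    def test_degenerate_equal_constants_give_one(self):
        assert eta_squared([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            eta_squared([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (2, 5),
                      elements=st.floats(-10, 10, allow_nan=False)))
    def test_matrix_agrees_with_pairwise_scalar(self, f):
        f = f + np.arange(10).reshape(2, 5) * 1e-3  # avoid degenerate pairs
        s = similarity_matrix(f)
        # the matrix path expands ||a-b||^2 via inner products, so agreement
        # with the direct scalar formula is limited by cancellation error
        assert s[0, 1] == pytest.approx(eta_squared(f[0], f[1]), abs=1e-8)
        assert s[0, 0] == 1.0 and s[1, 1] == 1.0


class TestFingerprints:
    def test_svd_compression_preserves_eta_squared(self, small_bold_pair):
        roi, tgt = small_bold_pair
        fp = compute_fingerprints(roi, tgt, variance_kept=1.0)
        s_svd = similarity_matrix(fp)
        s_raw = similarity_matrix(raw_fingerprints(roi, tgt))
        assert np.abs(s_svd - s_raw).max() < 1e-6

    def test_rank_bookkeeping_on_rank2_target(self, small_bold_pair, rng):
        roi, tgt = small_bold_pair
        sig = rng.standard_normal((50, 2))
        mix = rng.standard_normal((2, tgt.n_voxels))
        tgt2 = BoldData(tgt.grid, tgt.mask, sig @ mix)
        fp = compute_fingerprints(roi, tgt2, variance_kept=1.0)
        assert fp.n_components == 2

    def test_roi_voxel_equal_to_network_signal_loads_one_component(
            self, small_bold_pair, rng):
        roi, tgt = small_bold_pair
        # centered, in-sample-orthogonal signals so the SVD recovers them exactly
        sig = rng.standard_normal((50, 2))
        sig -= sig.mean(axis=0)
        sig[:, 1] -= (sig[:, 0] @ sig[:, 1]) / (sig[:, 0] @ sig[:, 0]) * sig[:, 0]
        # one strong network (many voxels), one weak
        mix = np.zeros((2, tgt.n_voxels))
        mix[0, :20] = 1.0
        mix[1, 20:] = 0.6
        tgt2 = BoldData(tgt.grid, tgt.mask, sig @ mix)
        series = roi.series.copy()
        series[:, 0] = sig[:, 0]
        roi2 = BoldData(roi.grid, roi.mask, series)
        f = compute_fingerprints(roi2, tgt2, 1.0).components[0]
        assert abs(f[1]) < 1e-8 * abs(f[0])  # collinear with component 1

    def test_mismatched_length_rejected(self, small_bold_pair):
        roi, tgt = small_bold_pair
        short = BoldData(tgt.grid, tgt.mask, tgt.series[:-1])
        with pytest.raises(ValueError, match="T="):
            compute_fingerprints(roi, short)

    def test_all_zero_target_rejected(self, small_bold_pair):
        roi, tgt = small_bold_pair
        flat = BoldData(tgt.grid, tgt.mask, np.zeros_like(tgt.series))
        with pytest.raises(ValueError, match="all zero"):
            compute_fingerprints(roi, flat)

    def test_variance_kept_bounds(self, small_bold_pair):
        roi, tgt = small_bold_pair
        with pytest.raises(ValueError):
            compute_fingerprints(roi, tgt, variance_kept=0.0)


class TestBuildGraph:
    def test_triangle_connected_at_k1(self):
        s = np.full((3, 3), 0.9)
        np.fill_diagonal(s, 1.0)
        w, k = build_graph(s, k_neighbors=1)
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components
        assert connected_components(csr_matrix(w), directed=False)[0] == 1

    def test_chain_similarity_yields_chain_adjacency(self):
        n = 5
        s = np.eye(n)
        for i in range(n - 1):
            s[i, i + 1] = s[i + 1, i] = 0.8
        s[s == 0] = 0.1
        np.fill_diagonal(s, 1.0)
        w, _ = build_graph(s, k_neighbors=1)
        expected = (np.abs(np.subtract.outer(range(n), range(n))) == 1)
        assert np.array_equal(w > 0, expected)
        np.testing.assert_allclose(w[w > 0], 0.8)

    def test_disconnected_escalates_k_and_logs(self, caplog):
        # two tight triangles, weak cross-links
        s = np.full((6, 6), 0.05)
        for block in (slice(0, 3), slice(3, 6)):
            s[block, block] = 0.9
        np.fill_diagonal(s, 1.0)
        with caplog.at_level(logging.INFO, logger="connectograd"):
            w, k_used = build_graph(s, k_neighbors=1)
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components
        assert connected_components(csr_matrix(w), directed=False)[0] == 1
        assert k_used > 1
        assert "escalated" in caplog.text

    def test_dense_mode_keeps_offdiagonal_similarity(self):
        s = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.6], [0.2, 0.6, 1.0]])
        w, k = build_graph(s, dense=True)
        assert k == 0
        np.testing.assert_allclose(np.diag(w), 0.0)
        np.testing.assert_allclose(w[0, 1], 0.4)

    def test_invalid_similarity_rejected(self):
        with pytest.raises(ValueError):
            build_graph(np.array([[1.0, 2.0], [2.0, 1.0]]), 1)  # entries > 1


class TestLaplacianEigenmaps:
    def path_graph(self, n=10):
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        return w

    def test_path_graph_dominant_gradient_is_monotone(self):
        g = laplacian_eigenmaps(self.path_graph(), 1)[0]
        d = np.diff(g.values)
        assert np.all(d > 0) or np.all(d < 0)
        assert g.values.min() == 0.0 and g.values.max() == 1.0

    @pytest.mark.parametrize("n_nodes,k", [(20, 4), (80, 6), (150, 8)])
    def test_matches_dense_generalized_eigensolver(self, n_nodes, k, rng):
        f = rng.standard_normal((n_nodes, 12))
        w, _ = build_graph(similarity_matrix(f), k)
        grads = laplacian_eigenmaps(w, 3)
        deg = np.diag(w.sum(axis=1))
        evals, evecs = sla.eigh(deg - w, deg)
        for i, g in enumerate(grads):
            assert shape_cos(g.values, evecs[:, 1 + i]) >= 1 - 1e-8
            assert g.eigenvalue == pytest.approx(evals[1 + i], abs=1e-10)

    def test_complete_graph_flags_degenerate_spectrum(self, caplog):
        w = np.ones((6, 6)) - np.eye(6)
        with caplog.at_level(logging.WARNING, logger="connectograd"):
            laplacian_eigenmaps(w, 2)
        assert "degenerate" in caplog.text.lower()

    def test_weight_scaling_leaves_gradients_unchanged(self):
        w = self.path_graph(8)
        g1 = laplacian_eigenmaps(w, 1)[0]
        g2 = laplacian_eigenmaps(10.0 * w, 1)[0]
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-9)

    def test_disconnected_graph_rejected(self):
        # two separate 3-node paths
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            w[i, j] = w[j, i] = 1.0
        with pytest.raises(ValueError, match="disconnect|connected"):
            laplacian_eigenmaps(w, 1)


class TestSignAlignment:
    def test_aligned_to_itself_unchanged(self, rng):
        g = GradientMap(rng.random(20), 0.1)
        out = align_sign(g, g)
        np.testing.assert_array_equal(out.values, g.values)
        assert not out.sign_flipped

    def test_anti_aligned_is_flipped(self, rng):
        v = rng.random(20)
        g = GradientMap(v, 0.1)
        out = align_sign(g, GradientMap(1 - v, 0.1))
        assert out.sign_flipped
        assert np.corrcoef(out.values, 1 - v)[0, 1] == pytest.approx(1.0)

    def test_alignment_contract_random_sweep(self, rng):
        for _ in range(50):
            g = GradientMap(rng.random(30), 0.1)
            ref = GradientMap(rng.random(30), 0.1)
            out = align_sign(g, ref)
            assert np.corrcoef(out.values, ref.values)[0, 1] >= 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            align_sign(GradientMap(np.full(5, 0.5), 0.1),
                       GradientMap(np.linspace(0, 1, 5), 0.1))

    def test_orient_to_axis_increases_with_z(self, rng):
        coords = rng.standard_normal((40, 3)) * 10
        v = -coords[:, 2] + 0.1 * rng.standard_normal(40)
        v = (v - v.min()) / (v.max() - v.min())
        out = orient_to_axis(GradientMap(v, 0.1), coords)
        assert np.corrcoef(out.values, coords[:, 2])[0, 1] > 0


class TestGroupGradient:
    def test_identical_inputs_reproduced(self, rng):
        v = rng.random(25)
        v = (v - v.min()) / (v.max() - v.min())
        g = GradientMap(v, 0.1)
        out = group_gradient([g, g, g])
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_flip_is_absorbed(self, rng):
        v = rng.random(25)
        v = (v - v.min()) / (v.max() - v.min())
        out = group_gradient([GradientMap(v, 0.1), GradientMap(1 - v, 0.1)])
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_averaging_beats_median_individual(self, rng):
        truth = np.linspace(0, 1, 100)
        noisy = []
        cors = []
        for _ in range(20):
            v = truth + 0.35 * rng.standard_normal(100)
            v = (v - v.min()) / (v.max() - v.min())
            noisy.append(GradientMap(v, 0.1))
            cors.append(np.corrcoef(v, truth)[0, 1])
        grp = group_gradient(noisy)
        assert np.corrcoef(grp.values, truth)[0, 1] > np.median(cors)

    def test_mismatched_voxel_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            group_gradient([GradientMap(rng.random(10), 0.1),
                            GradientMap(rng.random(11), 0.1)])


class TestPipelineInvariances:
    def test_network_relabeling_and_amplitude_invariance(self):
        from connectograd.simulate import GradientScenario, simulate_gradient_bold
        sc = GradientScenario(seed=4, t=120, roi_shape=(5, 5, 5),
                              n_target_per_network=30)
        roi, tgt, s = simulate_gradient_bold(sc)
        g_ref, _ = connectopic_gradients(roi, tgt)

        # permute target voxels (relabel networks) and rescale BOLD amplitude
        perm = np.random.default_rng(0).permutation(tgt.n_voxels)
        tgt_perm = BoldData(tgt.grid, tgt.mask, tgt.series[:, perm] * 7.3)
        roi_scaled = BoldData(roi.grid, roi.mask, roi.series * 0.01)
        g_alt, _ = connectopic_gradients(roi_scaled, tgt_perm)

        aligned = align_sign(g_alt[0], g_ref[0])
        np.testing.assert_allclose(aligned.values, g_ref[0].values, atol=1e-6)
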