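"""Spectral analysis: eigendecomposition, mode similarity, windowed
mean-mode statistics, prominent modes, and hotspots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rigiditygraph as rg
from rigiditygraph import graphs, spectral
from rigiditygraph.graphs import RigidityGraph
from rigiditygraph.spectral import (SpectralResult, eigendecompose,
                                    hotspot_residues, mean_graph,
                                    mean_mode_content, mode_similarity,
                                    prominent_mode_indices,
                                    select_prominent_modes)


class TestEigendecompose:
    def test_single_edge_signless_laplacian_modes(self):
        g = RigidityGraph(np.array([[0.0, 2.0], [2.0, 0.0]]))
        spec = eigendecompose(g, "K")
        np.testing.assert_allclose(spec.eigenvalues, [4.0, 0.0], atol=1e-12)

    def test_connected_laplacian_has_exactly_one_zero_mode(self, small_ref):
        g = graphs.residue_graph(small_ref.model, "ALL", "all")
        spec = eigendecompose(g, "L")
        scale = spec.eigenvalues.max()
        assert np.sum(np.abs(spec.eigenvalues) < 1e-10 * scale) == 1

    def test_spectrum_matches_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 2, size=(6, 6))
        A = np.triu(A, 1)
        A = A + A.T
        K = RigidityGraph(A).signless_laplacian
        spec = eigendecompose(K)
        roots = np.sort(np.roots(np.poly(K)).real)[::-1]
        np.testing.assert_allclose(spec.eigenvalues, roots, atol=1e-8)

    def test_eigenvectors_orthonormal(self, small_ref):
        g = graphs.residue_graph(small_ref.model, "ALL", "nonskeleton")
        spec = eigendecompose(g, "K")
        V = spec.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(spec.n), atol=1e-8)

    def test_sign_convention_is_deterministic(self):
        M = np.diag([3.0, 1.0])
        spec = eigendecompose(M)
        assert spec.mode(0)[0] > 0 and spec.mode(1)[1] > 0

    def test_nonfinite_entries_rejected(self):
        M = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            eigendecompose(M)


class TestModeSimilarity:
    def test_self_comparison_is_unity_for_every_mode(self, small_ref):
        g = graphs.residue_graph(small_ref.model, "ALL", "nonskeleton")
        spec = eigendecompose(g, "K")
        for a in range(spec.n):
            r, b = mode_similarity(spec, spec, a)
            assert r == pytest.approx(1.0, abs=1e-9)
            assert b == a

    def test_rotated_basis_gives_inverse_sqrt2(self):
        ref = SpectralResult(np.array([2.0, 1.0]), np.eye(2))
        s = 1 / np.sqrt(2)
        comp = SpectralResult(np.array([2.0, 1.0]),
                              np.array([[s, s], [s, -s]]))
        r, b = mode_similarity(comp, ref, 0)
        assert r == pytest.approx(s)
        assert b == 0  # tie broken toward smaller mode index

    def test_sign_flip_invariance(self, small_ref):
        g = graphs.residue_graph(small_ref.model, "ALL", "nonskeleton")
        spec = eigendecompose(g, "K")
        flipped = SpectralResult(spec.eigenvalues, -spec.eigenvectors)
        for a in (0, 3, 7):
            assert mode_similarity(flipped, spec, a)[0] == pytest.approx(1.0)

    def test_dimension_mismatch_raises(self):
        a = SpectralResult(np.ones(2), np.eye(2))
        b = SpectralResult(np.ones(3), np.eye(3))
        with pytest.raises(ValueError, match="dimension"):
            mode_similarity(a, b, 0)

    def test_skeleton_laplacian_low_modes_track_contact_topology(self, helix_ref):
        """The lowest chain modes of the skeleton-only Laplacian coincide
        with those of the unit-stiffness contact network."""
        m = helix_ref.model
        cg = rg.CGModel(m.sites, m.coords)
        L_skel = graphs.residue_graph(m, "ALL", "skeleton")
        L0 = graphs.contact_graph(rg.build_bsenm0(cg, helix_ref.spec.lc))
        s_skel = eigendecompose(L_skel, "L")
        s_l0 = eigendecompose(L0, "L")
        n = s_l0.n
        rs = [mode_similarity(s_skel, s_l0, a)[0]
              for a in range(n - 2, n - 5, -1)]  # 3 lowest nontrivial
        assert min(rs) > 0.9


class TestMeanGraph:
    def test_identical_windows_return_first(self, small_ref):
        g = graphs.residue_graph(small_ref.model, "ALL", "nonskeleton")
        gbar = mean_graph([g, g, g])
        np.testing.assert_allclose(gbar.adjacency, g.adjacency)

    def test_entrywise_mean_of_two_windows(self):
        a = np.array([[0.0, 0.0], [0.0, 0.0]])
        b = np.array([[0.0, 2.0], [2.0, 0.0]])
        gbar = mean_graph([RigidityGraph(a), RigidityGraph(b)])
        assert gbar.adjacency[0, 1] == pytest.approx(1.0)

    def test_matches_streaming_mean(self, small_ref):
        series = rg.make_window_series(small_ref, n_windows=10, seed=2)
        Ks = series.window_graphs()
        direct = mean_graph(Ks)
        streaming = np.zeros_like(Ks[0])
        for n, K in enumerate(Ks, start=1):
            streaming += (K - streaming) / n
        np.testing.assert_allclose(direct, streaming, rtol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            mean_graph([np.zeros((2, 2)), np.zeros((3, 3))])


class TestMeanModeContent:
    def test_identical_windows_have_unit_content(self, small_ref):
        g = graphs.residue_graph(small_ref.model, "ALL", "nonskeleton")
        stats = mean_mode_content([g, g, g], "K")
        np.testing.assert_allclose(stats.contents, 1.0, atol=1e-8)

    def test_single_window_average_equals_that_window(self, small_ref):
        g = graphs.residue_graph(small_ref.model, "ALL", "nonskeleton")
        stats = mean_mode_content([g], "K")
        np.testing.assert_allclose(stats.mean_contents, stats.contents[0])

    def test_planted_edge_mode_outlasts_noise_modes(self, small_ref):
        series = rg.make_window_series(small_ref, n_windows=20,
                                       perturbation=0.3, seed=6)
        stats = mean_mode_content(series.window_graphs(), "K")
        I, J = series.planted_residues
        w = stats.spectrum.eigenvectors[I, :] ** 2 + \
            stats.spectrum.eigenvectors[J, :] ** 2
        planted_mode = int(np.argmax(w))
        others = np.delete(stats.mean_contents, planted_mode)
        assert stats.mean_contents[planted_mode] > np.median(others)


class TestProminentModes:
    def test_single_strength_outlier_selected(self):
        lams = np.array([1.0] * 19 + [100.0])
        contents = np.full(20, 0.9)
        idx, fence, thr = prominent_mode_indices(lams, contents, 0.0)
        assert idx == [19]

    def test_equal_strengths_select_nothing(self):
        lams = np.full(10, 3.0)
        contents = np.linspace(0.5, 1.0, 10)
        idx, _, _ = prominent_mode_indices(lams, contents, 0.75)
        assert idx == []

    def test_matches_independent_quantile_oracle(self, small_ref):
        series = rg.make_window_series(small_ref, n_windows=12, seed=9)
        stats = mean_mode_content(series.window_graphs(), "K")
        lams, contents = stats.strengths, stats.mean_contents
        idx, _, _ = prominent_mode_indices(lams, contents, 0.75)

        def quantile_type7(x, q):
            xs = np.sort(np.asarray(x, float))
            h = (len(xs) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        q1 = quantile_type7(lams, 0.25)
        q3 = quantile_type7(lams, 0.75)
        fence = q3 + 1.5 * (q3 - q1)
        cthr = quantile_type7(contents, 0.75)
        brute = [a for a in range(len(lams))
                 if lams[a] > fence and contents[a] >= cthr]
        assert idx == brute

    def test_fewer_than_four_modes_rejected(self):
        with pytest.raises(ValueError, match="4 modes"):
            prominent_mode_indices(np.ones(3), np.ones(3), 0.75)


class TestHotspots:
    def test_threshold_selects_significantly_weighted_residues(self):
        v = np.sqrt([0.5, 0.3, 0.15, 0.05])
        assert hotspot_residues(v, 0.1) == [0, 1, 2]

    def test_uniform_mode_has_no_hotspots(self):
        v = np.full(20, np.sqrt(0.05))
        assert hotspot_residues(v, 0.1) == []

    def test_dual_residue_mode_has_exactly_two(self):
        v = np.zeros(10)
        v[2] = v[7] = np.sqrt(0.5)
        assert hotspot_residues(v, 0.1) == [2, 7]

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=2, max_value=40), st.integers(0, 10_000))
    def test_hotspot_count_bounded_by_normalization(self, n, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=n)
        v /= np.linalg.norm(v)
        assert len(hotspot_residues(v, 0.1)) <= 10

    def test_dominant_edge_mode_localizes_on_its_endpoints(self):
        # as one edge weight grows, the top signless-Laplacian mode
        # concentrates on its two nodes, approaching 0.5/0.5
        rng = np.random.default_rng(12)
        A = rng.uniform(0.5, 1.5, size=(5, 5))
        A = np.triu(A, 1) + np.triu(A, 1).T
        prev = 0.0
        for w in (5.0, 20.0, 100.0, 1000.0):
            B = A.copy()
            B[0, 1] = B[1, 0] = w
            spec = eigendecompose(RigidityGraph(B).signless_laplacian)
            weight = spec.mode(0)[0] ** 2 + spec.mode(0)[1] ** 2
            assert weight > prev
            prev = weight
        assert prev > 0.999

    def test_planted_edge_residues_are_prominent_hotspots(self, small_ref):
        hits = 0
        for seed in range(10):
            series = rg.make_window_series(small_ref, n_windows=20,
                                           perturbation=0.3, seed=seed)
            stats = mean_mode_content(series.window_graphs(), "K")
            prom = select_prominent_modes(stats, 0.75)
            if any(set(series.planted_residues) <= set(prom.hotspots[a])
                   for a in prom.modes):
                hits += 1
        assert hits >= 9
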