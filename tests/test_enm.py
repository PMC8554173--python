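"""Elastic-network Hessian, fluctuation prediction, and matching."""

import numpy as np
import pytest

import rigiditygraph as rg
from rigiditygraph import enm
from rigiditygraph.constants import kT
from rigiditygraph.core import BsENM, CGModel, CGSite, FluctuationTargets, Spring


def _sites(n, residues_of_three=True):
    sites = []
    for i in range(n):
        res = i // 3 if residues_of_three else i
        cls = "backbone" if (i % 3) < 2 else "sidechain"
        sites.append(CGSite(i, res, "A", cls, "N", "ALA"))
    return sites


def pair_model(d=4.0, k=1.0, temperature=300.0):
    sites = [CGSite(0, 0, "A", "backbone", "N", "ALA"),
             CGSite(1, 1, "A", "backbone", "N", "ALA")]
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    return BsENM(sites, [Spring(0, 1, d, k)], coords, temperature)


class TestHessian:
    def test_single_spring_eigenvalues_are_2k_and_five_zeros(self):
        H = enm.enm_hessian(pair_model(k=1.0))
        evals = np.sort(np.linalg.eigvalsh(H))
        np.testing.assert_allclose(evals[:5], 0.0, atol=1e-12)
        assert evals[5] == pytest.approx(2.0)

    def test_all_zero_stiffness_gives_zero_matrix(self):
        m = pair_model(k=1.0)
        m.springs[0].k = 0.0
        assert not enm.enm_hessian(m).any()

    def test_hessian_matches_finite_difference_of_harmonic_energy(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(scale=3.0, size=(4, 3))
        springs = []
        for i in range(4):
            for j in range(i + 1, 4):
                springs.append(Spring(i, j, float(np.linalg.norm(coords[i] - coords[j])),
                                      float(rng.uniform(0.5, 3.0))))
        model = BsENM(_sites(4), springs, coords)

        def energy(x):
            x = x.reshape(4, 3)
            e = 0.0
            for s in springs:
                e += 0.5 * s.k * (np.linalg.norm(x[s.i] - x[s.j]) - s.l0) ** 2
            return e

        x0 = coords.ravel()
        h = 1e-5
        H_num = np.zeros((12, 12))
        for a in range(12):
            for b in range(12):
                xs = [x0.copy() for _ in range(4)]
                xs[0][a] += h; xs[0][b] += h
                xs[1][a] += h; xs[1][b] -= h
                xs[2][a] -= h; xs[2][b] += h
                xs[3][a] -= h; xs[3][b] -= h
                H_num[a, b] = (energy(xs[0]) - energy(xs[1])
                               - energy(xs[2]) + energy(xs[3])) / (4 * h * h)
        np.testing.assert_allclose(enm.enm_hessian(model), H_num,
                                   rtol=1e-4, atol=1e-5)

    def test_symmetric_and_positive_semidefinite(self, small_ref):
        H = enm.enm_hessian(small_ref.model)
        np.testing.assert_allclose(H, H.T, atol=1e-12)
        evals = np.linalg.eigvalsh(H)
        assert evals.min() >= -1e-8 * evals.max()

    def test_coincident_connected_sites_raise(self):
        m = pair_model()
        m.coords[1] = m.coords[0]
        with pytest.raises(ValueError, match="coincident"):
            enm.enm_hessian(m)


class TestDistanceFluctuations:
    def test_isolated_pair_closed_form_kbt_over_k(self):
        var = enm.enm_distance_fluctuations(pair_model(k=1.0))
        assert var[0] == pytest.approx(0.5961, abs=1e-4)

    def test_doubling_stiffness_halves_every_variance(self, small_ref):
        m = small_ref.model
        v1 = enm.enm_distance_fluctuations(m)
        v2 = enm.enm_distance_fluctuations(m.with_stiffnesses(2 * m.stiffnesses()))
        np.testing.assert_allclose(v2, v1 / 2, rtol=1e-9)

    def test_matches_monte_carlo_from_gaussian_ensemble(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=3.0, size=(5, 3))
        springs = [Spring(i, j, float(np.linalg.norm(coords[i] - coords[j])),
                          float(rng.uniform(0.5, 2.0)))
                   for i in range(5) for j in range(i + 1, 5)]
        model = BsENM(_sites(5), springs, coords)
        C = enm.enm_covariance(model)
        evals, evecs = np.linalg.eigh(C)
        factor = evecs * np.sqrt(np.clip(evals, 0, None))
        z = rng.standard_normal((100_000, 15))
        frames = coords.ravel() + z @ factor.T
        # linearized distance fluctuation: project displacement on ê
        pairs = model.spring_pairs()
        v_pred = enm.enm_distance_fluctuations(model, covariance=C)
        for p, (i, j) in enumerate(pairs):
            d = coords[i] - coords[j]
            e = d / np.linalg.norm(d)
            rel = (frames[:, 3 * i:3 * i + 3] - frames[:, 3 * j:3 * j + 3]) @ e
            v_mc = rel.var()
            se = v_mc * np.sqrt(2 / 100_000)
            assert abs(v_mc - v_pred[p]) < 3 * se

    def test_rigid_transform_leaves_predictions_unchanged(self, small_ref):
        from scipy.spatial.transform import Rotation

        m = small_ref.model
        v1 = enm.enm_distance_fluctuations(m)
        R = Rotation.from_euler("zyx", [1.0, -0.4, 2.2]).as_matrix()
        moved = BsENM(m.sites, m.springs, m.coords @ R.T + 7.5, m.temperature)
        v2 = enm.enm_distance_fluctuations(moved)
        np.testing.assert_allclose(v2, v1, rtol=1e-8)

    def test_disconnected_network_reports_rank_deficiency(self):
        sites = _sites(4)
        coords = np.array([[0., 0, 0], [4, 0, 0], [40, 0, 0], [44, 0, 1]])
        model = BsENM(sites, [Spring(0, 1, 4, 1.0), Spring(2, 3, 4.1, 1.0)],
                      coords)
        with pytest.raises(enm.NetworkRankError):
            enm.enm_covariance(model)


class TestBuildModels:
    def _cg(self, positions):
        return CGModel(_sites(len(positions)), np.asarray(positions, float))

    def test_pair_within_default_cutoff_gets_one_spring(self):
        m = enm.build_initial_model(self._cg([[0, 0, 0], [5, 0, 0]]), lc=7.8)
        assert len(m.springs) == 1

    def test_no_pairs_within_cutoff_raises(self):
        with pytest.raises(ValueError, match="cutoff"):
            enm.build_initial_model(self._cg([[0, 0, 0], [8, 0, 0]]), lc=7.8)

    def test_collinear_sites_wire_only_near_pairs(self):
        m = enm.build_initial_model(
            self._cg([[0, 0, 0], [4, 0, 0], [8, 0, 0]]), lc=5.0)
        assert sorted(s.pair for s in m.springs) == [(0, 1), (1, 2)]

    def test_bsenm0_has_unit_stiffness_everywhere(self, small_ref):
        cg = CGModel(small_ref.model.sites, small_ref.model.coords)
        m0 = enm.build_bsenm0(cg, 7.8)
        assert np.all(m0.stiffnesses() == 1.0)

    def test_rest_lengths_come_from_targets_when_supplied(self):
        cg = self._cg([[0, 0, 0], [5, 0, 0]])
        targets = FluctuationTargets([(0, 1)], [5.3], [0.2])
        m = enm.build_initial_model(cg, lc=7.8, targets=targets)
        assert m.springs[0].l0 == pytest.approx(5.3)


class TestFluctuationMatching:
    def test_isolated_pair_converges_to_closed_form(self):
        target_var = kT(300.0) / 2.0
        targets = FluctuationTargets([(0, 1)], [4.0], [target_var])
        for k0 in (0.1, 1.0, 10.0):
            fit, rep = enm.fluctuation_matching_round(pair_model(k=k0), targets)
            assert rep.converged
            assert fit.springs[0].k == pytest.approx(2.0, rel=1e-4)

    def test_recovers_reference_stiffness_from_analytic_targets(self, learned_small):
        fit, trimmed, ref = learned_small
        lookup = {s.pair: s.k for s in ref.model.springs}
        k_fit = fit.stiffnesses()
        k_ref = np.array([lookup[s.pair] for s in fit.springs])
        sel = k_ref > 0.1
        rel = np.abs(k_fit[sel] - k_ref[sel]) / k_ref[sel]
        assert rel.max() < 0.02

    def test_self_consistency_is_a_fixed_point(self, small_ref):
        model = small_ref.model
        own = FluctuationTargets(model.spring_pairs(),
                                 [s.l0 for s in model.springs],
                                 enm.enm_distance_fluctuations(model))
        fit, rep = enm.fluctuation_matching_round(model, own, max_iter=5)
        assert rep.converged and rep.iterations == 1
        np.testing.assert_allclose(fit.stiffnesses(), model.stiffnesses())

    def test_unachievable_target_drives_redundant_spring_to_zero(self):
        # fully connected 5-site network: 10 springs on 9 internal degrees
        # of freedom, so one spring is redundant.  Ask the (0,1) spring for
        # 10x the variance the network allows even at k01 = 0.
        rng = np.random.default_rng(4)
        coords = rng.normal(scale=3.0, size=(5, 3))
        sites = _sites(5)

        def build(k01):
            springs = []
            for i in range(5):
                for j in range(i + 1, 5):
                    k = k01 if (i, j) == (0, 1) else 1.0
                    springs.append(Spring(i, j, float(np.linalg.norm(coords[i] - coords[j])), k))
            return BsENM(sites, springs, coords)

        v_base = enm.enm_distance_fluctuations(build(0.0), pairs=[(0, 1)])[0]
        # grid-search oracle: variance along (0,1) is maximal at k01 = 0
        for k01 in (0.25, 0.5, 1.0, 2.0):
            assert enm.enm_distance_fluctuations(build(k01), pairs=[(0, 1)])[0] < v_base
        model = build(1.0)
        v = enm.enm_distance_fluctuations(build(0.0))
        var = v.copy()
        var[0] = 10 * v_base
        targets = FluctuationTargets(model.spring_pairs(),
                                     [s.l0 for s in model.springs], var)
        fit, rep = enm.fluctuation_matching_round(model, targets, max_iter=500)
        assert fit.springs[0].k == 0.0

    def test_matching_requires_positive_targets(self, small_ref):
        t = small_ref.targets
        bad = FluctuationTargets(t.pairs, t.l0, t.var.copy())
        bad.var[0] = 0.0
        with pytest.raises(ValueError, match="positive target variance"):
            enm.fluctuation_matching_round(small_ref.model, bad)


class TestTrimming:
    @pytest.mark.parametrize("weak_category,survives",
                             [("nonskeleton", False), ("skeleton1", True)])
    def test_threshold_removes_weak_spring_unless_skeleton1(
            self, weak_category, survives):
        rng = np.random.default_rng(8)
        coords = rng.normal(scale=3.0, size=(5, 3))
        sites = _sites(5)
        springs = []
        for i in range(5):
            for j in range(i + 1, 5):
                cat = weak_category if (i, j) == (0, 1) else "nonskeleton"
                k = 0.0005 if (i, j) == (0, 1) else 5.0
                springs.append(Spring(i, j, float(np.linalg.norm(coords[i] - coords[j])),
                                      k, cat))
        model = BsENM(sites, springs, coords)
        targets = FluctuationTargets(model.spring_pairs(),
                                     [s.l0 for s in model.springs],
                                     enm.enm_distance_fluctuations(model))
        trimmed, rep = enm.trim_and_refit(model, targets, k_min=1e-3,
                                          max_iter=100)
        expected = 10 if survives else 9
        assert len(trimmed.springs) == expected
        assert ((0, 1) in {s.pair for s in trimmed.springs}) is survives

    def test_kmin_zero_keeps_every_spring(self, learned_small):
        fit, _, ref = learned_small
        trimmed, rep = enm.trim_and_refit(fit, ref.targets, k_min=0.0,
                                          max_iter=50)
        assert len(trimmed.springs) == len(fit.springs)

    def test_trimmed_nonzero_set_matches_reference(self, learned_small):
        _, trimmed, ref = learned_small
        assert {s.pair for s in trimmed.springs} == ref.nonzero_pairs

    def test_trimming_a_bridge_spring_reports_disconnection(self):
        # two stiff tetrahedra joined by a single weak non-skeleton spring:
        # removing the bridge must be refused, not silently accepted
        rng = np.random.default_rng(1)
        a = rng.normal(scale=2.5, size=(4, 3))
        b = rng.normal(scale=2.5, size=(4, 3)) + np.array([7.0, 0, 0])
        coords = np.vstack([a, b])
        sites = _sites(8)
        springs = []
        for lo in (0, 4):
            for i in range(lo, lo + 4):
                for j in range(i + 1, lo + 4):
                    springs.append(Spring(i, j, float(np.linalg.norm(coords[i] - coords[j])),
                                          5.0, "nonskeleton"))
        springs.append(Spring(0, 4, float(np.linalg.norm(coords[0] - coords[4])),
                              5e-4, "nonskeleton"))
        model = BsENM(sites, springs, coords)
        targets = FluctuationTargets(model.spring_pairs(),
                                     [s.l0 for s in model.springs],
                                     np.ones(len(springs)))
        with pytest.raises(enm.NetworkRankError, match="lower k_min"):
            enm.trim_and_refit(model, targets, k_min=1e-3)


class TestModelIO:
    def test_tsv_round_trip(self, tmp_path, small_ref):
        path = tmp_path / "model.tsv"
        enm.write_model(small_ref.model, path, metadata={"lc": 7.8})
        back = enm.read_model(path, small_ref.model.sites,
                              small_ref.model.coords)
        assert [s.pair for s in back.springs] == [s.pair for s in small_ref.model.springs]
        np.testing.assert_allclose(back.stiffnesses(),
                                   small_ref.model.stiffnesses())
        assert [s.category for s in back.springs] == \
            [s.category for s in small_ref.model.springs]
        assert (path.parent / "model.tsv.json").exists()
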