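"""Unit and property tests of the conjugate predictive machinery."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from aspire import (
    EventMatrix,
    Hyperparams,
    SuffStats,
    class_predictive,
    default_hyperparams,
    joint_set_log_likelihood,
    local_cluster_predictive,
    posterior_niw,
    prior_predictive,
    student_t_logpdf,
    suffstats_update,
)

from _oracles import mc_predictive


class TestDefaultHyperparams:
    def test_vague_defaults_and_minimum_dof(self):
        batch = [EventMatrix("a", np.zeros((3, 2)))]
        hp = default_hyperparams(batch, s=1.0, kappa0=0.5, kappa1=0.1)
        assert hp.alpha == 1 and hp.gamma == 1
        assert hp.m == 4  # d + 2

    def test_mu0_is_pooled_mean(self):
        batch = [EventMatrix("a", np.array([[0.0, 0.0], [2.0, 2.0]]))]
        hp = default_hyperparams(batch)
        assert np.allclose(hp.mu0, [1.0, 1.0])

    def test_sigma0_is_identity_over_s(self):
        batch = [EventMatrix("a", np.zeros((2, 3)))]
        hp = default_hyperparams(batch, s=4.0)
        assert np.allclose(hp.Sigma0, np.diag([0.25, 0.25, 0.25]))

    def test_empty_batch_and_mismatched_dims_raise(self):
        with pytest.raises(ValueError):
            default_hyperparams([])
        with pytest.raises(ValueError, match="dimension"):
            default_hyperparams([EventMatrix("a", np.zeros((2, 2))),
                                 EventMatrix("b", np.zeros((2, 3)))])

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            Hyperparams(alpha=1, gamma=1, kappa0=-1, kappa1=1,
                        mu0=[0.0], Sigma0=[[1.0]], m=3)
        with pytest.raises(ValueError, match="m must be"):
            Hyperparams(alpha=1, gamma=1, kappa0=1, kappa1=1,
                        mu0=[0.0, 0.0], Sigma0=np.eye(2), m=3)


class TestSuffStats:
    def test_single_point(self):
        st0 = SuffStats.empty(2)
        st1 = suffstats_update(st0, [1.0, 2.0], "add")
        assert st1.n == 1
        assert np.allclose(st1.sum, [1, 2])
        assert np.allclose(st1.scatter, [[1, 2], [2, 4]])

    def test_three_points_1d(self):
        st_ = SuffStats.empty(1)
        for x in (1.0, 2.0, 3.0):
            st_ = suffstats_update(st_, [x], "add")
        assert st_.n == 3 and st_.sum[0] == 6 and st_.scatter[0, 0] == 14

    def test_remove_from_empty_raises(self):
        with pytest.raises(ValueError):
            suffstats_update(SuffStats.empty(1), [0.0], "remove")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=20),
           st.floats(-50, 50))
    def test_add_remove_round_trip(self, base, x):
        stats = SuffStats.from_points(np.asarray(base)[:, None])
        after = suffstats_update(suffstats_update(stats, [x], "add"),
                                 [x], "remove")
        assert after.n == stats.n
        assert np.allclose(after.sum, stats.sum, atol=1e-9)
        assert np.allclose(after.scatter, stats.scatter,
                           rtol=1e-12, atol=1e-9)


class TestPriorPredictive:
    def test_symmetric_about_mu0_and_argmax(self, hp1d):
        hp = dataclasses.replace(hp1d, mu0=np.array([0.7]))
        for delta in (0.3, 1.1, 4.0):
            lo = prior_predictive(np.array([0.7 - delta]), hp)
            hi = prior_predictive(np.array([0.7 + delta]), hp)
            assert lo == pytest.approx(hi, abs=1e-12)
            assert lo < prior_predictive(np.array([0.7]), hp)

    def test_collapsed_kappa_chain_is_standard_t(self):
        # mu0=0, kappa0=kappa1=1, Sigma0=1, m=3: scale (1+1+1)/3 = 1, dof 3
        from scipy.stats import t as tdist
        hp = Hyperparams(alpha=1, gamma=1, kappa0=1.0, kappa1=1.0,
                         mu0=[0.0], Sigma0=[[1.0]], m=3)
        for x in (-2.0, 0.0, 0.5, 3.3):
            assert prior_predictive(np.array([x]), hp) == pytest.approx(
                tdist.logpdf(x, 3), abs=1e-10)

    def test_equals_class_predictive_with_empty_stats(self, hp1d):
        x = np.array([0.4])
        tp = class_predictive(SuffStats.empty(1), hp1d)
        assert prior_predictive(x, hp1d) == pytest.approx(
            float(student_t_logpdf(x, tp)), abs=1e-12)

    def test_matches_monte_carlo(self, hp1d):
        x = np.array([0.8])
        est, se = mc_predictive(x, hp1d, clusters=[], n_draws=200_000, seed=1)
        assert prior_predictive(x, hp1d) == pytest.approx(est, abs=3 * se)


class TestClassPredictive:
    def test_density_normalizes_1d(self, hp1d):
        stats = SuffStats.from_points(np.array([[0.2], [0.5], [1.0]]))
        tp = class_predictive(stats, hp1d)
        sd = math.sqrt(tp.scale[0, 0]) * math.sqrt(tp.dof / (tp.dof - 2))
        lo, hi = tp.center[0] - 12 * sd, tp.center[0] + 12 * sd
        total, _ = quad(lambda x: math.exp(
            float(student_t_logpdf(np.array([x]), tp))), lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_center_converges_to_empirical_mean(self, hp1d):
        rng = np.random.default_rng(3)
        theta = 2.5
        pts = rng.normal(theta, 1.3, size=(10_000, 1))
        tp = class_predictive(SuffStats.from_points(pts), hp1d)
        # the prior pull vanishes at rate kappa0 / n
        assert tp.center[0] == pytest.approx(pts.mean(), abs=1e-3)
        assert abs(tp.center[0] - theta) < 0.05

    def test_matches_monte_carlo_flat_conditioning(self, hp1d):
        pts = np.array([[0.1], [0.6], [-0.4], [0.9], [0.3]])
        tp = class_predictive(SuffStats.from_points(pts), hp1d)
        for x in (-0.5, 0.4, 1.5):
            est, se = mc_predictive(np.array([x]), hp1d, clusters=[],
                                    flat_points=pts, n_draws=300_000, seed=5)
            assert float(student_t_logpdf(np.array([x]), tp)) == pytest.approx(
                est, abs=3 * se)

    def test_matches_monte_carlo_structured_conditioning_2d(self, hp2d):
        rng = np.random.default_rng(11)
        c1 = rng.normal(0.3, 0.8, size=(4, 2))
        c2 = rng.normal(-0.2, 0.8, size=(3, 2))
        clusters = [SuffStats.from_points(c1), SuffStats.from_points(c2)]
        tp = class_predictive(clusters, hp2d)
        x = np.array([0.25, -0.1])
        est, se = mc_predictive(x, hp2d, clusters=[c1, c2],
                                n_draws=300_000, seed=6)
        assert float(student_t_logpdf(x, tp)) == pytest.approx(est, abs=3 * se)


class TestLocalClusterPredictive:
    def test_requires_nonempty_cluster(self, hp1d):
        with pytest.raises(ValueError, match="non-empty"):
            local_cluster_predictive(np.array([0.0]), SuffStats.empty(1),
                                     SuffStats.empty(1), hp1d)

    def test_no_random_effects_limit_matches_union(self, hp1d):
        hp = dataclasses.replace(hp1d, kappa1=1e8)
        cl_pts = np.array([[0.5], [1.0], [1.5]])
        ctx_pts = np.array([[0.2], [0.4], [0.9], [1.3]])
        union = SuffStats.from_points(np.vstack([cl_pts, ctx_pts]))
        for x in (-1.0, 0.8, 2.0):
            lhs = local_cluster_predictive(
                np.array([x]), SuffStats.from_points(cl_pts),
                SuffStats.from_points(ctx_pts), hp)
            rhs = float(student_t_logpdf(np.array([x]),
                                         class_predictive(union, hp)))
            assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_matches_monte_carlo(self, hp1d):
        cluster = np.array([[0.6], [1.1], [0.8]])
        others = [np.array([[-0.5], [0.1], [0.3]]), np.array([[1.5], [0.9]])]
        x = np.array([0.7])
        est, se = mc_predictive(x, hp1d, clusters=[cluster] + others,
                                join=0, n_draws=400_000, seed=42)
        mine = local_cluster_predictive(
            x, SuffStats.from_points(cluster),
            [SuffStats.from_points(o) for o in others], hp1d)
        assert mine == pytest.approx(est, abs=3 * se)

    def test_monotone_in_kappa1_toward_class_mean(self, hp1d):
        # a point far from the cluster's empirical mean but close to the
        # class posterior mean gains density as random effects shrink
        cluster = SuffStats.from_points(np.array([[3.0], [3.2], [2.8]]))
        ctx = SuffStats.from_points(np.zeros((30, 1)))
        x = np.array([0.0])
        vals = [local_cluster_predictive(
            x, cluster, ctx, dataclasses.replace(hp1d, kappa1=k1))
            for k1 in (0.05, 0.2, 1.0, 5.0, 50.0)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestJointSetLogLikelihood:
    def test_singleton_equals_one_point_predictive(self, hp1d):
        ctx = SuffStats.from_points(np.array([[0.3], [0.9]]))
        x = np.array([0.5])
        joint = joint_set_log_likelihood(None, x[None, :], ctx, hp1d)
        tp = class_predictive(ctx, hp1d)
        assert joint == pytest.approx(float(student_t_logpdf(x, tp)),
                                      abs=1e-12)

    def test_order_invariance(self, hp2d):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        ctx = SuffStats.from_points(rng.normal(size=(8, 2)))
        base = joint_set_log_likelihood(None, pts, ctx, hp2d)
        for _ in range(5):
            perm = rng.permutation(6)
            assert joint_set_log_likelihood(None, pts[perm], ctx, hp2d) == \
                pytest.approx(base, abs=1e-9)

    def test_empty_set_raises(self, hp1d):
        with pytest.raises(ValueError):
            joint_set_log_likelihood(None, np.empty((0, 1)), None, hp1d)

    def test_matches_monte_carlo_joint(self, hp1d):
        """Whole-cluster marginal vs brute-force MC over the hierarchy."""
        pts = np.array([[0.4], [0.9], [0.1], [0.6]])
        mine = joint_set_log_likelihood(None, pts, None, hp1d)
        # chain the MC one-point predictives over growing cluster prefixes
        est_total, var_total = 0.0, 0.0
        for i in range(4):
            prefix = [pts[:i]] if i > 0 else []
            est, se = mc_predictive(pts[i], hp1d, clusters=prefix,
                                    join=0 if i > 0 else None,
                                    n_draws=300_000, seed=100 + i)
            est_total += est
            var_total += se ** 2
        assert mine == pytest.approx(est_total,
                                     abs=3 * math.sqrt(var_total))


class TestStructuredPosterior:
    def test_flat_equals_infinite_kappa1(self, hp2d):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 2))
        flat = posterior_niw(hp2d, [SuffStats.from_points(pts)],
                             kappa1=math.inf)
        assert flat.kappa == pytest.approx(hp2d.kappa0 + 9)
        assert np.allclose(flat.mu,
                           (hp2d.kappa0 * hp2d.mu0 + pts.sum(0))
                           / (hp2d.kappa0 + 9))

    def test_cluster_weights_bounded_by_kappa1(self, hp1d):
        big = posterior_niw(hp1d, [SuffStats.from_points(
            np.random.default_rng(0).normal(size=(1000, 1)))])
        # a single cluster can contribute at most kappa1 to the precision
        assert big.kappa <= hp1d.kappa0 + hp1d.kappa1 + 1e-12
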