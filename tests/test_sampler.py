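"""Tests of the collapsed Gibbs sampler: moves, invariants, consensus,
pruning, the random-effects grid search and the pooled baseline."""

import dataclasses

import numpy as np
import pytest

from aspire import (
    EventMatrix,
    GibbsConfig,
    Hyperparams,
    SuffStats,
    default_hyperparams,
    fit_pooled_dpgmm,
    gibbs_sweep,
    init_state,
    local_cluster_predictive,
    prune_small_clusters,
    relabel_and_consensus,
    run_sampler,
    sample_c,
    sample_t,
    select_kappa1,
    simulate_from_model,
    student_t_logpdf,
    class_predictive,
)
from aspire.sampler import PooledDPGMMState

from conftest import pooled_chisquare
from _oracles import enumerate_dpgmm_posterior, partition_key


def small_batch(seed=0, J=3, n=40, d=2):
    rng = np.random.default_rng(seed)
    return [EventMatrix(f"s{j}", rng.normal(size=(n, d))) for j in range(J)]


class TestGibbsConfig:
    def test_default_schedule(self):
        cfg = GibbsConfig()
        assert (cfg.n_sweeps, cfg.burn_in, cfg.thin, cfg.n_saved) == \
            (1000, 750, 50, 5)
        assert cfg.save_sweeps == [800, 850, 900, 950, 1000]

    def test_invalid_schedules_raise(self):
        with pytest.raises(ValueError):
            GibbsConfig(n_sweeps=100, burn_in=100)
        with pytest.raises(ValueError):
            GibbsConfig(n_sweeps=100, burn_in=50, thin=20, n_saved=5)


class TestInitState:
    def test_single_event_forces_one_cluster_one_class(self, hp2d):
        batch = [EventMatrix("a", np.array([[0.1, 0.2]]))]
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, seed=0)
        assert state.K == 1
        assert state.tcount[0] == 1
        state.validate()

    def test_invariants_hold_on_random_batches(self):
        batch = small_batch(3)
        hp = default_hyperparams(batch)
        for seed in (0, 1):
            state = init_state(batch, hp, seed)
            state.validate()

    def test_seeded_determinism(self):
        batch = small_batch(5)
        hp = default_hyperparams(batch)
        a = init_state(batch, hp, 11)
        b = init_state(batch, hp, 11)
        assert np.array_equal(a.t_arr, b.t_arr)
        assert np.array_equal(a.event_class_labels(), b.event_class_labels())

    def test_single_cluster_start(self):
        batch = small_batch(1)
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, 0, strategy="single")
        assert state.K == 1 and state.tcount[0] == len(batch)
        state.validate()


class TestKernelAgreesWithReferencePath:
    """The compiled predictive must equal the numpy/scipy closed form."""

    def test_event_scores_match_reference(self, hp2d):
        from aspire import _kernels as K
        rng = np.random.default_rng(0)
        batch = small_batch(2, J=2, n=30)
        hp = dataclasses.replace(default_hyperparams(batch), kappa1=0.3,
                                 kappa0=0.7)
        state = init_state(batch, hp, 4)
        x = rng.normal(size=2)
        for j in range(state.J):
            for idx in range(state.scl_count[j]):
                c = int(state.scl[j, idx])
                k = int(state.cl_class[c])
                A_ex = K._excl_accums(k, c, hp.kappa1, state.cl_n,
                                      state.cl_sum, state.cl_scat,
                                      state.k_A, state.k_b, state.k_C,
                                      state._vb, state._MC)
                got = K._pred_log(
                    x, state.cl_n[c], state.cl_sum[c], state.cl_scat[c],
                    A_ex, state._vb, state.k_n[k] - state.cl_n[c], state._MC,
                    hp.kappa0, hp.kappa1, float(hp.m), state._k0mu0,
                    state._base, state._P, state._v, state._v2, state._v3)
                # reference: same quantity through the scipy route
                cluster = SuffStats(int(state.cl_n[c]), state.cl_sum[c].copy(),
                                    state.cl_scat[c].copy())
                others = [SuffStats(int(state.cl_n[c2]),
                                    state.cl_sum[c2].copy(),
                                    state.cl_scat[c2].copy())
                          for c2 in state.active_clusters()
                          if state.cl_class[c2] == k and c2 != c]
                want = local_cluster_predictive(x, cluster, others, hp)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_new_class_score_matches_prior_predictive(self, hp2d):
        from aspire import _kernels as K
        from aspire import prior_predictive
        batch = small_batch(1, J=1, n=10)
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, 0)
        x = np.array([0.3, -0.2])
        got = K._pred_log(x, 0, state._zv, state._zM, 0.0, state._zv, 0,
                          state._zM, hp.kappa0, hp.kappa1, float(hp.m),
                          state._k0mu0, state._base,
                          state._P, state._v, state._v2, state._v3)
        assert got == pytest.approx(prior_predictive(x, hp), rel=1e-10)


class TestSampleMoves:
    def test_alpha_zero_keeps_single_cluster(self):
        rng = np.random.default_rng(0)
        batch = [EventMatrix("a", rng.normal(size=(20, 1)))]
        hp = dataclasses.replace(default_hyperparams(batch), alpha=0.0)
        state = init_state(batch, hp, 0, strategy="single")
        r = np.random.default_rng(1)
        for i in range(20):
            sample_t(state, 0, i, hp, r)
        assert state.tcount[0] == 1
        state.validate()

    def test_symmetric_clusters_get_equal_frequencies(self):
        # two identical clusters, equidistant event: empirical assignment
        # frequencies equal within binomial error
        batch = [EventMatrix("a", np.array(
            [[-1.0], [-1.0], [1.0], [1.0], [0.0]]))]
        hp = dataclasses.replace(default_hyperparams(batch),
                                 alpha=0.0, kappa1=1.0)
        counts = {0: 0, 1: 0}
        state = init_state(batch, hp, 0, strategy="single")
        # construct two symmetric clusters manually: events 0,1 vs 2,3
        from aspire import _kernels as K
        r = np.random.default_rng(5)
        n_rep = 4000
        state = init_state(batch, hp, 1, strategy="single")
        # split the single cluster: move events into a stable 2-cluster state
        hp_split = dataclasses.replace(hp, alpha=5.0)
        state = init_state(batch, hp_split, 3)
        for _ in range(50):
            gibbs_sweep(state, batch, hp_split, r)
            if state.tcount[0] == 2:
                break
        assert state.tcount[0] >= 2
        sizes = sorted(int(state.cl_n[c]) for c in state.active_clusters())
        # resample the middle event many times and track left/right choice
        left = 0
        for _ in range(n_rep):
            sample_t(state, 0, 4, hp, r)
            c = state.t_arr[4]
            if state.X[state.t_arr == c].mean() < 0:
                left += 1
        frac = left / n_rep
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n_rep) + 0.05

    def test_probability_vector_normalizes(self):
        # indirect: scores drawn through the kernel always produce a valid
        # categorical draw; validate state invariants over many moves
        batch = small_batch(9, J=2, n=25)
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, 2)
        r = np.random.default_rng(3)
        for _ in range(200):
            j = int(r.integers(0, 2))
            i = int(r.integers(0, 25))
            sample_t(state, j, i, hp, r)
        state.validate()

    def test_gamma_zero_keeps_single_class(self):
        batch = small_batch(4, J=2, n=30)
        hp = dataclasses.replace(default_hyperparams(batch), gamma=0.0)
        state = init_state(batch, hp, 0, strategy="single")
        r = np.random.default_rng(0)
        for j in range(2):
            for idx in range(int(state.scl_count[j])):
                sample_c(state, j, idx, hp, r)
        assert state.K == 1
        state.validate()

    def test_class_move_conserves_counts(self):
        batch = small_batch(8, J=3, n=30)
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, 1)
        total_events = state.N
        total_clusters = int(state.tcount[0])
        r = np.random.default_rng(9)
        for j in range(3):
            for idx in range(int(state.scl_count[j])):
                sample_c(state, j, idx, hp, r)
        assert int(state.tcount[0]) == total_clusters
        assert sum(int(state.cl_n[c]) for c in state.active_clusters()) \
            == total_events
        state.validate()

    def test_event_index_out_of_range(self):
        batch = small_batch(0, J=1, n=5)
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, 0)
        with pytest.raises(IndexError):
            sample_t(state, 0, 99, hp, np.random.default_rng(0))
        with pytest.raises(IndexError):
            sample_c(state, 0, 99, hp, np.random.default_rng(0))


class TestSweepInvariants:
    def test_invariants_and_stats_consistency_after_100_sweeps(self):
        batch = small_batch(6, J=3, n=40)
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, 0)
        rng = np.random.default_rng(1)
        cfg_rebuild_off = 0
        for _ in range(100):
            gibbs_sweep(state, batch, hp, rng)
        state.validate(atol=1e-8)

    def test_fixed_seed_reproduces_trajectory(self):
        batch = small_batch(2, J=2, n=30)
        hp = default_hyperparams(batch)
        outs = []
        for _ in range(2):
            state = init_state(batch, hp, 7)
            rng = np.random.default_rng(99)
            for _ in range(20):
                gibbs_sweep(state, batch, hp, rng)
            outs.append(state.event_class_labels())
        assert np.array_equal(outs[0], outs[1])

    def test_single_event_stays_one_cluster(self):
        batch = [EventMatrix("a", np.array([[0.5, 0.5]]))]
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, 0)
        rng = np.random.default_rng(0)
        gibbs_sweep(state, batch, hp, rng)
        assert state.K == 1 and state.tcount[0] == 1


class TestRunSampler:
    def test_two_separated_clusters_recovered(self, two_blob_batch):
        hp = default_hyperparams(two_blob_batch, kappa0=0.01, kappa1=0.5)
        hits = 0
        for seed in range(4):
            cfg = GibbsConfig(n_sweeps=80, burn_in=40, thin=5, n_saved=5,
                              seed=seed)
            res = prune_small_clusters(run_sampler(two_blob_batch, hp, cfg))
            hits += res.n_clusters == 2
        assert hits >= 3

    def test_bit_identical_results_for_identical_seeds(self, two_blob_batch):
        hp = default_hyperparams(two_blob_batch, kappa1=0.5)
        cfg = GibbsConfig(n_sweeps=40, burn_in=20, thin=2, n_saved=5, seed=3)
        a = run_sampler(two_blob_batch, hp, cfg)
        b = run_sampler(two_blob_batch, hp, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert a.gibbs_log_likelihood == b.gibbs_log_likelihood

    def test_summaries_sorted_and_counts_consistent(self, two_blob_batch):
        hp = default_hyperparams(two_blob_batch, kappa1=0.5)
        cfg = GibbsConfig(n_sweeps=40, burn_in=20, thin=2, n_saved=5, seed=0)
        res = run_sampler(two_blob_batch, hp, cfg)
        counts = [s.total_count for s in res.summaries]
        assert counts == sorted(counts, reverse=True)
        assert sum(counts) == res.labels.size
        for s in res.summaries:
            assert s.total_count == int(s.per_sample_counts.sum())
        assert res.trace.size == 40

    def test_strict_scope_mode_runs(self, two_blob_batch):
        hp = default_hyperparams(two_blob_batch, kappa1=0.5)
        cfg = GibbsConfig(n_sweeps=20, burn_in=10, thin=1, n_saved=5, seed=0)
        res = run_sampler(two_blob_batch, hp, cfg, strict_t_scope=True)
        assert res.labels.size == sum(s.n_events for s in two_blob_batch)


class TestConsensus:
    def test_permuted_draws_recover_reference(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 4, size=200)
        draws = [ref]
        for _ in range(4):
            perm = rng.permutation(4)
            draws.append(perm[ref])
        assert np.array_equal(relabel_and_consensus(draws), ref)

    def test_single_draw_is_identity(self):
        ref = np.array([0, 1, 1, 2])
        assert np.array_equal(relabel_and_consensus([ref]), ref)

    def test_mode_and_tie_break_toward_last(self):
        d1 = np.array([0, 0, 1])
        d2 = np.array([0, 0, 1])
        d3 = np.array([1, 0, 1])  # event 0: labels {0,0,1} -> 0
        assert relabel_and_consensus([d1, d2, d3])[0] == 0
        # two-way tie: {0,1} with last draw 1 -> 1
        e1 = np.array([0, 0])
        e2 = np.array([1, 0])
        out = relabel_and_consensus([e1, e2])
        # after alignment e2 maps 0->0; label of event 0 ties 0 vs new id
        assert out[1] == 0

    def test_no_draws_raises(self):
        with pytest.raises(ValueError):
            relabel_and_consensus([])


class TestPruning:
    def test_threshold_zero_keeps_everything(self, two_blob_batch):
        hp = default_hyperparams(two_blob_batch, kappa1=0.5)
        cfg = GibbsConfig(n_sweeps=30, burn_in=15, thin=1, n_saved=5, seed=0)
        res = run_sampler(two_blob_batch, hp, cfg)
        assert prune_small_clusters(res, 0.0).n_clusters == res.n_clusters

    def test_small_classes_dropped_by_count(self):
        # synthetic result with class sizes 900 / 96 / 4 over 1000 events
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1, 2], [900, 96, 4])
        batch = [EventMatrix("a", rng.normal(size=(1000, 1)))]
        hp = default_hyperparams(batch)
        state = init_state(batch, hp, 0)
        from aspire.sampler import ClusteringResult, _summarize
        new_labels, summaries = _summarize(labels, state)
        res = ClusteringResult(
            labels=new_labels, summaries=summaries, saved_draws=[new_labels],
            gibbs_log_likelihood=0.0, gibbs_log_likelihood_final=0.0,
            gibbs_log_likelihoods=[0.0], trace=np.zeros(1, dtype=np.int64),
            sample_ids=["a"], sample_start=np.array([0, 1000]),
            hp=hp, config=GibbsConfig(n_sweeps=2, burn_in=1, thin=1,
                                      n_saved=1, seed=0))
        pruned = prune_small_clusters(res, 0.005)
        assert pruned.n_clusters == 2
        assert len(pruned.pruned_class_ids) == 1

    def test_invalid_threshold(self, two_blob_batch):
        hp = default_hyperparams(two_blob_batch)
        cfg = GibbsConfig(n_sweeps=10, burn_in=5, thin=1, n_saved=5, seed=0)
        res = run_sampler(two_blob_batch, hp, cfg)
        with pytest.raises(ValueError):
            prune_small_clusters(res, 1.5)


class TestSelectKappa1:
    def test_default_grid(self):
        from aspire import DEFAULT_KAPPA1_GRID
        assert DEFAULT_KAPPA1_GRID == (0.05, 0.1, 0.25, 0.5, 1.0)

    def test_single_value_grid_returns_it(self, two_blob_batch):
        hp = default_hyperparams(two_blob_batch)
        cfg = GibbsConfig(n_sweeps=20, burn_in=10, thin=1, n_saved=5, seed=0)
        sel = select_kappa1(two_blob_batch, hp, cfg, grid=(0.25,))
        assert sel.best_kappa1 == 0.25
        assert set(sel.scores) == {0.25}

    def test_recovers_small_kappa1_under_strong_random_effects(self):
        # data generated with strong per-sample shifts: small kappa1 wins
        d = 2
        gen_hp = Hyperparams(alpha=1.0, gamma=1.0, kappa0=0.02, kappa1=0.05,
                             mu0=np.zeros(d), Sigma0=np.eye(d), m=d + 2)
        hits = 0
        for seed in range(3):
            batch, _ = simulate_from_model(3, 6, 120, gen_hp, seed=seed,
                                           min_separation=10.0)
            hp = default_hyperparams(batch, kappa0=0.02)
            cfg = GibbsConfig(n_sweeps=80, burn_in=50, thin=5, n_saved=5,
                              seed=seed)
            sel = select_kappa1(batch, hp, cfg, grid=(0.05, 0.25, 1.0))
            hits += sel.best_kappa1 <= 0.25
        assert hits >= 2


class TestPooledDPGMM:
    def test_two_pooled_blobs(self, two_blob_batch):
        hp = default_hyperparams(two_blob_batch, kappa0=0.01)
        hits = 0
        for seed in range(4):
            cfg = GibbsConfig(n_sweeps=60, burn_in=30, thin=2, n_saved=5,
                              seed=seed)
            res = prune_small_clusters(
                fit_pooled_dpgmm(two_blob_batch, hp, cfg), 0.01)
            hits += res.n_clusters == 2
        assert hits >= 3

    def test_tiny_alpha_merges_unimodal_blob(self):
        rng = np.random.default_rng(0)
        batch = [EventMatrix("a", rng.normal(size=(150, 2)))]
        hp = dataclasses.replace(default_hyperparams(batch), alpha=1e-9)
        cfg = GibbsConfig(n_sweeps=30, burn_in=15, thin=1, n_saved=5, seed=0)
        res = fit_pooled_dpgmm(batch, hp, cfg)
        assert res.n_clusters == 1

    def test_partition_distribution_matches_enumeration(self):
        """Five points, flat DP mixture: stationary partition frequencies vs
        exhaustive enumeration (CRP prior x NIW marginal likelihood)."""
        pts = np.array([[0.0], [0.4], [1.9], [-0.7], [2.3]])
        hp = Hyperparams(alpha=1.0, gamma=1.0, kappa0=1.0, kappa1=1.0,
                         mu0=[0.0], Sigma0=[[1.0]], m=4)
        exact = enumerate_dpgmm_posterior(pts, hp)
        batch = [EventMatrix("a", pts)]
        state = PooledDPGMMState(batch, hp)
        rng = np.random.default_rng(17)
        state.seed_sequential(rng.random(state.N))
        counts: dict = {}
        for s in range(30_000):
            state.sweep(rng.random(state.N))
            if s >= 500 and s % 5 == 0:
                key = partition_key(state.t.tolist())
                counts[key] = counts.get(key, 0) + 1
        stat, p = pooled_chisquare(counts, exact)
        assert p > 0.01
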