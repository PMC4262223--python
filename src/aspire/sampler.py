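"""Collapsed Gibbs sampler for joint clustering and cluster matching.

Each sweep resamples, in order, every event's local-cluster indicator
(``t`` loop) and every local cluster's class indicator (``c`` loop), with
component parameters integrated out analytically.  The new-cluster move in
the ``t`` loop follows the Chinese-restaurant-franchise convention: an
event may open a new local cluster under any existing class (weighted by
that class's cluster count) or under a brand-new class (weight ``gamma``),
so events can migrate between classes one at a time.  A literal mode that
restricts candidates to the event's current class is available via
``strict_t_scope`` for comparison.

Randomness is consumed as a flat stream of uniforms drawn per sweep from a
``numpy.random.Generator``, so identical seeds give bit-identical
trajectories regardless of the compiled code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import _kernels as K
from .data import EventMatrix, check_batch
from .model import Hyperparams, NIWPosterior, SuffStats, posterior_niw

DEFAULT_KAPPA1_GRID = (0.05, 0.1, 0.25, 0.5, 1.0)
DEFAULT_PRUNE_THRESHOLD = 0.005


@dataclass
class GibbsConfig:
    """Sweep schedule of the sampler.

    Defaults follow the standard schedule: 1000 sweeps, the first 750
    discarded as burn-in, and five draws saved one every 50 sweeps.
    """

    n_sweeps: int = 1000
    burn_in: int = 750
    thin: int = 50
    n_saved: int = 5
    seed: int = 0
    rebuild_every: int = 25  # refresh sufficient statistics from raw events

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_sweeps:
            raise ValueError("burn_in must be smaller than n_sweeps")
        if self.n_saved * self.thin > self.n_sweeps - self.burn_in:
            raise ValueError("n_saved * thin must fit between burn_in and n_sweeps")
        if self.thin < 1 or self.n_saved < 1:
            raise ValueError("thin and n_saved must be >= 1")

    @property
    def save_sweeps(self) -> list[int]:
        """1-based sweep indices at which draws are saved."""
        return [self.burn_in + (i + 1) * self.thin for i in range(self.n_saved)]


@dataclass(eq=False)
class GlobalClusterSummary:
    """Posterior summary of one global cluster (class)."""

    class_id: int
    mean: np.ndarray
    covariance: np.ndarray
    total_count: int
    per_sample_counts: np.ndarray


@dataclass(eq=False)
class ClusteringResult:
    """Consensus clustering of a batch plus the saved posterior draws."""

    labels: np.ndarray                      # per-event consensus class ids
    summaries: list[GlobalClusterSummary]
    saved_draws: list[np.ndarray]           # per-draw per-event class labels
    gibbs_log_likelihood: float             # mean over saved draws
    gibbs_log_likelihood_final: float
    gibbs_log_likelihoods: list[float]
    trace: np.ndarray                       # class count after each sweep
    sample_ids: list[str]
    sample_start: np.ndarray
    hp: Hyperparams
    config: GibbsConfig
    pruned_class_ids: tuple[int, ...] = ()
    method: str = "aspire"
    local_cluster_ids: np.ndarray | None = None  # within-sample ids, final state

    @property
    def n_clusters(self) -> int:
        """Number of reported global clusters (pruned classes excluded)."""
        return len(self.summaries)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def labels_by_sample(self) -> dict[str, np.ndarray]:
        out = {}
        for j, sid in enumerate(self.sample_ids):
            out[sid] = self.labels[self.sample_start[j]:self.sample_start[j + 1]]
        return out


class AssignmentState:
    """The sampler's entire mutable state, backed by flat preallocated arrays.

    Events are indexed globally (samples concatenated); ``t_arr[i]`` holds
    the slot id of event ``i``'s local cluster, ``cl_class[c]`` the slot id
    of cluster ``c``'s class.  Per-class Normal-inverse-Wishart accumulators
    are maintained incrementally and refreshed from raw events periodically.
    """

    def __init__(self, batch: Sequence[EventMatrix], hp: Hyperparams):
        d = check_batch(list(batch))
        if d != hp.dim:
            raise ValueError("hyperparameter dimension does not match batch")
        self.hp = hp
        self.d = d
        self.sample_ids = [s.sample_id for s in batch]
        sizes = [s.n_events for s in batch]
        self.J = len(batch)
        self.N = int(sum(sizes))
        self.sample_start = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        self.X = np.concatenate([s.data for s in batch], axis=0)
        N, J = self.N, self.J
        CC = N + 2
        self.t_arr = np.full(N, -1, dtype=np.int64)
        self.cl_n = np.zeros(CC, dtype=np.int64)
        self.cl_sum = np.zeros((CC, d))
        self.cl_scat = np.zeros((CC, d, d))
        self.cl_class = np.zeros(CC, dtype=np.int64)
        self.cl_sample = np.zeros(CC, dtype=np.int64)
        self.cl_pos = np.zeros(CC, dtype=np.int64)
        self.cl_free = np.arange(CC - 1, -1, -1, dtype=np.int64)
        self.cl_ftop = np.array([CC], dtype=np.int64)
        maxcl = max(sizes) + 1
        self.scl = np.zeros((J, maxcl), dtype=np.int64)
        self.scl_count = np.zeros(J, dtype=np.int64)
        self.klist = np.zeros(CC, dtype=np.int64)
        self.kcount = np.zeros(1, dtype=np.int64)
        self.k_pos = np.zeros(CC, dtype=np.int64)
        self.k_free = np.arange(CC - 1, -1, -1, dtype=np.int64)
        self.k_ftop = np.array([CC], dtype=np.int64)
        self.k_n = np.zeros(CC, dtype=np.int64)
        self.k_ncl = np.zeros(CC, dtype=np.int64)
        self.k_A = np.zeros(CC)
        self.k_b = np.zeros((CC, d))
        self.k_C = np.zeros((CC, d, d))
        self.tcount = np.zeros(1, dtype=np.int64)
        # scratch buffers
        self._score = np.zeros(maxcl + 2)
        self._kscore = np.zeros(CC + 1)
        self._ptidx = np.zeros(max(sizes), dtype=np.int64)
        self._P = np.zeros((d, d))
        self._v = np.zeros(d)
        self._v2 = np.zeros(d)
        self._v3 = np.zeros(d)
        self._vb = np.zeros(d)
        self._MC = np.zeros((d, d))
        self._tsum = np.zeros(d)
        self._tscat = np.zeros((d, d))
        self._zv = np.zeros(d)
        self._zM = np.zeros((d, d))
        self._accA = np.zeros(1)
        self._accb = np.zeros(d)
        self._accC = np.zeros((d, d))
        # precomputed hyperparameter pieces consumed by the kernels
        self._k0mu0 = hp.kappa0 * hp.mu0
        self._base = hp.Sigma0 + hp.kappa0 * np.outer(hp.mu0, hp.mu0)
        self.rng_seed: int | None = None

    # -- kernel plumbing ---------------------------------------------------

    def _core_args(self):
        return (self.X, self.t_arr,
                self.cl_n, self.cl_sum, self.cl_scat, self.cl_class,
                self.cl_sample, self.cl_pos, self.cl_free, self.cl_ftop,
                self.scl, self.scl_count,
                self.klist, self.kcount, self.k_pos, self.k_free, self.k_ftop,
                self.k_n, self.k_ncl, self.k_A, self.k_b, self.k_C,
                self.tcount,
                self.hp.alpha, self.hp.gamma, self.hp.kappa0, self.hp.kappa1,
                float(self.hp.m), self._k0mu0, self._base)

    def sweep(self, u: np.ndarray, strict: bool = False) -> None:
        K._sweep(u, strict, self.sample_start, *self._core_args(),
                 self._score, self._kscore, self._ptidx,
                 self._P, self._v, self._v2, self._v3, self._vb, self._MC,
                 self._tsum, self._tscat, self._zv, self._zM)

    def seed_sequential(self, u: np.ndarray) -> None:
        K._seed(u, self.sample_start, *self._core_args(),
                self._score, self._kscore,
                self._P, self._v, self._v2, self._v3, self._vb, self._MC,
                self._zv, self._zM)

    def resample_event(self, i_global: int, u1: float, u2: float,
                       strict: bool = False) -> None:
        j = int(np.searchsorted(self.sample_start, i_global, side="right") - 1)
        K._resample_event(i_global, j, False, u1, u2, strict,
                          *self._core_args(),
                          self._score, self._kscore,
                          self._P, self._v, self._v2, self._v3,
                          self._vb, self._MC, self._zv, self._zM)

    def resample_cluster(self, c: int, u1: float) -> None:
        j = int(self.cl_sample[c])
        K._resample_cluster(c, j, u1, self.sample_start,
                            self.X, self.t_arr,
                            self.cl_n, self.cl_sum, self.cl_scat,
                            self.cl_class, self.cl_sample, self.cl_pos,
                            self.klist, self.kcount, self.k_pos,
                            self.k_free, self.k_ftop,
                            self.k_n, self.k_ncl, self.k_A, self.k_b, self.k_C,
                            self.hp.gamma, self.hp.kappa0, self.hp.kappa1,
                            float(self.hp.m), self._k0mu0, self._base,
                            self._kscore, self._ptidx,
                            self._P, self._v, self._v2, self._v3,
                            self._tsum, self._tscat, self._zv, self._zM)

    def log_likelihood(self) -> float:
        """Joint marginal log likelihood of all events given the assignments."""
        return float(K._state_loglik(
            self.sample_start, self.X, self.t_arr,
            self.cl_class, self.scl, self.scl_count,
            self.klist, self.kcount,
            self.hp.kappa0, self.hp.kappa1, float(self.hp.m),
            self._k0mu0, self._base,
            self.cl_n, self.cl_sum, self.cl_scat,
            self._P, self._MC, self._v, self._v2,
            self._accA, self._accb, self._accC))

    # -- maintenance -------------------------------------------------------

    def rebuild(self) -> None:
        """Recompute all sufficient statistics from raw events in place."""
        d = self.d
        active = self.active_clusters()
        for c in active:
            mask = self.t_arr == c
            pts = self.X[mask]
            self.cl_n[c] = pts.shape[0]
            self.cl_sum[c] = pts.sum(axis=0)
            self.cl_scat[c] = pts.T @ pts
        for k in self.active_classes():
            self.k_n[k] = 0
            self.k_A[k] = 0.0
            self.k_b[k] = 0.0
            self.k_C[k] = 0.0
        for c in active:
            K._class_upd(self.cl_class[c], c, 1, self.hp.kappa1,
                         self.cl_n, self.cl_sum, self.cl_scat,
                         self.k_n, self.k_A, self.k_b, self.k_C)

    # -- views -------------------------------------------------------------

    def active_clusters(self) -> np.ndarray:
        out = []
        for j in range(self.J):
            out.extend(self.scl[j, :self.scl_count[j]])
        return np.array(out, dtype=np.int64)

    def active_classes(self) -> np.ndarray:
        return self.klist[:self.kcount[0]].copy()

    @property
    def K(self) -> int:
        """Current number of classes (global clusters)."""
        return int(self.kcount[0])

    @property
    def t(self) -> list[np.ndarray]:
        """Per-sample local-cluster indicators (indices into that sample's
        cluster list)."""
        out = []
        for j in range(self.J):
            ids = self.scl[j, :self.scl_count[j]]
            remap = {int(c): idx for idx, c in enumerate(ids)}
            seg = self.t_arr[self.sample_start[j]:self.sample_start[j + 1]]
            out.append(np.array([remap[int(c)] for c in seg], dtype=np.int64))
        return out

    @property
    def c(self) -> dict[tuple[int, int], int]:
        """Class indicator of each (sample index, local cluster index)."""
        out = {}
        kmap = {int(k): idx for idx, k in enumerate(self.active_classes())}
        for j in range(self.J):
            for idx in range(self.scl_count[j]):
                cslot = int(self.scl[j, idx])
                out[(j, idx)] = kmap[int(self.cl_class[cslot])]
        return out

    @property
    def n_jkt(self) -> dict[tuple[int, int], int]:
        out = {}
        for j in range(self.J):
            for idx in range(self.scl_count[j]):
                out[(j, idx)] = int(self.cl_n[self.scl[j, idx]])
        return out

    @property
    def m_jk(self) -> np.ndarray:
        """Sample-by-class local cluster counts."""
        ks = self.active_classes()
        kmap = {int(k): i for i, k in enumerate(ks)}
        out = np.zeros((self.J, len(ks)), dtype=np.int64)
        for j in range(self.J):
            for idx in range(self.scl_count[j]):
                cslot = self.scl[j, idx]
                out[j, kmap[int(self.cl_class[cslot])]] += 1
        return out

    @property
    def m_dot_k(self) -> np.ndarray:
        return self.m_jk.sum(axis=0)

    @property
    def class_stats(self) -> list[SuffStats]:
        out = []
        for k in self.active_classes():
            n = int(self.k_n[k])
            mask = self._class_mask(int(k))
            pts = self.X[mask]
            out.append(SuffStats(n, pts.sum(axis=0), pts.T @ pts))
        return out

    @property
    def cluster_stats(self) -> dict[tuple[int, int], SuffStats]:
        out = {}
        for j in range(self.J):
            for idx in range(self.scl_count[j]):
                c = self.scl[j, idx]
                out[(j, idx)] = SuffStats(int(self.cl_n[c]),
                                          self.cl_sum[c].copy(),
                                          self.cl_scat[c].copy())
        return out

    def _class_mask(self, k: int) -> np.ndarray:
        return np.isin(self.t_arr, [c for c in self.active_clusters()
                                    if self.cl_class[c] == k])

    def event_class_labels(self) -> np.ndarray:
        """Per-event class slot ids (not compacted)."""
        return self.cl_class[self.t_arr].copy()

    def class_niw(self, k_slot: int) -> NIWPosterior:
        """Exact structured NIW posterior of class ``k_slot``."""
        kap = self.hp.kappa0 + self.k_A[k_slot]
        eta = self._k0mu0 + self.k_b[k_slot]
        nu = self.hp.m + self.k_n[k_slot]
        Psi = self._base + self.k_C[k_slot] - np.outer(eta, eta) / kap
        return NIWPosterior(kappa=float(kap), mu=eta / kap, nu=float(nu),
                            Psi=0.5 * (Psi + Psi.T))

    # -- invariants --------------------------------------------------------

    def validate(self, atol: float = 1e-6) -> None:
        """Check structural invariants; raises AssertionError on violation."""
        assert np.all(self.t_arr >= 0), "unassigned events"
        for j in range(self.J):
            seg = self.t_arr[self.sample_start[j]:self.sample_start[j + 1]]
            ids = set(int(c) for c in self.scl[j, :self.scl_count[j]])
            counts = {c: 0 for c in ids}
            for c in seg:
                assert int(c) in ids, "event assigned to unlisted cluster"
                counts[int(c)] += 1
            for c in ids:
                assert counts[c] == self.cl_n[c] > 0, "cluster count mismatch"
        total_cl = 0
        for k in self.active_classes():
            k = int(k)
            members = [c for c in self.active_clusters()
                       if self.cl_class[c] == k]
            assert len(members) == self.k_ncl[k] > 0, "class cluster count"
            assert sum(int(self.cl_n[c]) for c in members) == self.k_n[k]
            total_cl += len(members)
        assert total_cl == self.tcount[0], "total cluster count"
        # accumulator consistency against recomputation from raw events
        snap = {int(k): (self.k_A[k], self.k_b[k].copy(), self.k_C[k].copy())
                for k in self.active_classes()}
        clsnap = {int(c): (int(self.cl_n[c]), self.cl_sum[c].copy(),
                           self.cl_scat[c].copy())
                  for c in self.active_clusters()}
        self.rebuild()
        for k, (A, b, C) in snap.items():
            assert abs(A - self.k_A[k]) <= atol * (1 + abs(A))
            assert np.allclose(b, self.k_b[k], atol=atol, rtol=atol)
            assert np.allclose(C, self.k_C[k], atol=atol, rtol=atol)
        for c, (n, sm, sc) in clsnap.items():
            assert n == self.cl_n[c]
            assert np.allclose(sm, self.cl_sum[c], atol=atol, rtol=atol)
            assert np.allclose(sc, self.cl_scat[c], atol=atol, rtol=atol)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def init_state(batch: Sequence[EventMatrix], hp: Hyperparams,
               seed: int | np.random.Generator,
               strategy: str = "sequential") -> AssignmentState:
    """Initialize the sampler state.

    ``sequential`` (default) assigns events one at a time by sampling from
    the same predictive mixture used in the ``t`` loop, which typically
    lands close to the posterior mode.  ``single`` starts with one local
    cluster per sample, all sharing one class.
    """
    state = AssignmentState(batch, hp)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    state.rng_seed = None if isinstance(seed, np.random.Generator) else int(seed)
    if strategy == "sequential":
        u = rng.random(2 * state.N)
        state.seed_sequential(u)
    elif strategy == "single":
        k = K._new_class(state.klist, state.kcount, state.k_free, state.k_ftop,
                         state.k_n, state.k_ncl, state.k_A, state.k_b,
                         state.k_C, state.k_pos)
        for j in range(state.J):
            c = K._new_cluster(j, k, state.cl_free, state.cl_ftop,
                               state.cl_n, state.cl_sum, state.cl_scat,
                               state.cl_class, state.cl_sample, state.cl_pos,
                               state.scl, state.scl_count, state.k_ncl,
                               state.tcount)
            lo, hi = state.sample_start[j], state.sample_start[j + 1]
            state.t_arr[lo:hi] = c
        state.rebuild()
    else:
        raise ValueError(f"unknown init strategy {strategy!r}")
    return state


def sample_t(state: AssignmentState, j: int, i: int, hp: Hyperparams,
             rng: np.random.Generator, strict: bool = False) -> AssignmentState:
    """Resample the local-cluster indicator of event ``i`` of sample ``j``."""
    lo, hi = state.sample_start[j], state.sample_start[j + 1]
    if not 0 <= i < hi - lo:
        raise IndexError(f"event index {i} out of range for sample {j}")
    u = rng.random(2)
    state.resample_event(int(lo + i), u[0], u[1], strict)
    return state


def sample_c(state: AssignmentState, j: int, cluster_index: int,
             hp: Hyperparams, rng: np.random.Generator) -> AssignmentState:
    """Resample the class indicator of local cluster ``cluster_index`` of
    sample ``j``."""
    if not 0 <= cluster_index < state.scl_count[j]:
        raise IndexError(f"cluster index {cluster_index} out of range")
    c = int(state.scl[j, cluster_index])
    if state.cl_n[c] == 0:
        raise ValueError("cannot resample the class of an empty cluster")
    state.resample_cluster(c, float(rng.random()))
    return state


def gibbs_sweep(state: AssignmentState, batch, hp: Hyperparams,
                rng: np.random.Generator, strict: bool = False) -> AssignmentState:
    """Run one full sweep (t loop over all events, then c loop over all
    clusters), consuming uniforms from ``rng``."""
    u = rng.random(3 * state.N)
    state.sweep(u, strict)
    return state


def run_sampler(batch: Sequence[EventMatrix], hp: Hyperparams,
                config: GibbsConfig | None = None,
                init: str = "sequential",
                strict_t_scope: bool = False) -> ClusteringResult:
    """Run the full sampler and return the consensus clustering.

    Saves ``config.n_saved`` posterior draws after burn-in, aligns their
    labels (label switching), takes the per-event mode as the consensus
    label, and summarizes each surviving class by the posterior mean of its
    Normal-inverse-Wishart posterior given the consensus assignments.
    """
    config = config or GibbsConfig()
    ss = np.random.SeedSequence(config.seed)
    s_init, s_sweep = ss.spawn(2)
    state = init_state(batch, hp, np.random.default_rng(s_init), init)
    state.rng_seed = config.seed
    rng = np.random.default_rng(s_sweep)
    save_at = set(config.save_sweeps)
    trace = np.zeros(config.n_sweeps, dtype=np.int64)
    draws: list[np.ndarray] = []
    logliks: list[float] = []
    for sweep_idx in range(1, config.n_sweeps + 1):
        gibbs_sweep(state, batch, hp, rng, strict_t_scope)
        trace[sweep_idx - 1] = state.K
        if config.rebuild_every and sweep_idx % config.rebuild_every == 0:
            state.rebuild()
        if sweep_idx in save_at:
            draws.append(state.event_class_labels())
            logliks.append(state.log_likelihood())
    final_ll = state.log_likelihood()
    labels = relabel_and_consensus(draws)
    labels, summaries = _summarize(labels, state)
    return ClusteringResult(
        labels=labels, summaries=summaries, saved_draws=draws,
        gibbs_log_likelihood=float(np.mean(logliks)),
        gibbs_log_likelihood_final=final_ll,
        gibbs_log_likelihoods=logliks,
        trace=trace, sample_ids=state.sample_ids,
        sample_start=state.sample_start, hp=hp, config=config,
        local_cluster_ids=np.concatenate(state.t))


def relabel_and_consensus(saved_draws: Sequence[np.ndarray]) -> np.ndarray:
    """Resolve label switching across saved draws and return consensus labels.

    Later draws are aligned to the first by maximum-overlap matching of the
    event-level contingency table (Hungarian assignment); labels with no
    counterpart receive fresh ids.  The per-event consensus is the mode of
    the aligned labels, ties broken toward the last draw.
    """
    if len(saved_draws) == 0:
        raise ValueError("consensus requires at least one saved draw")
    ref = saved_draws[0]
    aligned = [ref]
    next_free = int(ref.max()) + 1
    for draw in saved_draws[1:]:
        ref_ids = np.unique(ref)
        draw_ids = np.unique(draw)
        table = np.zeros((len(ref_ids), len(draw_ids)), dtype=np.int64)
        ref_idx = np.searchsorted(ref_ids, ref)
        draw_idx = np.searchsorted(draw_ids, draw)
        np.add.at(table, (ref_idx, draw_idx), 1)
        rows, cols = linear_sum_assignment(table, maximize=True)
        mapping = {}
        for r, cidx in zip(rows, cols):
            if table[r, cidx] > 0:
                mapping[int(draw_ids[cidx])] = int(ref_ids[r])
        out = np.empty_like(draw)
        for did in draw_ids:
            did = int(did)
            if did not in mapping:
                mapping[did] = next_free
                next_free += 1
            out[draw == did] = mapping[did]
        aligned.append(out)
    stacked = np.stack(aligned)  # (S, N)
    S, N = stacked.shape
    if S == 1:
        return stacked[0].copy()
    consensus = np.empty(N, dtype=np.int64)
    for i in range(N):
        vals, counts = np.unique(stacked[:, i], return_counts=True)
        top = counts.max()
        cands = set(vals[counts == top].tolist())
        if int(stacked[-1, i]) in cands:
            consensus[i] = stacked[-1, i]
        else:
            # latest draw whose label is among the tied candidates
            for s in range(S - 1, -1, -1):
                if int(stacked[s, i]) in cands:
                    consensus[i] = stacked[s, i]
                    break
    return consensus


def _summarize(labels: np.ndarray, state: AssignmentState
               ) -> tuple[np.ndarray, list[GlobalClusterSummary]]:
    """Relabel consensus classes by descending size and build summaries.

    Class parameters are posterior means under the exact structured NIW
    posterior with one local cluster per (sample, class) block of the
    consensus labeling.
    """
    hp = state.hp
    d = state.d
    ids, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    new_labels = np.empty_like(labels)
    summaries = []
    for rank, oi in enumerate(order):
        old = ids[oi]
        mask = labels == old
        new_labels[mask] = rank
        clusters = []
        per_sample = np.zeros(state.J, dtype=np.int64)
        for j in range(state.J):
            lo, hi = state.sample_start[j], state.sample_start[j + 1]
            sub = mask[lo:hi]
            per_sample[j] = int(sub.sum())
            if per_sample[j] > 0:
                clusters.append(SuffStats.from_points(state.X[lo:hi][sub]))
        niw = posterior_niw(hp, clusters)
        cov = niw.Psi / (niw.nu - d - 1)
        summaries.append(GlobalClusterSummary(
            class_id=rank, mean=niw.mu, covariance=cov,
            total_count=int(counts[oi]), per_sample_counts=per_sample))
    return new_labels, summaries


def prune_small_clusters(result: ClusteringResult,
                         threshold_fraction: float = DEFAULT_PRUNE_THRESHOLD
                         ) -> ClusteringResult:
    """Drop classes holding less than ``threshold_fraction`` of all events.

    Pruned classes disappear from the summaries and the reported cluster
    count; their events keep their labels but are flagged so that
    proportion features can renormalize over surviving classes.
    """
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in [0, 1)")
    total = result.labels.size
    pruned = tuple(s.class_id for s in result.summaries
                   if s.total_count < threshold_fraction * total)
    kept = [s for s in result.summaries if s.class_id not in pruned]
    return replace(result, summaries=kept,
                   pruned_class_ids=tuple(sorted(set(result.pruned_class_ids)
                                                 | set(pruned))))


@dataclass
class Kappa1Selection:
    """Outcome of the random-effects scale grid search."""

    best_kappa1: float
    scores: dict[float, float]
    results: dict[float, ClusteringResult] = field(default_factory=dict)


def select_kappa1(batch: Sequence[EventMatrix], hp: Hyperparams,
                  config: GibbsConfig | None = None,
                  grid: Sequence[float] = DEFAULT_KAPPA1_GRID,
                  criterion: str = "averaged",
                  keep_results: bool = False) -> Kappa1Selection:
    """Select ``kappa1`` from a grid by maximizing the Gibbs likelihood.

    The score of each candidate is the joint marginal likelihood of all
    events given the assignments, averaged over the saved draws
    (``criterion="averaged"``, default) or evaluated at the final state
    (``criterion="final"``).
    """
    if len(grid) == 0:
        raise ValueError("kappa1 grid must be non-empty")
    if criterion not in ("averaged", "final"):
        raise ValueError("criterion must be 'averaged' or 'final'")
    scores: dict[float, float] = {}
    results: dict[float, ClusteringResult] = {}
    for k1 in grid:
        res = run_sampler(batch, replace(hp, kappa1=float(k1)), config)
        scores[float(k1)] = (res.gibbs_log_likelihood
                             if criterion == "averaged"
                             else res.gibbs_log_likelihood_final)
        if keep_results:
            results[float(k1)] = res
    best = max(scores, key=scores.get)
    return Kappa1Selection(best_kappa1=best, scores=scores, results=results)


# ---------------------------------------------------------------------------
# pooled DPGMM baseline
# ---------------------------------------------------------------------------


class PooledDPGMMState:
    """Mutable state of the single-level pooled DP mixture sampler."""

    def __init__(self, batch: Sequence[EventMatrix], hp: Hyperparams):
        check_batch(list(batch))
        d = hp.dim
        sizes = [s.n_events for s in batch]
        self.sample_ids = [s.sample_id for s in batch]
        self.sample_start = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        self.X = np.concatenate([s.data for s in batch], axis=0)
        self.hp = hp
        self.d = d
        N = self.X.shape[0]
        self.N = N
        CC = N + 2
        self.t = np.full(N, -1, dtype=np.int64)
        self.cl_n = np.zeros(CC, dtype=np.int64)
        self.cl_sum = np.zeros((CC, d))
        self.cl_scat = np.zeros((CC, d, d))
        self.cl_class = np.zeros(CC, dtype=np.int64)
        self.cl_sample = np.zeros(CC, dtype=np.int64)
        self.cl_pos = np.zeros(CC, dtype=np.int64)
        self.cl_free = np.arange(CC - 1, -1, -1, dtype=np.int64)
        self.cl_ftop = np.array([CC], dtype=np.int64)
        self.scl = np.zeros((1, N + 1), dtype=np.int64)
        self.scl_count = np.zeros(1, dtype=np.int64)
        self.tcount = np.zeros(1, dtype=np.int64)
        self._score = np.zeros(N + 2)
        self._P = np.zeros((d, d))
        self._v = np.zeros(d)
        self._v2 = np.zeros(d)
        self._v3 = np.zeros(d)
        self._zv = np.zeros(d)
        self._zM = np.zeros((d, d))
        self._ptidx = np.zeros(N, dtype=np.int64)
        self._tsum = np.zeros(d)
        self._tscat = np.zeros((d, d))
        self._k0mu0 = hp.kappa0 * hp.mu0
        self._base = hp.Sigma0 + hp.kappa0 * np.outer(hp.mu0, hp.mu0)

    def _args(self):
        hp = self.hp
        return (self.X, self.t, self.cl_n, self.cl_sum, self.cl_scat,
                self.cl_class, self.cl_sample, self.cl_pos,
                self.cl_free, self.cl_ftop, self.scl, self.scl_count,
                self.tcount, hp.alpha, hp.kappa0, float(hp.m),
                self._k0mu0, self._base,
                self._score, self._P, self._v, self._v2, self._v3,
                self._zv, self._zM)

    def seed_sequential(self, u: np.ndarray) -> None:
        K._dpgmm_sweep(u, self.N, True, *self._args())

    def sweep(self, u: np.ndarray) -> None:
        K._dpgmm_sweep(u, self.N, False, *self._args())

    @property
    def n_clusters(self) -> int:
        return int(self.scl_count[0])

    def log_likelihood(self) -> float:
        hp = self.hp
        return float(K._dpgmm_loglik(
            self.X, self.t, self.scl, self.scl_count,
            hp.kappa0, float(hp.m), self._k0mu0, self._base,
            self._ptidx, self._P, self._v, self._v2, self._v3,
            self._tsum, self._tscat))


def fit_pooled_dpgmm(batch: Sequence[EventMatrix], hp: Hyperparams,
                     config: GibbsConfig | None = None) -> ClusteringResult:
    """Collapsed Dirichlet-process Gaussian mixture on pooled events.

    All samples are concatenated and clustered jointly with no hierarchy and
    no random effects; the recovered mixture components serve directly as
    global clusters.  Uses the same schedule, consensus and summary
    machinery as the hierarchical sampler.
    """
    config = config or GibbsConfig()
    state = PooledDPGMMState(batch, hp)
    d = hp.dim
    ss = np.random.SeedSequence(config.seed)
    s_init, s_sweep = ss.spawn(2)
    state.seed_sequential(np.random.default_rng(s_init).random(state.N))
    rng = np.random.default_rng(s_sweep)
    save_at = set(config.save_sweeps)
    trace = np.zeros(config.n_sweeps, dtype=np.int64)
    draws: list[np.ndarray] = []
    logliks: list[float] = []
    for sweep_idx in range(1, config.n_sweeps + 1):
        state.sweep(rng.random(state.N))
        trace[sweep_idx - 1] = state.n_clusters
        if sweep_idx in save_at:
            draws.append(state.t.copy())
            logliks.append(state.log_likelihood())
    final_ll = state.log_likelihood()
    labels = relabel_and_consensus(draws)
    # summaries under the flat (single-level) posterior
    ids, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    new_labels = np.empty_like(labels)
    summaries = []
    for rank, oi in enumerate(order):
        mask = labels == ids[oi]
        stats = SuffStats.from_points(state.X[mask])
        new_labels[mask] = rank
        niw = posterior_niw(hp, [stats], kappa1=math.inf)
        per_sample = np.array(
            [int(mask[state.sample_start[j]:state.sample_start[j + 1]].sum())
             for j in range(len(batch))], dtype=np.int64)
        summaries.append(GlobalClusterSummary(
            class_id=rank, mean=niw.mu,
            covariance=niw.Psi / (niw.nu - d - 1),
            total_count=int(counts[oi]), per_sample_counts=per_sample))
    return ClusteringResult(
        labels=new_labels, summaries=summaries, saved_draws=draws,
        gibbs_log_likelihood=float(np.mean(logliks)),
        gibbs_log_likelihood_final=final_ll,
        gibbs_log_likelihoods=logliks,
        trace=trace, sample_ids=state.sample_ids,
        sample_start=state.sample_start,
        hp=hp, config=config, method="dpgmm",
        local_cluster_ids=new_labels.copy())
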