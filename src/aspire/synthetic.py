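"""Synthetic-data generators with full ground truth.

Two generators are provided:

* :func:`simulate_experiment1` builds the 25-sample, two-dimensional anomaly
  benchmark: 10 normal samples drawn from three shared global clusters, and
  three groups of 5 anomalous samples each — altered mixing proportions,
  added rare populations of a handful of events, and location/scale
  distortions mimicking measurement artifacts (e.g. mis-compensation).
  Every sample's local cluster means are displaced around the global means
  with random-effects scale ``kappa1_gen``, so no two samples share cluster
  locations exactly.

* :func:`simulate_from_model` draws batches directly from the full
  generative model (NIW global parameters, per-sample local clusters from a
  Dirichlet process within each class, local means displaced by the random
  effect), for parameter-recovery tests.

Numeric defaults of the benchmark live in ``data/experiment1.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.stats import invwishart

from .data import EventMatrix
from .model import Hyperparams

GROUP_NORMAL = "normal"
GROUP_PROPORTION = "proportion-shift"
GROUP_RARE = "rare-population"
GROUP_ARTIFACT = "artifact"


def _load_defaults() -> dict:
    text = resources.files("aspire").joinpath("data/experiment1.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(eq=False)
class GeneratorSpec:
    """Parameters of the 25-sample anomaly benchmark."""

    n_samples_normal: int
    n_anomalous_per_group: int
    events_per_sample: int
    dim: int
    global_means: np.ndarray          # (3, d) normal cluster means
    global_covs: np.ndarray           # (3, d, d)
    normal_proportions: np.ndarray
    group1_proportions: np.ndarray
    rare_means: np.ndarray
    rare_covs: np.ndarray
    group3_shifts: np.ndarray
    kappa1_gen: float
    rare_pop_size: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.global_means = np.asarray(self.global_means, dtype=float)
        self.global_covs = np.asarray(self.global_covs, dtype=float)
        self.normal_proportions = np.asarray(self.normal_proportions, dtype=float)
        self.group1_proportions = np.asarray(self.group1_proportions, dtype=float)
        self.rare_means = np.asarray(self.rare_means, dtype=float)
        self.rare_covs = np.asarray(self.rare_covs, dtype=float)
        self.group3_shifts = np.asarray(self.group3_shifts, dtype=float)
        for name in ("normal_proportions", "group1_proportions"):
            p = getattr(self, name)
            if not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name} must sum to 1")
            if np.any(p < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.kappa1_gen <= 0:
            raise ValueError("kappa1_gen must be positive")
        if self.rare_pop_size < 1:
            raise ValueError("rare_pop_size must be >= 1")
        n_rare_events = 3 * self.rare_pop_size
        if n_rare_events >= self.events_per_sample:
            raise ValueError("rare populations cannot exhaust a sample")

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "GeneratorSpec":
        cfg = _load_defaults()
        kwargs = dict(
            n_samples_normal=cfg["n_samples_normal"],
            n_anomalous_per_group=cfg["n_anomalous_per_group"],
            events_per_sample=cfg["events_per_sample"],
            dim=cfg["dim"],
            global_means=cfg["normal_means"],
            global_covs=cfg["normal_covs"],
            normal_proportions=cfg["normal_proportions"],
            group1_proportions=cfg["group1_proportions"],
            rare_means=cfg["rare_means"],
            rare_covs=cfg["rare_covs"],
            group3_shifts=cfg["group3_shifts"],
            kappa1_gen=cfg["kappa1_gen"],
            rare_pop_size=cfg["rare_pop_size"],
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def n_global_clusters(self) -> int:
        """Total distinct global clusters: normal + rare + artifact."""
        return (self.global_means.shape[0] + self.rare_means.shape[0]
                + self.group3_shifts.shape[0])


@dataclass(eq=False)
class GroundTruth:
    """Everything the generator knows about a simulated batch."""

    labels: dict[str, np.ndarray]             # per-event global cluster ids
    groups: dict[str, str]                    # sample_id -> group name
    anomaly_flags: dict[str, bool]
    means: np.ndarray                         # (K, d) true global means
    covs: np.ndarray                          # (K, d, d) true global covariances
    local_means: dict[tuple[str, int], np.ndarray]

    @property
    def n_anomalous(self) -> int:
        return int(sum(self.anomaly_flags.values()))

    def labels_concatenated(self, sample_ids: list[str]) -> np.ndarray:
        return np.concatenate([self.labels[s] for s in sample_ids])


def _draw_sample(rng: np.random.Generator, sample_id: str,
                 cluster_ids: list[int], counts: list[int],
                 means: np.ndarray, covs: np.ndarray, kappa1: float,
                 labels_out: dict, local_out: dict) -> EventMatrix:
    """Draw one sample: local means around the global means, then events."""
    pts, labs = [], []
    for cid, n in zip(cluster_ids, counts):
        local = rng.multivariate_normal(means[cid], covs[cid] / kappa1)
        local_out[(sample_id, cid)] = local
        if n > 0:
            pts.append(rng.multivariate_normal(local, covs[cid], size=n))
            labs.append(np.full(n, cid, dtype=np.int64))
    x = np.concatenate(pts, axis=0)
    lab = np.concatenate(labs)
    perm = rng.permutation(x.shape[0])
    labels_out[sample_id] = lab[perm]
    return EventMatrix(sample_id=sample_id, data=x[perm])


def simulate_experiment1(spec: GeneratorSpec | None = None,
                         seed: int | None = None
                         ) -> tuple[list[EventMatrix], GroundTruth]:
    """Generate the 25-sample anomaly benchmark.

    Returns the batch (normal samples first, then the three anomalous
    groups) and the full ground truth.  Global cluster ids: 0..2 normal,
    3..5 rare populations, 6..8 artifact clusters.
    """
    spec = spec or GeneratorSpec.default()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    d = spec.dim
    n3 = spec.global_means.shape[0]
    means = np.concatenate([
        spec.global_means,
        spec.rare_means,
        spec.global_means + spec.group3_shifts,
    ])
    covs = np.concatenate([
        spec.global_covs,
        spec.rare_covs,
        spec.global_covs / 4.0,        # standard deviations halved per dimension
    ])
    labels: dict[str, np.ndarray] = {}
    local_means: dict[tuple[str, int], np.ndarray] = {}
    groups: dict[str, str] = {}
    flags: dict[str, bool] = {}
    batch: list[EventMatrix] = []

    def add(sample_id, group, flag, cluster_ids, counts):
        groups[sample_id] = group
        flags[sample_id] = flag
        batch.append(_draw_sample(rng, sample_id, cluster_ids, counts,
                                  means, covs, spec.kappa1_gen,
                                  labels, local_means))

    normal_ids = list(range(n3))
    for i in range(spec.n_samples_normal):
        counts = rng.multinomial(spec.events_per_sample, spec.normal_proportions)
        add(f"normal_{i:02d}", GROUP_NORMAL, False, normal_ids, list(counts))
    for i in range(spec.n_anomalous_per_group):
        counts = rng.multinomial(spec.events_per_sample, spec.group1_proportions)
        add(f"propshift_{i:02d}", GROUP_PROPORTION, True, normal_ids, list(counts))
    rare_ids = list(range(n3, n3 + spec.rare_means.shape[0]))
    for i in range(spec.n_anomalous_per_group):
        n_rare = spec.rare_pop_size * len(rare_ids)
        counts = rng.multinomial(spec.events_per_sample - n_rare,
                                 spec.normal_proportions)
        add(f"rarepop_{i:02d}", GROUP_RARE, True,
            normal_ids + rare_ids,
            list(counts) + [spec.rare_pop_size] * len(rare_ids))
    art_ids = list(range(n3 + len(rare_ids), spec.n_global_clusters))
    for i in range(spec.n_anomalous_per_group):
        counts = rng.multinomial(spec.events_per_sample, spec.normal_proportions)
        add(f"artifact_{i:02d}", GROUP_ARTIFACT, True, art_ids, list(counts))
    return batch, GroundTruth(labels=labels, groups=groups,
                              anomaly_flags=flags, means=means, covs=covs,
                              local_means=local_means)


def simulate_from_model(K: int, J: int, n_per_sample: int, hp: Hyperparams,
                        class_weights=None, seed: int = 0,
                        min_separation: float | None = None,
                        ) -> tuple[list[EventMatrix], GroundTruth]:
    """Draw a batch directly from the generative model.

    Global parameters come from the NIW base distribution, per-sample local
    clusters from a Chinese-restaurant process with precision ``hp.alpha``
    within each class, local means from ``N(mu_k, Sigma_k/kappa1)`` and
    events from ``N(local mean, Sigma_k)``.  ``class_weights`` are the
    per-sample class mixing proportions (uniform by default; the top-level
    stick weights are not resampled per batch).

    ``min_separation`` optionally rejects global mean configurations in
    which any two class means are closer than this multiple of the larger
    of the two clusters' root-maximum-eigenvalue scales, guaranteeing
    identifiable classes in recovery experiments.
    """
    if K < 1 or J < 1:
        raise ValueError("K and J must be >= 1")
    rng = np.random.default_rng(seed)
    d = hp.dim
    weights = (np.full(K, 1.0 / K) if class_weights is None
               else np.asarray(class_weights, dtype=float))
    if weights.size != K or not np.isclose(weights.sum(), 1.0):
        raise ValueError("class_weights must be a length-K simplex vector")
    covs = np.stack([invwishart.rvs(df=hp.m, scale=hp.Sigma0, random_state=rng)
                     .reshape(d, d) for _ in range(K)])
    scales = np.sqrt([np.linalg.eigvalsh(c).max() for c in covs])
    for _ in range(10000):
        means = np.stack([rng.multivariate_normal(hp.mu0, covs[k] / hp.kappa0)
                          for k in range(K)])
        if min_separation is None or K == 1:
            break
        dist = np.linalg.norm(means[:, None] - means[None, :], axis=-1)
        lim = min_separation * np.maximum(scales[:, None], scales[None, :])
        if np.all(dist[np.triu_indices(K, 1)] >= lim[np.triu_indices(K, 1)]):
            break
    else:
        raise RuntimeError("could not achieve the requested class separation")
    labels: dict[str, np.ndarray] = {}
    local_means: dict[tuple[str, int], np.ndarray] = {}
    batch: list[EventMatrix] = []
    for j in range(J):
        sid = f"sample_{j:03d}"
        cls = rng.choice(K, size=n_per_sample, p=weights)
        x = np.empty((n_per_sample, d))
        for k in range(K):
            idx = np.flatnonzero(cls == k)
            if idx.size == 0:
                continue
            # CRP partition of this class's events into local clusters
            tables: list[int] = []       # table sizes
            assign = np.empty(idx.size, dtype=np.int64)
            for ii in range(idx.size):
                probs = np.array(tables + [hp.alpha], dtype=float)
                choice = rng.choice(probs.size, p=probs / probs.sum())
                if choice == len(tables):
                    tables.append(1)
                else:
                    tables[choice] += 1
                assign[ii] = choice
            for tt in range(len(tables)):
                local = rng.multivariate_normal(means[k], covs[k] / hp.kappa1)
                local_means[(sid, k * 1000 + tt)] = local
                members = idx[assign == tt]
                x[members] = rng.multivariate_normal(local, covs[k],
                                                     size=members.size)
        batch.append(EventMatrix(sample_id=sid, data=x))
        labels[sid] = cls.astype(np.int64)
    groups = {s.sample_id: GROUP_NORMAL for s in batch}
    flags = {s.sample_id: False for s in batch}
    return batch, GroundTruth(labels=labels, groups=groups,
                              anomaly_flags=flags, means=means, covs=covs,
                              local_means=local_means)
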