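"""Conjugate Normal-inverse-Wishart machinery for the random-effects mixture.

The hierarchy collapsed here is, for one global cluster (class) ``k``:

.. math::

    (\\mu_k, \\Sigma_k) &\\sim \\mathrm{NIW}(\\mu_0, \\kappa_0, m, \\Sigma_0) \\\\
    \\mu_{jkt} \\mid \\mu_k, \\Sigma_k &\\sim \\mathcal N(\\mu_k, \\Sigma_k/\\kappa_1) \\\\
    x \\mid \\mu_{jkt}, \\Sigma_k &\\sim \\mathcal N(\\mu_{jkt}, \\Sigma_k)

where ``mu_jkt`` is the mean of local cluster ``t`` of class ``k`` in sample
``j`` — a *noisy realization* of the global mean, with the random-effects
scale ``kappa1`` controlling how far local means wander.  Covariances of all
local clusters of a class are identical to the class covariance; only the
means are subject to random effects.

Because every layer is Gaussian given ``Sigma_k`` and the covariance of each
layer is a multiple of ``Sigma_k``, all marginal predictive densities needed
by the collapsed Gibbs sampler are multivariate Student-t distributions.
This module derives them in closed form; the test suite validates each one
against brute-force Monte-Carlo integration of the hierarchy above.

Two conditioning conventions are exposed:

* a *flat* convention, where the conditioning set of a class is summarized
  by pooled sufficient statistics and treated as direct draws from
  ``N(mu_k, Sigma_k)`` (exact when ``kappa1`` is infinite, i.e. no random
  effects);
* a *structured* convention, where the conditioning set is a collection of
  local clusters, each entering the class posterior through its
  precision-weighted mean (weight ``n_t * kappa1 / (n_t + kappa1)``) and its
  within-cluster scatter.  This is the exact collapsed posterior of the
  hierarchy and is what the sampler uses.

In both conventions the *candidate* local cluster (the one a new point is
being scored against, possibly empty) is handled exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import multivariate_t


class NumericalBreakdownError(RuntimeError):
    """Raised when a posterior scale matrix loses positive definiteness."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Hyperparams:
    """The seven free parameters of the model.

    Attributes
    ----------
    alpha
        Precision of the within-sample Dirichlet process; larger values
        favour more local clusters per sample.
    gamma
        Precision of the top-level Dirichlet process over classes.
    kappa0
        Scaling of the prior on the class mean: ``mu_k ~ N(mu0, Sigma_k/kappa0)``.
        Smaller values let class means spread further from ``mu0``.
    kappa1
        Random-effects scaling: ``mu_jkt ~ N(mu_k, Sigma_k/kappa1)``.  Small
        values mean strong sample-to-sample displacement of local clusters;
        very large values recover exact sharing of the class mean.
    mu0
        Prior mean (d-vector), conventionally the pooled data mean.
    Sigma0
        Inverse-Wishart scale matrix (d x d, symmetric positive definite),
        conventionally ``I / s``.
    m
        Inverse-Wishart degrees of freedom; must satisfy ``m >= d + 2`` so
        the prior expectation ``E[Sigma] = Sigma0 / (m - d - 1)`` exists.
    s
        The scale constant behind the ``Sigma0 = I/s`` default (kept for
        bookkeeping; ``Sigma0`` itself is authoritative).
    """

    alpha: float
    gamma: float
    kappa0: float
    kappa1: float
    mu0: np.ndarray
    Sigma0: np.ndarray
    m: float
    s: float = 1.0

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=np.float64).ravel()
        self.Sigma0 = np.asarray(self.Sigma0, dtype=np.float64)
        d = self.mu0.size
        if self.Sigma0.shape != (d, d):
            raise ValueError("Sigma0 shape does not match mu0 dimension")
        for name in ("alpha", "gamma", "kappa0", "kappa1", "s"):
            if getattr(self, name) <= 0 and not (
                name in ("alpha", "gamma") and getattr(self, name) == 0.0
            ):
                # alpha/gamma == 0 is allowed as a degenerate limit used in tests
                if getattr(self, name) < 0:
                    raise ValueError(f"{name} must be positive")
                if name not in ("alpha", "gamma"):
                    raise ValueError(f"{name} must be positive")
        if self.m < d + 2:
            raise ValueError(f"m must be at least d + 2 = {d + 2}, got {self.m}")
        if not np.allclose(self.Sigma0, self.Sigma0.T, atol=1e-10):
            raise ValueError("Sigma0 must be symmetric")
        try:
            np.linalg.cholesky(self.Sigma0)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - message only
            raise ValueError("Sigma0 must be positive definite") from exc

    @property
    def dim(self) -> int:
        return self.mu0.size


@dataclass(eq=False)
class SuffStats:
    """Zero/first/second-moment sufficient statistics of a point set.

    ``n`` points with sum vector ``sum`` and raw scatter ``sum_i x_i x_i^T``.
    """

    n: int
    sum: np.ndarray
    scatter: np.ndarray

    @classmethod
    def empty(cls, d: int) -> "SuffStats":
        return cls(0, np.zeros(d), np.zeros((d, d)))

    @classmethod
    def from_points(cls, x: np.ndarray) -> "SuffStats":
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return cls(x.shape[0], x.sum(axis=0), x.T @ x)

    def copy(self) -> "SuffStats":
        return SuffStats(self.n, self.sum.copy(), self.scatter.copy())

    @property
    def mean(self) -> np.ndarray:
        if self.n == 0:
            raise ValueError("mean of empty stats")
        return self.sum / self.n

    def centered_scatter(self) -> np.ndarray:
        """``sum_i (x_i - xbar)(x_i - xbar)^T``; zero matrix when empty."""
        if self.n == 0:
            return np.zeros_like(self.scatter)
        return self.scatter - np.outer(self.sum, self.sum) / self.n


@dataclass(eq=False)
class StudentTParams:
    """Parameters of a multivariate Student-t predictive density."""

    dof: float
    center: np.ndarray
    scale: np.ndarray

    def logpdf(self, x: np.ndarray) -> float | np.ndarray:
        return student_t_logpdf(x, self)


@dataclass(eq=False)
class NIWPosterior:
    """Normal-inverse-Wishart posterior over a class's ``(mu_k, Sigma_k)``."""

    kappa: float
    mu: np.ndarray
    nu: float
    Psi: np.ndarray


# ---------------------------------------------------------------------------
# hyperparameter defaults and sufficient statistics
# ---------------------------------------------------------------------------


def default_hyperparams(
    batch,
    s: float = 1.0,
    kappa0: float = 0.01,
    kappa1: float = 0.05,
    alpha: float = 1.0,
    gamma: float = 1.0,
) -> Hyperparams:
    """Data-driven default hyperparameters for a batch.

    ``alpha`` and ``gamma`` default to the vague value 1, the inverse-Wishart
    degrees of freedom ``m`` to the minimum feasible ``d + 2`` (maximally
    diffuse covariance prior with a finite mean), ``mu0`` to the pooled mean
    of all events across all samples, and ``Sigma0`` to ``I / s``.

    ``kappa0`` and ``s`` lack a universal default; the shipped values target
    channel-standardized data whose clusters have roughly unit covariance
    and whose means spread over tens of units.
    """
    from .data import check_batch, pooled_data

    d = check_batch(batch)
    pooled = pooled_data(batch)
    return Hyperparams(
        alpha=alpha,
        gamma=gamma,
        kappa0=kappa0,
        kappa1=kappa1,
        mu0=pooled.mean(axis=0),
        Sigma0=np.eye(d) / s,
        m=float(d + 2),
        s=s,
    )


def suffstats_update(stats: SuffStats, x: np.ndarray, direction: str) -> SuffStats:
    """Return ``stats`` with point ``x`` added or removed (non-mutating)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    out = stats.copy()
    if direction == "add":
        out.n += 1
        out.sum += x
        out.scatter += np.outer(x, x)
    elif direction == "remove":
        if stats.n < 1:
            raise ValueError("cannot remove a point from empty sufficient statistics")
        out.n -= 1
        out.sum -= x
        out.scatter -= np.outer(x, x)
        if out.n == 0:
            out.sum[:] = 0.0
            out.scatter[:] = 0.0
    else:
        raise ValueError(f"direction must be 'add' or 'remove', got {direction!r}")
    return out


# ---------------------------------------------------------------------------
# posteriors and predictives
# ---------------------------------------------------------------------------


def posterior_niw(
    hp: Hyperparams,
    clusters: Iterable[SuffStats] = (),
    kappa1: float | None = None,
) -> NIWPosterior:
    """Collapsed NIW posterior of a class given its local clusters.

    Each local cluster of size ``n_t`` informs the class mean only through
    its own mean, which (after integrating the local mean) is distributed
    ``N(mu_k, Sigma_k (1/n_t + 1/kappa1))``; it therefore enters the
    posterior with the *effective weight* ``w_t = n_t kappa1/(n_t+kappa1)``,
    bounded above by ``kappa1``.  The within-cluster scatter informs the
    covariance at full strength.

    With ``kappa1 = inf`` (no random effects) this is the textbook NIW
    update treating every point as a direct draw from ``N(mu_k, Sigma_k)``.
    """
    if kappa1 is None:
        kappa1 = hp.kappa1
    d = hp.dim
    kap = hp.kappa0
    eta = hp.kappa0 * hp.mu0.copy()
    nu = hp.m
    Lam = hp.Sigma0 + hp.kappa0 * np.outer(hp.mu0, hp.mu0)
    for st in clusters:
        if st.n == 0:
            continue
        if math.isinf(kappa1):
            w = float(st.n)
            b = st.sum
            C = st.scatter
        else:
            w = st.n * kappa1 / (st.n + kappa1)
            b = kappa1 * st.sum / (st.n + kappa1)
            C = st.scatter - np.outer(st.sum, st.sum) / (st.n + kappa1)
        kap += w
        eta = eta + b
        nu += st.n
        Lam = Lam + C
    mu = eta / kap
    Psi = Lam - np.outer(eta, eta) / kap
    Psi = 0.5 * (Psi + Psi.T)
    return NIWPosterior(kappa=kap, mu=mu, nu=nu, Psi=Psi)


def _as_niw(class_stats, hp: Hyperparams) -> NIWPosterior:
    """Coerce flat stats / cluster list / ready posterior to an NIW posterior."""
    if isinstance(class_stats, NIWPosterior):
        return class_stats
    if class_stats is None:
        return posterior_niw(hp)
    if isinstance(class_stats, SuffStats):
        return posterior_niw(hp, [class_stats], kappa1=math.inf)
    return posterior_niw(hp, class_stats)  # sequence of per-cluster stats


def predictive_t_params(
    niw: NIWPosterior,
    cluster_stats: SuffStats | None,
    kappa1: float,
) -> StudentTParams:
    """Student-t predictive of a point joining a local cluster of the class.

    ``cluster_stats`` holds the candidate cluster's current members (``None``
    or empty for a brand-new local cluster).  The cluster's shared local mean
    and the class parameters are both marginalized exactly:

    * conditioning on the cluster updates the class posterior through the
      cluster's weighted mean and scatter;
    * the new point is centered on the posterior blend
      ``(kappa1 * mu'' + n * ybar) / (kappa1 + n)`` of the class mean and the
      cluster's empirical mean, with covariance factor
      ``1 + 1/(kappa1+n) + (kappa1/(kappa1+n))^2 / kappa''``.
    """
    d = niw.mu.size
    if cluster_stats is None or cluster_stats.n == 0:
        kap2, mu2, nu2, Psi2 = niw.kappa, niw.mu, niw.nu, niw.Psi
        n = 0
        ybar = np.zeros(d)
    else:
        n = cluster_stats.n
        ybar = cluster_stats.mean
        S = cluster_stats.centered_scatter()
        if math.isinf(kappa1):
            w = float(n)
        else:
            w = n * kappa1 / (n + kappa1)
        kap2 = niw.kappa + w
        mu2 = (niw.kappa * niw.mu + w * ybar) / kap2
        nu2 = niw.nu + n
        dev = ybar - niw.mu
        Psi2 = niw.Psi + S + (niw.kappa * w / (niw.kappa + w)) * np.outer(dev, dev)
    if math.isinf(kappa1):
        center = mu2 if n == 0 else mu2  # local mean pinned to the class mean
        c = 1.0 + 1.0 / kap2
    else:
        center = (kappa1 * mu2 + n * ybar) / (kappa1 + n)
        a = kappa1 / (kappa1 + n)
        c = 1.0 + 1.0 / (kappa1 + n) + a * a / kap2
    dof = nu2 - d + 1
    if dof <= 0:
        raise NumericalBreakdownError(f"non-positive predictive dof {dof}")
    scale = Psi2 * (c / dof)
    return StudentTParams(dof=dof, center=center, scale=0.5 * (scale + scale.T))


def student_t_logpdf(x: np.ndarray, tp: StudentTParams) -> float | np.ndarray:
    """Multivariate Student-t log density (delegates to scipy)."""
    try:
        rv = multivariate_t(loc=tp.center, shape=tp.scale, df=tp.dof)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise NumericalBreakdownError(
            f"predictive scale matrix is not positive definite: {exc}"
        ) from exc
    return rv.logpdf(np.asarray(x, dtype=np.float64))


def class_predictive(class_stats, hp: Hyperparams) -> StudentTParams:
    """Predictive density of a new event opening a *new* local cluster of a class.

    ``class_stats`` may be flat pooled :class:`SuffStats` (conditioning
    points treated as direct class draws), a sequence of per-cluster
    :class:`SuffStats` (exact random-effects conditioning), or a ready
    :class:`NIWPosterior`.  Empty statistics give the prior predictive.
    """
    niw = _as_niw(class_stats, hp)
    return predictive_t_params(niw, None, hp.kappa1)


def prior_predictive(x: np.ndarray, hp: Hyperparams) -> float:
    """Log predictive density of an event under a brand-new class.

    A Student-t centered at ``mu0`` with ``m - d + 1`` degrees of freedom and
    scale ``Sigma0 (1 + 1/kappa1 + 1/kappa0) / (m - d + 1)``: the chain of
    kappas collapses into a single variance inflation factor.
    """
    return float(student_t_logpdf(x, class_predictive(None, hp)))


def local_cluster_predictive(
    x: np.ndarray,
    cluster_stats: SuffStats,
    class_stats_excl,
    hp: Hyperparams,
) -> float:
    """Log predictive of ``x`` joining an existing non-empty local cluster.

    ``class_stats_excl`` summarizes the class's *other* data (the candidate
    cluster's members excluded); the candidate cluster itself is conditioned
    on exactly.  As ``kappa1 -> inf`` this converges to
    :func:`class_predictive` evaluated on the union of cluster and class
    statistics (no random effects: the local mean equals the class mean).
    """
    if cluster_stats is None or cluster_stats.n < 1:
        raise ValueError(
            "local_cluster_predictive requires a non-empty cluster; "
            "use prior_predictive / class_predictive for new clusters"
        )
    niw = _as_niw(class_stats_excl, hp)
    tp = predictive_t_params(niw, cluster_stats, hp.kappa1)
    return float(student_t_logpdf(x, tp))


def joint_set_log_likelihood(
    set_stats: SuffStats | None,
    set_points: Sequence[np.ndarray] | np.ndarray,
    context_stats,
    hp: Hyperparams,
) -> float:
    """Joint marginal log likelihood of one whole local cluster under a class.

    The points in ``set_points`` share a single local mean.  Computed by the
    chain rule as sequential one-point predictives with the candidate
    cluster's statistics grown after each point while the class conditioning
    (``context_stats``) stays fixed; exchangeability makes the result
    order-invariant.  ``set_stats``, if given, must agree with
    ``set_points`` (it is redundant and only sanity-checked).
    """
    pts = np.atleast_2d(np.asarray(set_points, dtype=np.float64))
    if pts.shape[0] == 0:
        raise ValueError("joint_set_log_likelihood requires a non-empty point set")
    if set_stats is not None and set_stats.n != pts.shape[0]:
        raise ValueError("set_stats inconsistent with set_points")
    niw = _as_niw(context_stats, hp)
    acc = SuffStats.empty(pts.shape[1])
    total = 0.0
    for x in pts:
        tp = predictive_t_params(niw, acc, hp.kappa1)
        total += float(student_t_logpdf(x, tp))
        acc.n += 1
        acc.sum += x
        acc.scatter += np.outer(x, x)
    return total
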