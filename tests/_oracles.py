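"""Independent numerical oracles used by the test suite.

Everything here is computed by brute force — Monte-Carlo integration of the
generative hierarchy, quadrature over the explicit priors, or exhaustive
enumeration of partitions — deliberately avoiding the closed-form
derivations inside the package so the two routes can disagree if either is
wrong.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import invgamma, invwishart


# ---------------------------------------------------------------------------
# Monte-Carlo predictive oracle
# ---------------------------------------------------------------------------


def _batched_mvn_logpdf(x, means, covs):
    """log N(x; means_i, covs_i) for stacked means (M,d), covs (M,d,d)."""
    d = x.shape[-1]
    L = np.linalg.cholesky(covs)
    diff = (x - means)[..., None]
    z = np.linalg.solve(L, diff)[..., 0]
    logdet = np.log(np.einsum("...ii->...i", L)).sum(-1)
    return -0.5 * (z ** 2).sum(-1) - logdet - 0.5 * d * math.log(2 * math.pi)


def mc_predictive(x, hp, clusters, flat_points=None, join=None,
                  n_draws=200_000, seed=0):
    """Monte-Carlo estimate of a collapsed predictive log density.

    Draws (mu_k, Sigma_k) from the NIW prior and one local mean per
    conditioning cluster, weights each draw by the likelihood of the
    conditioning data, and averages the conditional density of ``x``:

    * ``clusters``: list of (n_i, d) arrays, each sharing a local mean;
    * ``flat_points``: optional (n, d) array of direct class draws
      (exact-sharing convention);
    * ``join``: index into ``clusters`` whose local mean ``x`` shares, or
      None for a brand-new local cluster.

    Returns (log estimate, delta-method standard error of the log).
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x, float))
    d = x.size
    M = n_draws
    Sig = invwishart.rvs(df=hp.m, scale=hp.Sigma0, size=M, random_state=rng)
    Sig = Sig.reshape(M, d, d)
    Lk = np.linalg.cholesky(Sig)
    mu = hp.mu0 + np.einsum(
        "mij,mj->mi", Lk, rng.standard_normal((M, d))) / math.sqrt(hp.kappa0)
    logw = np.zeros(M)
    phis = []
    for pts in clusters:
        pts = np.atleast_2d(np.asarray(pts, float))
        phi = mu + np.einsum("mij,mj->mi", Lk,
                             rng.standard_normal((M, d))) / math.sqrt(hp.kappa1)
        phis.append(phi)
        for p in pts:
            logw += _batched_mvn_logpdf(p, phi, Sig)
    if flat_points is not None:
        for p in np.atleast_2d(np.asarray(flat_points, float)):
            logw += _batched_mvn_logpdf(p, mu, Sig)
    if join is None:
        f = _batched_mvn_logpdf(x, mu, Sig * (1.0 + 1.0 / hp.kappa1))
    else:
        f = _batched_mvn_logpdf(x, phis[join], Sig)
    mx = logw.max()
    w = np.exp(logw - mx)
    g = np.exp(f)
    den = w.sum()
    num = (w * g).sum()
    r = num / den
    se = math.sqrt(np.sum((w * (g - r)) ** 2)) / den / r
    return math.log(r), se


# ---------------------------------------------------------------------------
# closed-form / quadrature marginal likelihoods (1-D)
# ---------------------------------------------------------------------------


def niw_marginal_loglik(points, hp):
    """Textbook marginal likelihood of i.i.d. Gaussian data under the NIW
    prior (multivariate Gamma ratio form), for the no-random-effects model."""
    X = np.atleast_2d(np.asarray(points, float))
    n, d = X.shape
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    kn = hp.kappa0 + n
    nun = hp.m + n
    dev = xbar - hp.mu0
    Psin = hp.Sigma0 + S + (hp.kappa0 * n / kn) * np.outer(dev, dev)

    def mvgammaln(a, dd):
        return (dd * (dd - 1) / 4) * math.log(math.pi) + sum(
            math.lgamma(a + (1 - j) / 2) for j in range(1, dd + 1))

    return (-0.5 * n * d * math.log(math.pi)
            + mvgammaln(nun / 2, d) - mvgammaln(hp.m / 2, d)
            + 0.5 * hp.m * np.linalg.slogdet(hp.Sigma0)[1]
            - 0.5 * nun * np.linalg.slogdet(Psin)[1]
            + 0.5 * d * (math.log(hp.kappa0) - math.log(kn)))


def class_marginal_loglik_1d(clusters, hp, n_sigma=600, n_mu=201):
    """Quadrature marginal likelihood of a class's clusters in 1-D.

    Integrates over (mu_k, sigma^2) on a quantile grid of the
    normal-inverse-gamma prior; each cluster's local mean is marginalized in
    closed Gaussian form (compound-symmetric covariance via
    Sherman-Morrison), independent of the package's sequential predictives.
    """
    a, b = hp.m / 2.0, float(hp.Sigma0[0, 0]) / 2.0
    qs = (np.arange(n_sigma) + 0.5) / n_sigma
    sig2 = invgamma.ppf(qs, a, scale=b)
    zs = (np.arange(n_mu) + 0.5) / n_mu
    from scipy.stats import norm
    z = norm.ppf(zs)
    total = np.zeros((n_sigma, n_mu))
    mu = np.sqrt(sig2[:, None] / hp.kappa0) * z[None, :] + float(hp.mu0[0])
    for pts in clusters:
        y = np.asarray(pts, float).ravel()
        n = y.size
        ssq = np.sum((y - y.mean()) ** 2)
        # log N(y; mu 1, sigma^2 (I + J/kappa1)):
        # |Sigma| = sigma^(2n) (1 + n/kappa1)
        # quad = [ssq + n(ybar-mu)^2 * kappa1/(n+kappa1)] / sigma^2
        quad = (ssq + n * (y.mean() - mu) ** 2 * hp.kappa1
                / (n + hp.kappa1)) / sig2[:, None]
        total += (-0.5 * n * np.log(2 * np.pi * sig2[:, None])
                  - 0.5 * math.log(1 + n / hp.kappa1) - 0.5 * quad)
    mx = total.max()
    return mx + math.log(np.exp(total - mx).mean())


# ---------------------------------------------------------------------------
# exhaustive partition enumeration
# ---------------------------------------------------------------------------


def set_partitions(items):
    """All set partitions of a sequence (lists of lists)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def log_crp(block_sizes, conc):
    """Log probability of a partition with the given block sizes under a
    Chinese-restaurant process with concentration ``conc``."""
    n = sum(block_sizes)
    lp = len(block_sizes) * math.log(conc)
    lp += sum(math.lgamma(b) for b in block_sizes)
    lp -= sum(math.log(conc + i) for i in range(n))
    return lp


def partition_key(labels):
    """Canonical key of a partition given per-item labels."""
    order = {}
    out = []
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
        out.append(order[lab])
    return tuple(out)


def enumerate_posterior_1d(points, hp):
    """Exact posterior over event partitions of a single sample.

    Enumerates every (cluster partition, class partition of the clusters)
    pair; the prior is CRP(alpha) on events times CRP(gamma) on clusters,
    the likelihood the quadrature class marginal.  Returns
    {event-partition key: probability} marginalized over class structure.
    """
    points = [np.atleast_1d(p) for p in points]
    n = len(points)
    idx = list(range(n))
    ml_cache: dict = {}

    def class_ml(cluster_blocks):
        key = tuple(sorted(tuple(sorted(b)) for b in cluster_blocks))
        if key not in ml_cache:
            ml_cache[key] = class_marginal_loglik_1d(
                [[points[i] for i in b] for b in cluster_blocks], hp)
        return ml_cache[key]

    logps = {}
    for rho in set_partitions(idx):
        lp_rho = log_crp([len(b) for b in rho], hp.alpha)
        blocks = list(range(len(rho)))
        labels = np.empty(n, dtype=int)
        for bi, b in enumerate(rho):
            for i in b:
                labels[i] = bi
        key = partition_key(labels)
        for sigma in set_partitions(blocks):
            lp = lp_rho + log_crp([len(s) for s in sigma], hp.gamma)
            for cls in sigma:
                lp += class_ml([rho[b] for b in cls])
            logps[key] = np.logaddexp(logps.get(key, -np.inf), lp)
    mx = max(logps.values())
    total = sum(math.exp(v - mx) for v in logps.values())
    return {k: math.exp(v - mx) / total for k, v in logps.items()}


def enumerate_dpgmm_posterior(points, hp):
    """Exact posterior over partitions for the flat DP mixture:
    CRP(alpha) prior times the textbook NIW marginal per block."""
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    logps = {}
    for rho in set_partitions(list(range(n))):
        lp = log_crp([len(b) for b in rho], hp.alpha)
        for b in rho:
            lp += niw_marginal_loglik(points[b], hp)
        labels = np.empty(n, dtype=int)
        for bi, b in enumerate(rho):
            for i in b:
                labels[i] = bi
        logps[partition_key(labels)] = lp
    mx = max(logps.values())
    total = sum(math.exp(v - mx) for v in logps.values())
    return {k: math.exp(v - mx) / total for k, v in logps.items()}
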