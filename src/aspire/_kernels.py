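"""Compiled inner loops of the collapsed Gibbs sampler.

Everything here operates on flat preallocated arrays owned by
:class:`aspire.sampler.AssignmentState`; no Python objects cross into the
hot path.  The mathematical content mirrors :mod:`aspire.model` exactly
(the test suite asserts agreement between the two code paths): a class's
Normal-inverse-Wishart posterior is maintained through per-cluster
contributions

* weight      ``w_t  = n_t * kappa1 / (n_t + kappa1)``
* mean term   ``b_t  = kappa1 * sum_t / (n_t + kappa1)``
* scatter     ``C_t  = scatter_t - sum_t sum_t^T / (n_t + kappa1)``

accumulated into ``k_A``, ``k_b``, ``k_C`` (plus the raw event count
``k_n``), from which the posterior is
``kappa* = kappa0 + A``, ``eta = kappa0*mu0 + b``, ``mu* = eta/kappa*``,
``nu* = m + n``, ``Psi* = Sigma0 + kappa0 mu0 mu0^T + C - eta eta^T / kappa*``.

Cluster bookkeeping uses free-list slot allocation so cluster/class ids are
stable while they live; per-sample cluster membership lists support O(1)
swap-removal.
"""

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e308
BIG_KAPPA1 = 1.0e14  # stands in for kappa1 = inf (exact sharing / plain DPGMM)


@njit(cache=True, inline="always")
def _safelog(v):
    if v <= 0.0:
        return NEG_INF
    return math.log(v)


# ---------------------------------------------------------------------------
# predictive density
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pred_log(x, ncl, csum, cscat,
              A, bvec, nk, CK,
              kappa0, kappa1, m, k0mu0, base,
              P, v, v2, v3):
    """Log Student-t predictive of x joining a local cluster of a class.

    (ncl, csum, cscat): the candidate cluster's members (ncl == 0 for a new
    local cluster).  (A, bvec, nk, CK): the class accumulators *excluding*
    the candidate cluster.  P, v, v2, v3 are scratch buffers (d*d, d, d, d).
    Returns NEG_INF if the scale matrix is numerically indefinite.
    """
    d = x.shape[0]
    kap = kappa0 + A
    nu = m + nk
    # class posterior mean -> v, scale -> P
    for a in range(d):
        v[a] = (k0mu0[a] + bvec[a]) / kap
    for a in range(d):
        ea = k0mu0[a] + bvec[a]
        for b in range(d):
            P[a, b] = base[a, b] + CK[a, b] - ea * (k0mu0[b] + bvec[b]) / kap
    if ncl > 0:
        w = ncl * kappa1 / (ncl + kappa1)
        kap2 = kap + w
        nu2 = nu + ncl
        coef = kap * w / (kap + w)
        for a in range(d):
            v2[a] = csum[a] / ncl          # ybar
            v3[a] = v2[a] - v[a]           # dev = ybar - mu*
        for a in range(d):
            for b in range(d):
                # + within-cluster scatter + coef * dev dev^T
                P[a, b] += (cscat[a, b] - csum[a] * csum[b] / ncl
                            + coef * v3[a] * v3[b])
        aa = kappa1 / (kappa1 + ncl)
        c = 1.0 + 1.0 / (kappa1 + ncl) + aa * aa / kap2
        for a in range(d):
            # center = (kappa1 * mu2 + ncl * ybar) / (kappa1 + ncl)
            mu2a = (kap * v[a] + w * v2[a]) / kap2
            v3[a] = (kappa1 * mu2a + ncl * v2[a]) / (kappa1 + ncl)
    else:
        nu2 = nu
        c = 1.0 + 1.0 / kappa1 + 1.0 / kap
        for a in range(d):
            v3[a] = v[a]
    dof = nu2 - d + 1.0
    if dof <= 0.0:
        return NEG_INF
    sc = c / dof
    for a in range(d):
        for b in range(d):
            P[a, b] *= sc
    # in-place Cholesky of P (lower triangle)
    logdet_half = 0.0
    for a in range(d):
        for b in range(a + 1):
            s = P[a, b]
            for kk in range(b):
                s -= P[a, kk] * P[b, kk]
            if a == b:
                if s <= 0.0:
                    return NEG_INF
                P[a, a] = math.sqrt(s)
                logdet_half += math.log(P[a, a])
            else:
                P[a, b] = s / P[b, b]
    # solve L z = x - center, q = z.z
    q = 0.0
    for a in range(d):
        s = x[a] - v3[a]
        for kk in range(a):
            s -= P[a, kk] * v[kk]
        v[a] = s / P[a, a]
        q += v[a] * v[a]
    return (math.lgamma(0.5 * (dof + d)) - math.lgamma(0.5 * dof)
            - 0.5 * d * math.log(dof * math.pi) - logdet_half
            - 0.5 * (dof + d) * math.log1p(q / dof))


# ---------------------------------------------------------------------------
# class-accumulator bookkeeping
# ---------------------------------------------------------------------------


@njit(cache=True)
def _class_upd(k, c, sign, kappa1,
               cl_n, cl_sum, cl_scat, k_n, k_A, k_b, k_C):
    """Add (sign=+1) or remove (sign=-1) cluster c's contribution to class k."""
    n = cl_n[c]
    if n == 0:
        return
    d = cl_sum.shape[1]
    den = n + kappa1
    w = n * kappa1 / den
    k_A[k] += sign * w
    k_n[k] += sign * n
    for a in range(d):
        k_b[k, a] += sign * kappa1 * cl_sum[c, a] / den
    for a in range(d):
        for b in range(d):
            k_C[k, a, b] += sign * (cl_scat[c, a, b]
                                    - cl_sum[c, a] * cl_sum[c, b] / den)


@njit(cache=True)
def _excl_accums(k, c, kappa1, cl_n, cl_sum, cl_scat, k_A, k_b, k_C,
                 vb, MC):
    """Class-k accumulators with cluster c's contribution removed (into vb, MC).

    Returns (A_excl, n_excl_delta) where the caller subtracts cl_n[c] itself.
    """
    d = cl_sum.shape[1]
    n = cl_n[c]
    den = n + kappa1
    w = n * kappa1 / den
    for a in range(d):
        vb[a] = k_b[k, a] - kappa1 * cl_sum[c, a] / den
    for a in range(d):
        for b in range(d):
            MC[a, b] = k_C[k, a, b] - (cl_scat[c, a, b]
                                       - cl_sum[c, a] * cl_sum[c, b] / den)
    return k_A[k] - w


# ---------------------------------------------------------------------------
# slot allocation helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def _new_class(klist, kcount, k_free, k_ftop, k_n, k_ncl, k_A, k_b, k_C, k_pos):
    k_ftop[0] -= 1
    k = k_free[k_ftop[0]]
    pos = kcount[0]
    klist[pos] = k
    k_pos[k] = pos
    kcount[0] += 1
    k_n[k] = 0
    k_ncl[k] = 0
    k_A[k] = 0.0
    k_b[k, :] = 0.0
    k_C[k, :, :] = 0.0
    return k


@njit(cache=True)
def _remove_class(k, klist, kcount, k_free, k_ftop, k_pos):
    pos = k_pos[k]
    last = klist[kcount[0] - 1]
    klist[pos] = last
    k_pos[last] = pos
    kcount[0] -= 1
    k_free[k_ftop[0]] = k
    k_ftop[0] += 1


@njit(cache=True)
def _new_cluster(j, k, cl_free, cl_ftop, cl_n, cl_sum, cl_scat, cl_class,
                 cl_sample, cl_pos, scl, scl_count, k_ncl, tcount):
    cl_ftop[0] -= 1
    c = cl_free[cl_ftop[0]]
    cl_n[c] = 0
    cl_sum[c, :] = 0.0
    cl_scat[c, :, :] = 0.0
    cl_class[c] = k
    cl_sample[c] = j
    pos = scl_count[j]
    scl[j, pos] = c
    cl_pos[c] = pos
    scl_count[j] += 1
    k_ncl[k] += 1
    tcount[0] += 1
    return c


@njit(cache=True)
def _remove_cluster(c, cl_free, cl_ftop, cl_class, cl_sample, cl_pos,
                    scl, scl_count, k_ncl, tcount):
    j = cl_sample[c]
    pos = cl_pos[c]
    last = scl[j, scl_count[j] - 1]
    scl[j, pos] = last
    cl_pos[last] = pos
    scl_count[j] -= 1
    k_ncl[cl_class[c]] -= 1
    tcount[0] -= 1
    cl_free[cl_ftop[0]] = c
    cl_ftop[0] += 1


# ---------------------------------------------------------------------------
# Gibbs moves
# ---------------------------------------------------------------------------


@njit(cache=True)
def _resample_event(i, j, skip_remove, u1, u2, strict,
                    X, t,
                    cl_n, cl_sum, cl_scat, cl_class, cl_sample, cl_pos,
                    cl_free, cl_ftop, scl, scl_count,
                    klist, kcount, k_pos, k_free, k_ftop,
                    k_n, k_ncl, k_A, k_b, k_C, tcount,
                    alpha, gamma, kappa0, kappa1, m, k0mu0, base,
                    score, kscore, P, v, v2, v3, vb, MC, zv, zM):
    """One draw of the local-cluster indicator of event i in sample j.

    Existing clusters in the sample are scored by count times the exact
    random-effects predictive under their own class; the new-cluster option
    is a franchise-level mixture over existing classes (weights = cluster
    counts) and a brand-new class (weight gamma).  When ``strict`` is set,
    candidates are restricted to the event's current class.
    """
    x = X[i]
    kcur = -1
    if not skip_remove:
        cold = t[i]
        kcur = cl_class[cold]
        _class_upd(kcur, cold, -1, kappa1, cl_n, cl_sum, cl_scat,
                   k_n, k_A, k_b, k_C)
        cl_n[cold] -= 1
        d = x.shape[0]
        for a in range(d):
            cl_sum[cold, a] -= x[a]
            for b in range(d):
                cl_scat[cold, a, b] -= x[a] * x[b]
        if cl_n[cold] == 0:
            _remove_cluster(cold, cl_free, cl_ftop, cl_class, cl_sample,
                            cl_pos, scl, scl_count, k_ncl, tcount)
            if k_ncl[kcur] == 0:
                _remove_class(kcur, klist, kcount, k_free, k_ftop, k_pos)
                kcur = -1
        else:
            _class_upd(kcur, cold, 1, kappa1, cl_n, cl_sum, cl_scat,
                       k_n, k_A, k_b, k_C)
    # --- score existing clusters in sample j ---
    ncand = scl_count[j]
    maxlp = NEG_INF
    for idx in range(ncand):
        c = scl[j, idx]
        k = cl_class[c]
        if strict and kcur >= 0 and k != kcur:
            score[idx] = NEG_INF
            continue
        A_ex = _excl_accums(k, c, kappa1, cl_n, cl_sum, cl_scat,
                            k_A, k_b, k_C, vb, MC)
        lp = _safelog(float(cl_n[c])) + _pred_log(
            x, cl_n[c], cl_sum[c], cl_scat[c],
            A_ex, vb, k_n[k] - cl_n[c], MC,
            kappa0, kappa1, m, k0mu0, base, P, v, v2, v3)
        score[idx] = lp
        if lp > maxlp:
            maxlp = lp
    # --- new-cluster option: mixture over classes ---
    K = kcount[0]
    maxk = NEG_INF
    for ki in range(K):
        k = klist[ki]
        if strict and kcur >= 0 and k != kcur:
            kscore[ki] = NEG_INF
            continue
        lp = _safelog(float(k_ncl[k])) + _pred_log(
            x, 0, zv, zM, k_A[k], k_b[k], k_n[k], k_C[k],
            kappa0, kappa1, m, k0mu0, base, P, v, v2, v3)
        kscore[ki] = lp
        if lp > maxk:
            maxk = lp
    if strict and kcur >= 0:
        kscore[K] = NEG_INF
    else:
        kscore[K] = _safelog(gamma) + _pred_log(
            x, 0, zv, zM, 0.0, zv, 0, zM,
            kappa0, kappa1, m, k0mu0, base, P, v, v2, v3)
    if kscore[K] > maxk:
        maxk = kscore[K]
    sk = 0.0
    for ki in range(K + 1):
        if kscore[ki] > NEG_INF:
            sk += math.exp(kscore[ki] - maxk)
    lognew = maxk + math.log(sk) - math.log(tcount[0] + gamma)
    score[ncand] = _safelog(alpha) + lognew
    if score[ncand] > maxlp:
        maxlp = score[ncand]
    # --- categorical draw ---
    tot = 0.0
    for idx in range(ncand + 1):
        if score[idx] > NEG_INF:
            tot += math.exp(score[idx] - maxlp)
    r = u1 * tot
    acc = 0.0
    chosen = ncand
    for idx in range(ncand + 1):
        if score[idx] > NEG_INF:
            acc += math.exp(score[idx] - maxlp)
            if acc >= r:
                chosen = idx
                break
    d = x.shape[0]
    if chosen < ncand:
        c = scl[j, chosen]
        k = cl_class[c]
        _class_upd(k, c, -1, kappa1, cl_n, cl_sum, cl_scat, k_n, k_A, k_b, k_C)
        cl_n[c] += 1
        for a in range(d):
            cl_sum[c, a] += x[a]
            for b in range(d):
                cl_scat[c, a, b] += x[a] * x[b]
        _class_upd(k, c, 1, kappa1, cl_n, cl_sum, cl_scat, k_n, k_A, k_b, k_C)
        t[i] = c
    else:
        # pick the new cluster's class from the same posterior mixture
        totk = 0.0
        for ki in range(K + 1):
            if kscore[ki] > NEG_INF:
                totk += math.exp(kscore[ki] - maxk)
        rk = u2 * totk
        acck = 0.0
        kich = K
        for ki in range(K + 1):
            if kscore[ki] > NEG_INF:
                acck += math.exp(kscore[ki] - maxk)
                if acck >= rk:
                    kich = ki
                    break
        if kich == K:
            knew = _new_class(klist, kcount, k_free, k_ftop, k_n, k_ncl,
                              k_A, k_b, k_C, k_pos)
        else:
            knew = klist[kich]
        c = _new_cluster(j, knew, cl_free, cl_ftop, cl_n, cl_sum, cl_scat,
                         cl_class, cl_sample, cl_pos, scl, scl_count,
                         k_ncl, tcount)
        cl_n[c] = 1
        for a in range(d):
            cl_sum[c, a] = x[a]
            for b in range(d):
                cl_scat[c, a, b] = x[a] * x[b]
        _class_upd(knew, c, 1, kappa1, cl_n, cl_sum, cl_scat,
                   k_n, k_A, k_b, k_C)
        t[i] = c


@njit(cache=True, inline="always")
def _lgammad(a, d):
    """Log multivariate gamma function."""
    out = 0.25 * d * (d - 1) * math.log(math.pi)
    for j in range(d):
        out += math.lgamma(a - 0.5 * j)
    return out


@njit(cache=True)
def _cluster_ml(n, csum, cscat,
                A, bvec, nk, CK,
                kappa0, kappa1, m, k0mu0, base,
                P, P2, v, v2):
    """Closed-form joint marginal log likelihood of one whole local cluster
    (n points sharing a local mean) under a class with the given
    conditioning accumulators.  Equals the chain of one-point predictives
    folded over the cluster, in a single evidence-ratio evaluation."""
    d = csum.shape[0]
    kap = kappa0 + A
    nu = m + nk
    for a in range(d):
        v[a] = (k0mu0[a] + bvec[a]) / kap
    for a in range(d):
        ea = k0mu0[a] + bvec[a]
        for b in range(d):
            P[a, b] = base[a, b] + CK[a, b] - ea * (k0mu0[b] + bvec[b]) / kap
    w = n * kappa1 / (n + kappa1)
    kap2 = kap + w
    nu2 = nu + n
    coef = kap * w / (kap + w)
    for a in range(d):
        v2[a] = csum[a] / n - v[a]       # dev = ybar - mu*
    for a in range(d):
        for b in range(d):
            P2[a, b] = (P[a, b] + cscat[a, b] - csum[a] * csum[b] / n
                        + coef * v2[a] * v2[b])
    # log determinants via in-place Cholesky (P and P2 are scratch)
    ld1 = 0.0
    ld2 = 0.0
    for a in range(d):
        for b in range(a + 1):
            s1 = P[a, b]
            s2 = P2[a, b]
            for kk in range(b):
                s1 -= P[a, kk] * P[b, kk]
                s2 -= P2[a, kk] * P2[b, kk]
            if a == b:
                if s1 <= 0.0 or s2 <= 0.0:
                    return NEG_INF
                P[a, a] = math.sqrt(s1)
                P2[a, a] = math.sqrt(s2)
                ld1 += math.log(P[a, a])
                ld2 += math.log(P2[a, a])
            else:
                P[a, b] = s1 / P[b, b]
                P2[a, b] = s2 / P2[b, b]
    return (-0.5 * n * d * math.log(math.pi)
            + _lgammad(0.5 * nu2, d) - _lgammad(0.5 * nu, d)
            + nu * ld1 - nu2 * ld2
            + 0.5 * d * (math.log(kap) - math.log(kap2))
            + 0.5 * d * (math.log(kappa1) - math.log(kappa1 + n)))


@njit(cache=True)
def _resample_cluster(c, j, u1, sample_start,
                      X, t,
                      cl_n, cl_sum, cl_scat, cl_class, cl_sample, cl_pos,
                      klist, kcount, k_pos, k_free, k_ftop,
                      k_n, k_ncl, k_A, k_b, k_C,
                      gamma, kappa0, kappa1, m, k0mu0, base,
                      kscore, ptidx, P, v, v2, v3, tsum, tscat, zv, zM):
    """One draw of the class indicator of local cluster c (non-empty)."""
    kold = cl_class[c]
    _class_upd(kold, c, -1, kappa1, cl_n, cl_sum, cl_scat, k_n, k_A, k_b, k_C)
    k_ncl[kold] -= 1
    if k_ncl[kold] == 0:
        _remove_class(kold, klist, kcount, k_free, k_ftop, k_pos)
    K = kcount[0]
    maxk = NEG_INF
    for ki in range(K):
        k = klist[ki]
        lp = _safelog(float(k_ncl[k])) + _cluster_ml(
            cl_n[c], cl_sum[c], cl_scat[c],
            k_A[k], k_b[k], k_n[k], k_C[k],
            kappa0, kappa1, m, k0mu0, base, P, tscat, v, v2)
        kscore[ki] = lp
        if lp > maxk:
            maxk = lp
    kscore[K] = _safelog(gamma) + _cluster_ml(
        cl_n[c], cl_sum[c], cl_scat[c], 0.0, zv, 0, zM,
        kappa0, kappa1, m, k0mu0, base, P, tscat, v, v2)
    if kscore[K] > maxk:
        maxk = kscore[K]
    tot = 0.0
    for ki in range(K + 1):
        if kscore[ki] > NEG_INF:
            tot += math.exp(kscore[ki] - maxk)
    r = u1 * tot
    acc = 0.0
    kich = K
    for ki in range(K + 1):
        if kscore[ki] > NEG_INF:
            acc += math.exp(kscore[ki] - maxk)
            if acc >= r:
                kich = ki
                break
    if kich == K:
        knew = _new_class(klist, kcount, k_free, k_ftop, k_n, k_ncl,
                          k_A, k_b, k_C, k_pos)
    else:
        knew = klist[kich]
    cl_class[c] = knew
    k_ncl[knew] += 1
    _class_upd(knew, c, 1, kappa1, cl_n, cl_sum, cl_scat, k_n, k_A, k_b, k_C)


@njit(cache=True)
def _sweep(u, strict, sample_start,
           X, t,
           cl_n, cl_sum, cl_scat, cl_class, cl_sample, cl_pos,
           cl_free, cl_ftop, scl, scl_count,
           klist, kcount, k_pos, k_free, k_ftop,
           k_n, k_ncl, k_A, k_b, k_C, tcount,
           alpha, gamma, kappa0, kappa1, m, k0mu0, base,
           score, kscore, ptidx, P, v, v2, v3, vb, MC, tsum, tscat, zv, zM):
    """One full sweep: t-loop over every event, then c-loop over every cluster."""
    J = sample_start.shape[0] - 1
    ui = 0
    for j in range(J):
        for i in range(sample_start[j], sample_start[j + 1]):
            _resample_event(i, j, False, u[ui], u[ui + 1], strict,
                            X, t, cl_n, cl_sum, cl_scat, cl_class, cl_sample,
                            cl_pos, cl_free, cl_ftop, scl, scl_count,
                            klist, kcount, k_pos, k_free, k_ftop,
                            k_n, k_ncl, k_A, k_b, k_C, tcount,
                            alpha, gamma, kappa0, kappa1, m, k0mu0, base,
                            score, kscore, P, v, v2, v3, vb, MC, zv, zM)
            ui += 2
    for j in range(J):
        nc = scl_count[j]
        for idx in range(nc):
            _resample_cluster(scl[j, idx], j, u[ui], sample_start,
                              X, t, cl_n, cl_sum, cl_scat, cl_class,
                              cl_sample, cl_pos,
                              klist, kcount, k_pos, k_free, k_ftop,
                              k_n, k_ncl, k_A, k_b, k_C,
                              gamma, kappa0, kappa1, m, k0mu0, base,
                              kscore, ptidx, P, v, v2, v3, tsum, tscat, zv, zM)
            ui += 1


@njit(cache=True)
def _seed(u, sample_start,
          X, t,
          cl_n, cl_sum, cl_scat, cl_class, cl_sample, cl_pos,
          cl_free, cl_ftop, scl, scl_count,
          klist, kcount, k_pos, k_free, k_ftop,
          k_n, k_ncl, k_A, k_b, k_C, tcount,
          alpha, gamma, kappa0, kappa1, m, k0mu0, base,
          score, kscore, P, v, v2, v3, vb, MC, zv, zM):
    """Sequential predictive seeding: assign events one at a time."""
    J = sample_start.shape[0] - 1
    ui = 0
    for j in range(J):
        for i in range(sample_start[j], sample_start[j + 1]):
            _resample_event(i, j, True, u[ui], u[ui + 1], False,
                            X, t, cl_n, cl_sum, cl_scat, cl_class, cl_sample,
                            cl_pos, cl_free, cl_ftop, scl, scl_count,
                            klist, kcount, k_pos, k_free, k_ftop,
                            k_n, k_ncl, k_A, k_b, k_C, tcount,
                            alpha, gamma, kappa0, kappa1, m, k0mu0, base,
                            score, kscore, P, v, v2, v3, vb, MC, zv, zM)
            ui += 2


@njit(cache=True)
def _state_loglik(sample_start, X, t,
                  cl_class, scl, scl_count,
                  klist, kcount,
                  kappa0, kappa1, m, k0mu0, base,
                  cl_n, cl_sum, cl_scat,
                  P, P2, v, v2,
                  accA, accb, accC):
    """Joint marginal log likelihood of all events given the current
    assignment structure (the "Gibbs likelihood").

    Computed class by class: clusters are folded in one at a time, each
    scored by its closed-form evidence against the accumulators of the
    clusters folded so far.  Exchangeability makes the per-class value
    independent of the fold order.
    """
    J = sample_start.shape[0] - 1
    d = X.shape[1]
    K = kcount[0]
    total = 0.0
    for ki in range(K):
        k = klist[ki]
        accA[0] = 0.0
        nk = 0
        for a in range(d):
            accb[a] = 0.0
            for b in range(d):
                accC[a, b] = 0.0
        for j in range(J):
            for idx in range(scl_count[j]):
                c = scl[j, idx]
                if cl_class[c] != k:
                    continue
                n = cl_n[c]
                total += _cluster_ml(n, cl_sum[c], cl_scat[c],
                                     accA[0], accb, nk, accC,
                                     kappa0, kappa1, m, k0mu0, base,
                                     P, P2, v, v2)
                den = n + kappa1
                accA[0] += n * kappa1 / den
                nk += n
                for a in range(d):
                    accb[a] += kappa1 * cl_sum[c, a] / den
                for a in range(d):
                    for b in range(d):
                        accC[a, b] += (cl_scat[c, a, b]
                                       - cl_sum[c, a] * cl_sum[c, b] / den)
    return total


# ---------------------------------------------------------------------------
# pooled DPGMM baseline (single-level collapsed DP mixture, no random effects)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _dpgmm_resample_event(i, skip_remove, u1,
                          X, t,
                          cl_n, cl_sum, cl_scat, cl_class, cl_sample, cl_pos,
                          cl_free, cl_ftop, scl, scl_count, tcount,
                          alpha, kappa0, m, k0mu0, base,
                          score, P, v, v2, v3, zv, zM):
    """One draw of the cluster indicator of pooled event i in a plain DPGMM.

    Clusters are scored flat: each point is a direct draw from the cluster's
    Gaussian under its own Normal-inverse-Wishart posterior.
    """
    x = X[i]
    d = x.shape[0]
    if not skip_remove:
        cold = t[i]
        cl_n[cold] -= 1
        for a in range(d):
            cl_sum[cold, a] -= x[a]
            for b in range(d):
                cl_scat[cold, a, b] -= x[a] * x[b]
        if cl_n[cold] == 0:
            _remove_cluster_flat(cold, cl_free, cl_ftop, cl_sample, cl_pos,
                                 scl, scl_count, tcount)
    ncand = scl_count[0]
    maxlp = NEG_INF
    for idx in range(ncand):
        c = scl[0, idx]
        lp = _safelog(float(cl_n[c])) + _pred_log(
            x, 0, zv, zM, float(cl_n[c]), cl_sum[c], cl_n[c], cl_scat[c],
            kappa0, BIG_KAPPA1, m, k0mu0, base, P, v, v2, v3)
        score[idx] = lp
        if lp > maxlp:
            maxlp = lp
    score[ncand] = _safelog(alpha) + _pred_log(
        x, 0, zv, zM, 0.0, zv, 0, zM,
        kappa0, BIG_KAPPA1, m, k0mu0, base, P, v, v2, v3)
    if score[ncand] > maxlp:
        maxlp = score[ncand]
    tot = 0.0
    for idx in range(ncand + 1):
        if score[idx] > NEG_INF:
            tot += math.exp(score[idx] - maxlp)
    r = u1 * tot
    acc = 0.0
    chosen = ncand
    for idx in range(ncand + 1):
        if score[idx] > NEG_INF:
            acc += math.exp(score[idx] - maxlp)
            if acc >= r:
                chosen = idx
                break
    if chosen < ncand:
        c = scl[0, chosen]
    else:
        c = _new_cluster_flat(cl_free, cl_ftop, cl_n, cl_sum, cl_scat,
                              cl_class, cl_sample, cl_pos, scl, scl_count,
                              tcount)
    cl_n[c] += 1
    for a in range(d):
        cl_sum[c, a] += x[a]
        for b in range(d):
            cl_scat[c, a, b] += x[a] * x[b]
    t[i] = c


@njit(cache=True)
def _new_cluster_flat(cl_free, cl_ftop, cl_n, cl_sum, cl_scat, cl_class,
                      cl_sample, cl_pos, scl, scl_count, tcount):
    cl_ftop[0] -= 1
    c = cl_free[cl_ftop[0]]
    cl_n[c] = 0
    cl_sum[c, :] = 0.0
    cl_scat[c, :, :] = 0.0
    cl_class[c] = c
    cl_sample[c] = 0
    pos = scl_count[0]
    scl[0, pos] = c
    cl_pos[c] = pos
    scl_count[0] += 1
    tcount[0] += 1
    return c


@njit(cache=True)
def _remove_cluster_flat(c, cl_free, cl_ftop, cl_sample, cl_pos,
                         scl, scl_count, tcount):
    pos = cl_pos[c]
    last = scl[0, scl_count[0] - 1]
    scl[0, pos] = last
    cl_pos[last] = pos
    scl_count[0] -= 1
    tcount[0] -= 1
    cl_free[cl_ftop[0]] = c
    cl_ftop[0] += 1


@njit(cache=True)
def _dpgmm_sweep(u, n_events, seed_mode,
                 X, t,
                 cl_n, cl_sum, cl_scat, cl_class, cl_sample, cl_pos,
                 cl_free, cl_ftop, scl, scl_count, tcount,
                 alpha, kappa0, m, k0mu0, base,
                 score, P, v, v2, v3, zv, zM):
    for i in range(n_events):
        _dpgmm_resample_event(i, seed_mode, u[i],
                              X, t, cl_n, cl_sum, cl_scat, cl_class,
                              cl_sample, cl_pos, cl_free, cl_ftop,
                              scl, scl_count, tcount,
                              alpha, kappa0, m, k0mu0, base,
                              score, P, v, v2, v3, zv, zM)


@njit(cache=True)
def _dpgmm_loglik(X, t, scl, scl_count,
                  kappa0, m, k0mu0, base,
                  ptidx, P, v, v2, v3, tsum, tscat):
    """Joint marginal log likelihood of pooled data given the partition."""
    total = 0.0
    n_events = X.shape[0]
    d = X.shape[1]
    for idx in range(scl_count[0]):
        c = scl[0, idx]
        npts = 0
        for i in range(n_events):
            if t[i] == c:
                ptidx[npts] = i
                npts += 1
        # flat chain: each point conditioned on earlier points of the cluster
        tn = 0
        for a in range(d):
            tsum[a] = 0.0
            for b in range(d):
                tscat[a, b] = 0.0
        for ii in range(npts):
            x = X[ptidx[ii]]
            total += _pred_log(x, 0, v2, P, float(tn), tsum, tn, tscat,
                               kappa0, BIG_KAPPA1, m, k0mu0, base,
                               P, v, v2, v3)
            tn += 1
            for a in range(d):
                tsum[a] += x[a]
                for b in range(d):
                    tscat[a, b] += x[a] * x[b]
    return total
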