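"""Fused numba kernel for the restarted-EM inner loop.

One virtual gene = one (gene, restart) pair. Each runs its own E/M alternation
to convergence against the shared (sample, cluster) design, avoiding the
temporary-array traffic of a vectorized implementation. The math mirrors the
module-level e_step/m_step functions exactly: responsibility-weighted least
squares with tied columns, pooled (or per-cluster) residual variance, free
mixture weights, and a log-space E-step.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _solve_inplace(A, b, x):
    """Gaussian elimination with partial pivoting; returns False when singular.

    Destroys A and b. Singularity threshold is relative to the largest entry,
    so the check is scale-free.
    """
    m = A.shape[0]
    scale = 0.0
    for a in range(m):
        for c in range(m):
            v = abs(A[a, c])
            if v > scale:
                scale = v
    if scale == 0.0:
        return False
    for col in range(m):
        piv = col
        big = abs(A[col, col])
        for r in range(col + 1, m):
            v = abs(A[r, col])
            if v > big:
                big = v
                piv = r
        if big <= 1e-12 * scale:
            return False
        if piv != col:
            for c in range(m):
                tmp = A[col, c]
                A[col, c] = A[piv, c]
                A[piv, c] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        inv = 1.0 / A[col, col]
        for r in range(col + 1, m):
            f = A[r, col] * inv
            if f != 0.0:
                for c in range(col, m):
                    A[r, c] -= f * A[col, c]
                b[r] -= f * b[col]
    for col in range(m - 1, -1, -1):
        acc = b[col]
        for c in range(col + 1, m):
            acc -= A[col, c] * x[c]
        x[col] = acc / A[col, col]
    return True


@njit(cache=True)
def em_kernel(Yv, Xf, XXf, R, nv, tol, max_iter, shared, sigma_floor, degen_frac, trace):
    B, n = Yv.shape
    nK, m = Xf.shape
    K = nK // n
    record_trace = trace.shape[0] == B

    theta_out = np.zeros((B, m))
    sigma2_out = np.full((B, K), np.nan)
    w_out = np.full((B, K), 1.0 / K)
    ll_out = np.full(B, -np.inf)
    n_iter = np.zeros(B, np.int64)
    converged = np.zeros(B, np.bool_)
    invalid = np.zeros(B, np.bool_)

    # per-cluster nonzero design columns: cluster k touches its own varying
    # block [k*nv, (k+1)*nv) plus the shared tied block [K*nv, m)
    nt = m - K * nv
    ncols = nv + nt
    colidx = np.empty((K, ncols), np.int64)
    for k in range(K):
        for j in range(nv):
            colidx[k, j] = k * nv + j
        for j in range(nt):
            colidx[k, nv + j] = K * nv + j

    log2pi = np.log(2.0 * np.pi)
    A = np.zeros((m, m))
    bv = np.zeros(m)
    mu = np.zeros((n, K))
    ld = np.zeros(K)
    s2 = np.zeros(K)
    w = np.zeros(K)
    ck = np.zeros(K)
    inv2s = np.zeros(K)
    theta = np.zeros(m)

    for g in range(B):
        Rg = R[g]  # (n, K), updated in place
        prev = -np.inf
        llg = -np.inf
        for it in range(max_iter):
            # cluster totals; a near-empty cluster invalidates this restart
            bad = False
            for k in range(K):
                tot = 0.0
                for i in range(n):
                    tot += Rg[i, k]
                w[k] = tot / n
                if tot < degen_frac * n:
                    bad = True
            if bad:
                invalid[g] = True
                break

            # M-step: weighted normal equations over the nonzero design columns
            for a in range(m):
                bv[a] = 0.0
                for c in range(m):
                    A[a, c] = 0.0
            for i in range(n):
                yi = Yv[g, i]
                for k in range(K):
                    r = Rg[i, k]
                    idx = i * K + k
                    for aa in range(ncols):
                        a = colidx[k, aa]
                        xa = Xf[idx, a]
                        bv[a] += r * yi * xa
                        ra = r * xa
                        for cc in range(aa, ncols):
                            c = colidx[k, cc]
                            A[a, c] += ra * Xf[idx, c]
            for a in range(m):
                for c in range(a):
                    A[a, c] = A[c, a]
            if not _solve_inplace(A, bv, theta):
                invalid[g] = True
                break

            # fitted means, pooled residual variance
            for i in range(n):
                for k in range(K):
                    idx = i * K + k
                    acc = 0.0
                    for aa in range(ncols):
                        a = colidx[k, aa]
                        acc += Xf[idx, a] * theta[a]
                    mu[i, k] = acc
            if shared:
                rss = 0.0
                for i in range(n):
                    yi = Yv[g, i]
                    for k in range(K):
                        d = yi - mu[i, k]
                        rss += Rg[i, k] * d * d
                v = rss / n
                if v < sigma_floor:
                    v = sigma_floor
                for k in range(K):
                    s2[k] = v
            else:
                for k in range(K):
                    rss = 0.0
                    tot = 0.0
                    for i in range(n):
                        d = Yv[g, i] - mu[i, k]
                        rss += Rg[i, k] * d * d
                        tot += Rg[i, k]
                    v = rss / tot
                    if v < sigma_floor:
                        v = sigma_floor
                    s2[k] = v

            # E-step in log space + observed-data log-likelihood
            for k in range(K):
                if w[k] > 0.0:
                    ck[k] = -0.5 * (log2pi + np.log(s2[k])) + np.log(w[k])
                else:
                    ck[k] = -np.inf
                inv2s[k] = 0.5 / s2[k]
            llg = 0.0
            for i in range(n):
                yi = Yv[g, i]
                top = -np.inf
                for k in range(K):
                    d = yi - mu[i, k]
                    ld[k] = ck[k] - d * d * inv2s[k]
                    if ld[k] > top:
                        top = ld[k]
                sexp = 0.0
                for k in range(K):
                    ld[k] = np.exp(ld[k] - top)
                    sexp += ld[k]
                llg += top + np.log(sexp)
                for k in range(K):
                    Rg[i, k] = ld[k] / sexp
            n_iter[g] = it + 1
            if record_trace:
                trace[g, it] = llg
            for a in range(m):
                theta_out[g, a] = theta[a]
            for k in range(K):
                sigma2_out[g, k] = s2[k]
                w_out[g, k] = w[k]
            ll_out[g] = llg
            if np.abs(llg - prev) < tol:
                converged[g] = True
                break
            prev = llg
        if invalid[g]:
            ll_out[g] = -np.inf
            converged[g] = False

    return theta_out, sigma2_out, w_out, ll_out, n_iter, converged, invalid
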