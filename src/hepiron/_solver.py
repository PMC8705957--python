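"""Numba kernels for the L1 coordinate-descent path.

Covariance-update formulation: the solver works on the p x p Gram matrix
G = X'X/n (column-centred) and the vector c = X'y/n (y centred).  The
residual correlation vector r = c - G b is maintained incrementally, so a
coordinate update costs O(p) only when the coefficient actually moves.  The
objective is

    (1/2n) ||y - b0 - X b||^2 + lam * sum_j w_j |b_j|

with an unpenalized intercept (handled by centring) and per-column penalty
weights w_j (1 for ordinary candidates, 0 for forced-in variables).
Convergence: maximum absolute coefficient change below ``tol`` in a full
cyclic sweep.  Along a penalty path the sequential strong rule screens the
coordinates entering each solve; screened-out coordinates are re-admitted
on a stationarity (KKT) violation, so solutions are exact.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def _sweep(G, beta, r, lam, w, mask, active_only):
    """One cyclic pass over the masked coordinates, updating beta and the
    cached residual correlations; returns max absolute coefficient change."""
    p = beta.shape[0]
    maxd = 0.0
    for j in range(p):
        if not mask[j]:
            continue
        if active_only and beta[j] == 0.0:
            continue
        gj = G[j, j]
        if gj <= 0.0:
            continue
        rho = r[j] + gj * beta[j]
        new = _soft(rho, lam * w[j]) / gj
        d = new - beta[j]
        if d != 0.0:
            ad = abs(d)
            if ad > maxd:
                maxd = ad
            beta[j] = new
            for m in range(p):
                r[m] -= G[m, j] * d
    return maxd


@njit(cache=True)
def _newton_step(G, beta, r, lam, w):
    """Solve the stationarity system exactly on the current active set
    (fixed signs): G_AA b_A = c_A - lam w_A sign(b_A).  Coordinates whose
    solved coefficient flips sign are dropped from the set and the reduced
    system re-solved (a few times); returns False (state untouched) when no
    sign-consistent solution is found.  Every accepted step is followed by
    ordinary sweeps in the caller, so exactness never rests on this step."""
    p = beta.shape[0]
    na = 0
    for j in range(p):
        if beta[j] != 0.0:
            na += 1
    if na == 0:
        return False
    idx = np.empty(na, dtype=np.int64)
    k = 0
    for j in range(p):
        if beta[j] != 0.0:
            idx[k] = j
            k += 1
    keep = np.ones(na, dtype=np.bool_)
    x = np.zeros(na)
    for _attempt in range(8):
        nk = int(keep.sum())
        if nk == 0:
            return False
        sub = np.empty(nk, dtype=np.int64)
        k = 0
        for ii in range(na):
            if keep[ii]:
                sub[k] = ii
                k += 1
        A = np.empty((nk, nk))
        b = np.empty(nk)
        for aa in range(nk):
            j = idx[sub[aa]]
            cj = r[j]
            for kk in range(na):  # c_j from the *current* beta (full set)
                cj += G[j, idx[kk]] * beta[idx[kk]]
            for bb in range(nk):
                A[aa, bb] = G[j, idx[sub[bb]]]
            A[aa, aa] += 1e-11  # keep the system nonsingular under duplicates
            s = 1.0 if beta[j] > 0.0 else -1.0
            b[aa] = cj - lam * w[j] * s
        sol = np.linalg.solve(A, b)
        flipped = False
        for aa in range(nk):
            s = 1.0 if beta[idx[sub[aa]]] > 0.0 else -1.0
            if sol[aa] * s <= 0.0:
                keep[sub[aa]] = False
                flipped = True
        if not flipped:
            x[:] = 0.0
            for aa in range(nk):
                x[sub[aa]] = sol[aa]
            for ii in range(na):
                j = idx[ii]
                d = x[ii] - beta[j]
                if d != 0.0:
                    beta[j] = x[ii]
                    for m in range(p):
                        r[m] -= G[m, j] * d
            return True
    return False


@njit(cache=True)
def _cd_masked(G, beta, r, lam, w, mask, tol, max_sweeps):
    total = 0
    newton_left = 100
    while True:
        maxd = _sweep(G, beta, r, lam, w, mask, False)
        total += 1
        if maxd < tol:
            return total
        if total >= max_sweeps:
            return -total
        if newton_left > 0:
            newton_left -= 1
            if _newton_step(G, beta, r, lam, w):
                total += 1
                maxd = _sweep(G, beta, r, lam, w, mask, False)
                total += 1
                if maxd < tol:
                    return total
        inner = 0
        while inner < 50:
            maxd = _sweep(G, beta, r, lam, w, mask, True)
            total += 1
            inner += 1
            if maxd < tol:
                break
            if total >= max_sweeps:
                return -total


@njit(cache=True)
def cd_solve(G, beta, r, lam, w, tol, max_sweeps):
    """Exact solve at one penalty from a warm start (r = c - G beta on
    entry).  Returns sweeps used (negative: sweep budget exhausted)."""
    p = beta.shape[0]
    mask = np.ones(p, dtype=np.bool_)
    return _cd_masked(G, beta, r, lam, w, mask, tol, max_sweeps)


@njit(cache=True)
def cd_solve_screened(G, beta, r, lam, lam_prev, w, tol, max_sweeps):
    """Solve at ``lam`` warm-started from the solution at ``lam_prev``,
    restricting work to the sequential-strong-rule set
    {j : |r_j| >= (2 lam - lam_prev) w_j} plus the current active set, and
    re-admitting any screened coordinate that violates stationarity."""
    p = beta.shape[0]
    mask = np.empty(p, dtype=np.bool_)
    thresh = 2.0 * lam - lam_prev
    for j in range(p):
        mask[j] = beta[j] != 0.0 or abs(r[j]) >= thresh * w[j]
    total = 0
    while True:
        res = _cd_masked(G, beta, r, lam, w, mask, tol, max_sweeps - total)
        if res < 0:
            return res - total
        total += res
        violated = False
        for j in range(p):
            if not mask[j] and abs(r[j]) > lam * w[j]:
                mask[j] = True
                violated = True
        if not violated:
            return total


@njit(cache=True)
def cd_single(G, c, lam, w, tol, max_sweeps):
    """Cold-start exact solve at one penalty; returns (beta, sweeps)."""
    beta = np.zeros(G.shape[0])
    r = c.copy()
    sweeps = cd_solve(G, beta, r, lam, w, tol, max_sweeps)
    return beta, sweeps


@njit(cache=True)
def cd_path(G, c, lambdas, w, tol, max_sweeps):
    """Warm-started, strong-rule-screened path over a decreasing grid.

    Returns (betas K x p, sweeps K); sweeps[k] < 0 flags non-convergence.
    """
    K = lambdas.shape[0]
    p = G.shape[0]
    betas = np.zeros((K, p))
    sweeps = np.zeros(K, dtype=np.int64)
    beta = np.zeros(p)
    r = c.copy()
    for k in range(K):
        lam_prev = lambdas[0] if k == 0 else lambdas[k - 1]
        sweeps[k] = cd_solve_screened(G, beta, r, lambdas[k], lam_prev,
                                      w, tol, max_sweeps)
        betas[k] = beta
    return betas, sweeps


@njit(cache=True)
def cv_fold_errors(XtX, Xty, Xsum, ysum, X, y, fold_ids, n_folds,
                   lambdas, w, tol, max_sweeps):
    """Out-of-fold squared-error sums, per fold and per penalty.

    Full-data cross-products are precomputed; each training fold's centred
    Gram is obtained by subtracting the fold's contribution.  Predictions
    use the training-fold intercept b0 = ybar_tr - xbar_tr' b.  Returns
    (sse_folds: n_folds x K, fold_sizes).
    """
    n, p = X.shape
    K = lambdas.shape[0]
    sse = np.zeros((n_folds, K))
    sizes = np.zeros(n_folds, dtype=np.int64)
    for f in range(n_folds):
        nf = 0
        for i in range(n):
            if fold_ids[i] == f:
                nf += 1
        sizes[f] = nf
        ntr = n - nf
        # fold cross-products
        S_f = np.zeros((p, p))
        t_f = np.zeros(p)
        m_f = np.zeros(p)
        ys_f = 0.0
        for i in range(n):
            if fold_ids[i] == f:
                xi = X[i]
                for a in range(p):
                    va = xi[a]
                    t_f[a] += va * y[i]
                    m_f[a] += va
                    for b in range(a, p):
                        S_f[a, b] += va * xi[b]
                ys_f += y[i]
        for a in range(p):
            for b in range(a, p):
                S_f[b, a] = S_f[a, b]
        xbar = (Xsum - m_f) / ntr
        ybar = (ysum - ys_f) / ntr
        G = np.empty((p, p))
        cvec = np.empty(p)
        for a in range(p):
            cvec[a] = (Xty[a] - t_f[a]) / ntr - xbar[a] * ybar
            for b in range(p):
                G[a, b] = (XtX[a, b] - S_f[a, b]) / ntr - xbar[a] * xbar[b]
        beta = np.zeros(p)
        r = cvec.copy()
        for k in range(K):
            lam_prev = lambdas[0] if k == 0 else lambdas[k - 1]
            cd_solve_screened(G, beta, r, lambdas[k], lam_prev,
                              w, tol, max_sweeps)
            # accumulate validation error at this penalty
            for i in range(n):
                if fold_ids[i] == f:
                    pred = ybar
                    for a in range(p):
                        if beta[a] != 0.0:
                            pred += (X[i, a] - xbar[a]) * beta[a]
                    resid = y[i] - pred
                    sse[f, k] += resid * resid
    return sse, sizes
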