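"""Compiled numerical kernels for Ising-network fitting and enumeration.

Everything here operates on *pattern counts*: a binary symptom matrix with
K columns has at most 2**K distinct rows, and both the nodewise logistic
likelihoods and the Boltzmann enumeration depend on the data only through
the count of each pattern. Working on counts makes a single network fit
O(2**K) instead of O(n), which is what lets the bootstrap machinery refit
the full pipeline hundreds of thousands of times.

Kernels are compiled with numba when available and fall back to pure
Python otherwise (same code path, slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every caller
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False)
def _soft_threshold(z, lam):
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


@njit(cache=False)
def _node_design(counts, j, K):
    """Response, predictors and weights for node j from pattern counts."""
    nstates = counts.shape[0]
    y = np.empty(nstates)
    X = np.empty((nstates, K - 1))
    for s in range(nstates):
        y[s] = (s >> j) & 1
        c = 0
        for k in range(K):
            if k == j:
                continue
            X[s, c] = (s >> k) & 1
            c += 1
    return y, X


@njit(cache=False)
def _cd_logistic(y, X, w, n, lam, state, tol, maxiter):
    """Weighted l1-penalized logistic regression, IRLS + coordinate descent.

    Minimizes (1/n) * sum_s w_s * [-y_s eta_s + log(1 + exp(eta_s))]
    + lam * ||beta||_1 with an unpenalized intercept. ``state`` holds the
    warm start [beta0, beta_1..beta_p], updated in place. Outer loop forms
    the glmnet-style quadratic approximation (working weights floored at
    1e-5); inner coordinate descent solves it to ``tol``.
    """
    nstates = y.shape[0]
    p = X.shape[1]
    eta = np.empty(nstates)
    v = np.empty(nstates)
    u = np.empty(nstates)
    for _outer in range(maxiter):
        for s in range(nstates):
            e = state[0]
            for k in range(p):
                bk = state[1 + k]
                if bk != 0.0:
                    e += X[s, k] * bk
            eta[s] = e
            mu = 1.0 / (1.0 + np.exp(-eta[s]))
            pq = mu * (1.0 - mu)
            if pq < 1e-5:
                pq = 1e-5
            v[s] = w[s] * pq / n
            u[s] = w[s] * (y[s] - mu) / n
        h0 = 0.0
        for s in range(nstates):
            h0 += v[s]
        h = np.empty(p)
        for k in range(p):
            acc = 0.0
            for s in range(nstates):
                if X[s, k] != 0.0:
                    acc += v[s]
            h[k] = acc
        outer_delta = 0.0
        for _inner in range(200):
            delta_max = 0.0
            # intercept
            g0 = 0.0
            for s in range(nstates):
                g0 += u[s]
            d0 = g0 / h0
            if d0 != 0.0:
                state[0] += d0
                for s in range(nstates):
                    u[s] -= v[s] * d0
                if abs(d0) > delta_max:
                    delta_max = abs(d0)
            for k in range(p):
                if h[k] <= 0.0:
                    continue
                gk = 0.0
                for s in range(nstates):
                    if X[s, k] != 0.0:
                        gk += u[s]
                z = h[k] * state[1 + k] + gk
                bnew = _soft_threshold(z, lam) / h[k]
                d = bnew - state[1 + k]
                if d != 0.0:
                    state[1 + k] = bnew
                    for s in range(nstates):
                        if X[s, k] != 0.0:
                            u[s] -= v[s] * d
                    if abs(d) > delta_max:
                        delta_max = abs(d)
            if delta_max > outer_delta:
                outer_delta = delta_max
            if delta_max < tol:
                break
        if outer_delta < tol:
            break
    return 0


@njit(cache=False)
def _weighted_loglik(y, X, w, beta0, beta):
    nstates = y.shape[0]
    p = X.shape[1]
    ll = 0.0
    for s in range(nstates):
        if w[s] == 0.0:
            continue
        eta = beta0
        for k in range(p):
            if beta[k] != 0.0:
                eta += X[s, k] * beta[k]
        # log(1 + exp(eta)) computed stably
        if eta > 30.0:
            lse = eta
        elif eta < -30.0:
            lse = 0.0
        else:
            lse = np.log(1.0 + np.exp(eta))
        ll += w[s] * (y[s] * eta - lse)
    return ll


@njit(cache=False)
def _fit_node_path(counts, j, K, gamma, nlambda, lambda_min_ratio, tol, maxiter):
    """EBIC-selected lasso-logistic fit of node j on the other K-1 nodes.

    Returns (intercept, coefficients over the other nodes in increasing
    node order, selected lambda). Ties on the EBIC path go to the larger
    lambda (sparser model).
    """
    y, X = _node_design(counts, j, K)
    w = counts.astype(np.float64)
    n = w.sum()
    p = K - 1
    # null fit and lambda_max
    ybar = 0.0
    for s in range(counts.shape[0]):
        ybar += w[s] * y[s]
    ybar /= n
    lam_max = 0.0
    for k in range(p):
        acc = 0.0
        for s in range(counts.shape[0]):
            acc += w[s] * X[s, k] * (y[s] - ybar)
        acc = abs(acc) / n
        if acc > lam_max:
            lam_max = acc
    if lam_max <= 0.0:
        lam_max = 1e-3
    logn = np.log(n)
    logp = np.log(p)
    state = np.zeros(p + 1)
    state[0] = np.log(ybar / (1.0 - ybar))
    best_ebic = np.inf
    best_state = state.copy()
    best_lam = lam_max
    ratio = lambda_min_ratio ** (1.0 / (nlambda - 1))
    lam = lam_max
    # the path is walked at a looser tolerance; the selected model is
    # refit tightly below (EBIC ranking is insensitive at this level)
    path_tol = tol if tol > 1e-5 else 1e-5
    for _ in range(nlambda):
        _cd_logistic(y, X, w, n, lam, state, path_tol, maxiter)
        # flush float-noise coefficients to exact zero so the model's df
        # is honest (soft-thresholding can leave ~1e-16 residues)
        df = 0
        for k in range(p):
            if abs(state[1 + k]) < 1e-8:
                state[1 + k] = 0.0
            else:
                df += 1
        ll = _weighted_loglik(y, X, w, state[0], state[1:])
        ebic = -2.0 * ll + df * logn + 2.0 * gamma * df * logp
        if ebic < best_ebic - 1e-10:
            best_ebic = ebic
            best_state = state.copy()
            best_lam = lam
        lam *= ratio
        # warm start carried in state
    _cd_logistic(y, X, w, n, best_lam, best_state, tol, maxiter)
    for k in range(p):
        if abs(best_state[1 + k]) < 1e-8:
            best_state[1 + k] = 0.0
    return best_state[0], best_state[1:].copy(), best_lam


@njit(cache=False)
def fit_elasso_counts(counts, K, gamma, rule_and, nlambda, lambda_min_ratio,
                      tol, maxiter):
    """Full eLasso fit from pattern counts.

    Returns (tau, W, D, lambdas) where D[j, k] is the directed coefficient
    of node k in the regression of node j (diagonal zero) and W is the
    symmetrized edge matrix (AND rule if rule_and, else OR).
    """
    tau = np.zeros(K)
    D = np.zeros((K, K))
    lambdas = np.zeros(K)
    for j in range(K):
        b0, b, lam = _fit_node_path(counts, j, K, gamma, nlambda,
                                    lambda_min_ratio, tol, maxiter)
        tau[j] = b0
        lambdas[j] = lam
        c = 0
        for k in range(K):
            if k == j:
                continue
            D[j, k] = b[c]
            c += 1
    W = np.zeros((K, K))
    for j in range(K):
        for k in range(j + 1, K):
            a = D[j, k]
            b_ = D[k, j]
            if rule_and:
                if a != 0.0 and b_ != 0.0:
                    W[j, k] = 0.5 * (a + b_)
            else:
                if a != 0.0 or b_ != 0.0:
                    W[j, k] = 0.5 * (a + b_)
            W[k, j] = W[j, k]
    return tau, W, D, lambdas


@njit(cache=False)
def state_log_weights(tau, W):
    """Unnormalized log-probabilities log ~P(x) = sum tau_i x_i + sum W_ij x_i x_j
    for all 2**K states (pattern index bit i = x_i)."""
    K = tau.shape[0]
    nstates = 1 << K
    lw = np.empty(nstates)
    for s in range(nstates):
        e = 0.0
        for i in range(K):
            if (s >> i) & 1:
                e += tau[i]
                for jj in range(i + 1, K):
                    if (s >> jj) & 1:
                        e += W[i, jj]
        lw[s] = e
    return lw


@njit(cache=False)
def activation_probabilities(tau, W):
    """Marginal distribution of the number of active nodes, by enumeration."""
    K = tau.shape[0]
    lw = state_log_weights(tau, W)
    m = lw.max()
    nstates = lw.shape[0]
    Pn = np.zeros(K + 1)
    total = 0.0
    for s in range(nstates):
        p = np.exp(lw[s] - m)
        total += p
        cnt = 0
        for i in range(K):
            if (s >> i) & 1:
                cnt += 1
        Pn[cnt] += p
    for nn in range(K + 1):
        Pn[nn] /= total
    return Pn


@njit(cache=False)
def stability_difference_counts(counts, K, gamma, rule_and, nlambda,
                                lambda_min_ratio, tol, maxiter, healthy_max):
    """Refit eLasso from counts and return the stability difference
    S = min_{n>healthy_max} U_n - min_{n<=healthy_max} U_n."""
    tau, W, D, lams = fit_elasso_counts(counts, K, gamma, rule_and, nlambda,
                                        lambda_min_ratio, tol, maxiter)
    Pn = activation_probabilities(tau, W)
    u_healthy = np.inf
    u_unhealthy = np.inf
    for nn in range(K + 1):
        u = -np.log(Pn[nn])
        if nn <= healthy_max:
            if u < u_healthy:
                u_healthy = u
        else:
            if u < u_unhealthy:
                u_unhealthy = u
    return u_unhealthy - u_healthy


@njit(cache=False)
def gibbs_sample(tau, W, n, burn_in, thin, u01):
    """Single-site Gibbs sampler for the Ising model.

    u01 is a pre-drawn flat array of uniforms of length
    (burn_in + n * thin) * K, consumed in order; keeps all randomness
    under the caller's generator.
    """
    K = tau.shape[0]
    x = np.zeros(K, dtype=np.int8)
    out = np.empty((n, K), dtype=np.int8)
    idx = 0
    total_sweeps = burn_in + n * thin
    kept = 0
    for sweep in range(total_sweeps):
        for i in range(K):
            eta = tau[i]
            for jj in range(K):
                if jj != i and x[jj] == 1:
                    eta += W[i, jj]
            p1 = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1 if u01[idx] < p1 else 0
            idx += 1
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            out[kept] = x
            kept += 1
    return out


def counts_from_matrix(X):
    """Pattern counts (length 2**K) from an n x K binary matrix."""
    X = np.asarray(X)
    K = X.shape[1]
    weights = (1 << np.arange(K)).astype(np.int64)
    idx = X.astype(np.int64) @ weights
    return np.bincount(idx, minlength=1 << K).astype(np.int64)


def matrix_from_counts(counts, K):
    """Expand pattern counts back into an n x K binary matrix (pattern order)."""
    rows = []
    for s, c in enumerate(counts):
        if c:
            bits = [(s >> i) & 1 for i in range(K)]
            rows.append(np.tile(np.array(bits, dtype=np.int8), (c, 1)))
    if not rows:
        return np.zeros((0, K), dtype=np.int8)
    return np.vstack(rows)
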