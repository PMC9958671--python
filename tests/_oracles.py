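"""Independent reference implementations used only as test oracles.

Deliberately written with different numerics than the package: dense
covariance matrices and generic optimizers instead of the eigenbasis
profiling used by the implementation, explicit Lance-Williams recursion
instead of scipy's nearest-neighbor chain, exhaustive label enumeration
instead of random permutations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# dense REML for the random-intercept model
# ---------------------------------------------------------------------------

def _dense_crit(theta: float, y, X, ZZT):
    n, p = X.shape
    V = np.eye(n) + theta * ZZT
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    s2e = float(r @ Vi @ r) / (n - p)
    if s2e <= 0:
        return -np.inf, beta, s2e, A
    crit = -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(A)[1]
                   + (n - p) * np.log(s2e))
    return crit, beta, s2e, A


def _dense_ll2(s2u: float, s2e: float, y, X, ZZT):
    n, p = X.shape
    V = s2e * np.eye(n) + s2u * ZZT
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return -np.inf
    A = X.T @ Vi @ X
    sign, lda = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (np.linalg.slogdet(V)[1] + lda + float(r @ Vi @ r))


def _dense_cvc(c, s2u, s2e, X, ZZT):
    n = X.shape[0]
    V = s2e * np.eye(n) + s2u * ZZT
    A = X.T @ np.linalg.inv(V) @ X
    return float(c @ np.linalg.solve(A, c))


def fit_reml_dense(y, X, subject_codes):
    """Grid + bounded 1-D refinement of the profiled REML criterion."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes = np.asarray(subject_codes)
    Z = (codes[:, None] == np.unique(codes)[None, :]).astype(float)
    ZZT = Z @ Z.T
    grid = np.concatenate([[0.0], np.logspace(-8, 6, 1000)])
    vals = np.array([_dense_crit(t, y, X, ZZT)[0] for t in grid])
    i = int(np.nanargmax(vals))
    if 0 < i < len(grid) - 1:
        res = optimize.minimize_scalar(
            lambda lt: -_dense_crit(np.exp(lt), y, X, ZZT)[0],
            bounds=(np.log(max(grid[i - 1], 1e-12)), np.log(grid[i + 1])),
            method="bounded", options={"xatol": 1e-12})
        theta = float(np.exp(res.x))
        if _dense_crit(theta, y, X, ZZT)[0] < vals[i]:
            theta = float(grid[i])
    else:
        theta = float(grid[i])
    crit, beta, s2e, A = _dense_crit(theta, y, X, ZZT)
    cov_beta = s2e * np.linalg.inv(A)
    return {"theta": theta, "beta": beta, "sigma2_e": s2e,
            "sigma2_u": theta * s2e, "crit": crit, "cov_beta": cov_beta,
            "X": X, "ZZT": ZZT, "y": y, "n": X.shape[0], "p": X.shape[1]}


def contrast_p_dense(fit: dict, c) -> tuple[float, float, float]:
    """(estimate, df, p) for c'beta with a dense-matrix Satterthwaite df."""
    c = np.asarray(c, dtype=float)
    est = float(c @ fit["beta"])
    var = float(c @ fit["cov_beta"] @ c)
    s2u, s2e = max(fit["sigma2_u"], 0.0), fit["sigma2_e"]
    resid_df = fit["n"] - fit["p"]
    X, ZZT, y = fit["X"], fit["ZZT"], fit["y"]
    if s2u <= 1e-10 * s2e:
        df = float(resid_df)
    else:
        hu, he = 2e-5 * s2u, 2e-5 * s2e

        def ll(u, e):
            return _dense_ll2(u, e, y, X, ZZT)

        f0 = ll(s2u, s2e)
        H = np.array([
            [(ll(s2u + hu, s2e) - 2 * f0 + ll(s2u - hu, s2e)) / hu ** 2,
             (ll(s2u + hu, s2e + he) - ll(s2u + hu, s2e - he)
              - ll(s2u - hu, s2e + he) + ll(s2u - hu, s2e - he))
             / (4 * hu * he)],
            [0.0, (ll(s2u, s2e + he) - 2 * f0 + ll(s2u, s2e - he)) / he ** 2],
        ])
        H[1, 0] = H[0, 1]
        f = _dense_cvc(c, s2u, s2e, X, ZZT)
        g = np.array([
            (_dense_cvc(c, s2u + hu, s2e, X, ZZT)
             - _dense_cvc(c, s2u - hu, s2e, X, ZZT)) / (2 * hu),
            (_dense_cvc(c, s2u, s2e + he, X, ZZT)
             - _dense_cvc(c, s2u, s2e - he, X, ZZT)) / (2 * he),
        ])
        W = np.linalg.inv(-H)
        denom = float(g @ W @ g)
        df = (2.0 * f * f / denom if denom > 0 else float(resid_df))
        df = float(np.clip(df, 1.0, resid_df))
    t = est / np.sqrt(var)
    return est, df, 2.0 * stats.t.sf(abs(t), df)


# ---------------------------------------------------------------------------
# Ward.D2 Lance-Williams agglomeration
# ---------------------------------------------------------------------------

def ward_d2_merge_heights(X) -> list[float]:
    """Brute-force Ward.D2: argmin merges with the Lance-Williams update on
    squared Euclidean distances; returns the merge heights in order."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    heights = []
    next_id = n
    while len(clusters) > 1:
        (a, b), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(best))
        na, nb = len(clusters[a]), len(clusters[b])
        new = clusters.pop(a) + clusters.pop(b)
        updates = {}
        for k in clusters:
            nk = len(clusters[k])
            dka = d2.pop((min(a, k), max(a, k)))
            dkb = d2.pop((min(b, k), max(b, k)))
            updates[(k, next_id)] = ((na + nk) * dka + (nb + nk) * dkb
                                     - nk * best) / (na + nb + nk)
        d2.pop((a, b), None)
        d2 = {k: v for k, v in d2.items() if a not in k and b not in k}
        d2.update(updates)
        clusters[next_id] = new
        next_id += 1
    return heights


# ---------------------------------------------------------------------------
# exhaustive global-test enumeration
# ---------------------------------------------------------------------------

def exhaustive_global_p(values, labels) -> float:
    """Exact permutation p of the global test by enumerating all label
    assignments with the observed class sizes (feasible for n <= 10)."""
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    m = Xs.shape[1]

    def stat(lab):
        s = Xs.T @ (lab - lab.mean())
        return float(s @ s) / m

    q_obs = stat(y)
    n, n1 = len(y), int(y.sum())
    qs = []
    for ones in combinations(range(n), n1):
        yp = np.zeros(n)
        yp[list(ones)] = 1.0
        qs.append(stat(yp))
    qs = np.asarray(qs)
    return float(np.mean(qs >= q_obs - 1e-12))
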