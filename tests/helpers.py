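"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the mixed-model oracle
builds the full dense covariance matrix and maximizes the likelihood over
absolute variance parameters with its own optimizer; the slope oracle is the
textbook normal-equations formula.
"""

import numpy as np
from scipy import optimize


def dense_nested_ml(y, X, family, individual=None):
    """Dense-matrix ML for a nested random-intercept model (small n only)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    F = (np.asarray(family)[:, None] == np.unique(family)[None, :]).astype(float)
    has_ind = individual is not None
    if has_ind:
        Z = (np.asarray(individual)[:, None]
             == np.unique(individual)[None, :]).astype(float)

    def nll(log_s):
        s = np.exp(np.clip(log_s, -40, 40))
        V = s[0] * np.eye(n) + s[-1] * (F @ F.T)
        if has_ind:
            V = V + s[1] * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        beta = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ beta
        _, ld = np.linalg.slogdet(V)
        return 0.5 * (n * np.log(2 * np.pi) + ld + r @ Vi @ r)

    k = 3 if has_ind else 2
    v0 = np.var(y) / k
    best = None
    for start in (np.full(k, np.log(v0)), np.full(k, np.log(v0 / 10))):
        res = optimize.minimize(
            nll, start, method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-14, maxiter=20000, maxfev=40000),
        )
        if best is None or res.fun < best.fun:
            best = res
    s = np.exp(best.x)
    V = s[0] * np.eye(n) + s[-1] * (F @ F.T)
    if has_ind:
        V = V + s[1] * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    out = {"params": beta, "sigma2_obs": s[0], "sigma2_fam": s[-1],
           "llf": -best.fun, "cov_params": np.linalg.inv(A)}
    if has_ind:
        out["sigma2_ind"] = s[1]
    return out


def ols_slope(x, y):
    """Normal-equations OLS slope and its standard error (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    if n > 2:
        se = np.sqrt((resid ** 2).sum() / (n - 2) / (sxx - sx * sx / n))
    else:
        se = np.inf
    return slope, se


def make_nested_data(rng, n_fam=10, kids=2, obs=2, beta=(1.0, 0.5),
                     vc=(0.5, 0.3, 0.2)):
    """Small three-level dataset with known fixed effects and components."""
    fam = np.repeat(np.arange(n_fam), kids * obs)
    ind = np.repeat(np.arange(n_fam * kids), obs)
    n = len(fam)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    u = rng.normal(0, np.sqrt(vc[2]), n_fam)[fam]
    v = rng.normal(0, np.sqrt(vc[1]), n_fam * kids)[ind]
    e = rng.normal(0, np.sqrt(vc[0]), n)
    y = X @ np.asarray(beta) + u + v + e
    return y, X, fam, ind
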