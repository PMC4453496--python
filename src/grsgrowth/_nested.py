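"""Maximum-likelihood machinery for nested random-intercept models.

Fits, by profile maximum likelihood, linear models with covariance

    V = sigma2_obs * ( I + r_ind * Z Z' + r_fam * F F' )

where Z and F are indicator matrices for individuals nested in families.
Either level may be absent (no ``individual`` gives the classic clustered
random-intercept GLS).  Because the random effects are nested intercepts,
V^{-1} x and log|V| have closed forms via two Sherman-Morrison sweeps
(one per individual block, one rank-one update per family), so each
likelihood evaluation is O(n * p).  The two variance ratios are profiled
out with a Nelder-Mead search on the log scale; the fixed effects and the
observation variance have closed-form GLS/ML solutions given the ratios.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .exceptions import ConvergenceError, InputError

__all__ = ["NestedMLFit", "fit_nested_ml"]


class _NestedDesign:
    """Row ordering and group index bookkeeping for the nested structure."""

    def __init__(self, y, X, family, individual=None):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("exog must be 2-dimensional")
        n = y.shape[0]
        if X.shape[0] != n:
            raise InputError("endog and exog have different lengths")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise InputError("endog/exog contain non-finite values")
        family = np.asarray(family)
        if family.shape[0] != n:
            raise InputError("family labels have wrong length")

        _, fam_codes = np.unique(family, return_inverse=True)
        self.has_ind = individual is not None
        if self.has_ind:
            individual = np.asarray(individual)
            if individual.shape[0] != n:
                raise InputError("individual labels have wrong length")
            _, ind_codes = np.unique(individual, return_inverse=True)
            # each individual must belong to exactly one family
            pairs = np.unique(np.column_stack([ind_codes, fam_codes]), axis=0)
            if len(pairs) != len(np.unique(ind_codes)):
                raise InputError(
                    "individuals are not nested in families: at least one "
                    "individual id appears in two families"
                )
            order = np.lexsort((ind_codes, fam_codes))
        else:
            ind_codes = None
            order = np.argsort(fam_codes, kind="stable")

        self.n = n
        self.order = order
        self.y = y[order]
        self.X = X[order]
        fam_sorted = fam_codes[order]
        self.fam_starts = np.r_[0, np.flatnonzero(np.diff(fam_sorted)) + 1]
        self.n_per_fam = np.diff(np.r_[self.fam_starts, n])
        self.n_fam = len(self.fam_starts)
        if self.has_ind:
            ind_sorted = ind_codes[order]
            self.ind_starts = np.r_[0, np.flatnonzero(np.diff(ind_sorted)) + 1]
            self.n_per_ind = np.diff(np.r_[self.ind_starts, n]).astype(float)
            self.n_ind = len(self.ind_starts)
            self.row_ind = np.repeat(np.arange(self.n_ind), self.n_per_ind.astype(int))
        self.row_fam = np.repeat(np.arange(self.n_fam), self.n_per_fam)

    def cinv_apply(self, M, r_ind, r_fam):
        """Return C^{-1} M for C = I + r_ind Z Z' + r_fam F F' (sorted rows)."""
        if M.ndim == 1:
            M = M[:, None]
        if self.has_ind:
            S = np.add.reduceat(M, self.ind_starts, axis=0)
            a = r_ind / (1.0 + r_ind * self.n_per_ind)
            WM = M - (a[:, None] * S)[self.row_ind]
            w_row = (1.0 / (1.0 + r_ind * self.n_per_ind))[self.row_ind]
        else:
            WM = M
            w_row = np.ones(self.n)
        sF = np.add.reduceat(WM, self.fam_starts, axis=0)
        dF = np.add.reduceat(w_row, self.fam_starts)
        kF = r_fam / (1.0 + r_fam * dF)
        return WM - w_row[:, None] * (kF[:, None] * sF)[self.row_fam]

    def logdet_c(self, r_ind, r_fam):
        if self.has_ind:
            ld = np.log1p(r_ind * self.n_per_ind).sum()
            dF = np.add.reduceat(
                (1.0 / (1.0 + r_ind * self.n_per_ind))[self.row_ind], self.fam_starts
            )
        else:
            ld = 0.0
            dF = self.n_per_fam.astype(float)
        return ld + np.log1p(r_fam * dF).sum()

    def profile(self, r_ind, r_fam):
        """GLS fixed effects and profiled nll at the given variance ratios."""
        CiX = self.cinv_apply(self.X, r_ind, r_fam)
        Ciy = self.cinv_apply(self.y, r_ind, r_fam).ravel()
        XtCiX = self.X.T @ CiX
        XtCiy = CiX.T @ self.y
        try:
            beta = np.linalg.solve(XtCiX, XtCiy)
        except np.linalg.LinAlgError:
            raise InputError("design matrix is singular (collinear columns?)")
        rss = float(self.y @ Ciy - beta @ XtCiy)
        rss = max(rss, 1e-300)
        sigma2 = rss / self.n
        nll = 0.5 * (
            self.n * (np.log(2.0 * np.pi * sigma2) + 1.0)
            + self.logdet_c(r_ind, r_fam)
        )
        return nll, beta, sigma2, XtCiX


def _newton_polish(fun, x0, f0, h=1e-4, iters=2):
    """Quadratic-model refinement of a located optimum.

    Central differences with a step well above the function's float-noise
    floor give a usable gradient/Hessian even where the raw values are only
    accurate to ~1e-12 relative; skipped when the local model is not convex
    (likelihood plateau at a zero variance component)."""
    x, f = np.asarray(x0, dtype=float), f0
    k = len(x)
    eye = np.eye(k)
    for _ in range(iters):
        g = np.zeros(k)
        H = np.zeros((k, k))
        fp = np.zeros(k)
        fm = np.zeros(k)
        for i in range(k):
            fp[i] = fun(x + h * eye[i])
            fm[i] = fun(x - h * eye[i])
            g[i] = (fp[i] - fm[i]) / (2 * h)
            H[i, i] = (fp[i] - 2 * f + fm[i]) / h ** 2
        for i in range(k):
            for j in range(i + 1, k):
                fpp = fun(x + h * (eye[i] + eye[j]))
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f) / h ** 2
        try:
            evals = np.linalg.eigvalsh(H)
        except np.linalg.LinAlgError:
            return x, f
        if evals.min() <= 0:
            return x, f
        step = np.linalg.solve(H, g)
        if np.abs(step).max() > 0.5:  # outside the quadratic trust region
            return x, f
        x_new = x - step
        f_new = fun(x_new)
        if f_new <= f + 1e-9 * max(1.0, abs(f)):
            x, f = x_new, min(f_new, f)
        else:
            return x, f
    return x, f


class NestedMLFit:
    """Raw result of :func:`fit_nested_ml` (fixed effects + variance components)."""

    def __init__(self, params, cov_params, sigma2_obs, sigma2_ind, sigma2_fam,
                 llf, nobs, n_fam, n_ind, converged, n_iter):
        self.params = params
        self.cov_params = cov_params
        self.sigma2_obs = sigma2_obs
        self.sigma2_ind = sigma2_ind
        self.sigma2_fam = sigma2_fam
        self.llf = llf
        self.nobs = nobs
        self.n_fam = n_fam
        self.n_ind = n_ind
        self.converged = converged
        self.n_iter = n_iter


def fit_nested_ml(y, X, family, individual=None, *, start=None,
                  xatol=1e-9, fatol=1e-12, maxiter=2000):
    """ML fit of a linear model with nested random intercepts.

    Parameters
    ----------
    y, X : array-like
        Response (n,) and design matrix (n, p).
    family : array-like
        Cluster labels for the top random-intercept level.
    individual : array-like, optional
        Labels for the individual level nested in `family`.  Omit for a
        two-level (cluster + residual) model.
    start : sequence of float, optional
        Starting variance ratios (individual, family) relative to the
        observation variance; defaults to 0.5 each.
    """
    design = _NestedDesign(y, X, family, individual)
    k = 2 if design.has_ind else 1
    if start is None:
        theta0 = np.full(k, np.log(0.5))
    else:
        start = np.atleast_1d(np.asarray(start, dtype=float))
        if start.shape[0] != k:
            raise InputError(f"start must have length {k}")
        theta0 = np.log(np.clip(start, 1e-12, None))

    def unpack(theta):
        r = np.exp(np.clip(theta, -35.0, 35.0))
        if design.has_ind:
            return float(r[0]), float(r[1])
        return 0.0, float(r[0])

    def nll(theta):
        r_ind, r_fam = unpack(theta)
        return design.profile(r_ind, r_fam)[0]

    res = optimize.minimize(
        nll, theta0, method="Nelder-Mead",
        options=dict(xatol=xatol, fatol=fatol, maxiter=maxiter,
                     maxfev=6 * maxiter),
    )
    if not res.success:
        # a variance ratio drifting to zero leaves the log-scale simplex on a
        # likelihood plateau; accept when the fit is flat in the likelihood
        fsim = res.final_simplex[1]
        if not np.ptp(fsim) <= 1e-8 * max(1.0, abs(res.fun)):
            raise ConvergenceError(
                f"nested ML did not converge in {maxiter} iterations: "
                f"{res.message}"
            )
    # Newton polish with finite differences: Nelder-Mead terminates once
    # function differences sink into float noise, which still leaves the
    # ratios ~1e-6 loose; one or two quadratic steps pin them down (a no-op
    # on likelihood plateaus, where the local model is not convex)
    res.x, res.fun = _newton_polish(nll, res.x, res.fun)
    r_ind, r_fam = unpack(res.x)
    _, beta, sigma2, XtCiX = design.profile(r_ind, r_fam)
    cov = sigma2 * np.linalg.inv(XtCiX)
    # ratios pushed to the clip boundary are numerically zero components
    sigma2_ind = sigma2 * r_ind if design.has_ind else None
    sigma2_fam = sigma2 * r_fam
    return NestedMLFit(
        params=beta,
        cov_params=cov,
        sigma2_obs=sigma2,
        sigma2_ind=sigma2_ind,
        sigma2_fam=sigma2_fam,
        llf=-res.fun,
        nobs=design.n,
        n_fam=design.n_fam,
        n_ind=design.n_ind if design.has_ind else None,
        converged=True,
        n_iter=res.nit,
    )
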