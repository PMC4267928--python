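"""REML estimation and Henderson mixed-model solving.

Two model families cover everything in the study:

* iid-residual family  V = sigma_g2 * Z K Z' + sigma_e2 * I.  The restricted
  likelihood is profiled over the variance ratio lambda = sigma_g2/sigma_e2
  after a single symmetric eigendecomposition of Z K Z', with sigma_e2
  updated in closed form; a log-spaced grid plus bounded Brent refinement
  makes the search robust near the lambda = 0 boundary.
* fixed-residual family  V = sigma_g2 * K + R with R known (used when the
  stage-1 precision of adjusted means is carried forward).  After whitening
  by the Cholesky factor of R the same eigen-trick applies and the REML
  criterion is maximized directly over sigma_g2 >= 0.

Boundary solutions (sigma_g2 = 0) are detected by explicit comparison with
the zero-variance criterion value and returned flagged, never raised, so
downstream code can count them the way the study counts zero genetic
variance.  Non-convergence (non-finite criterion, singular systems) is also
a flagged outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize_scalar

__all__ = ["REMLResult", "reml_fit", "solve_mme", "mean_variance_difference"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class REMLResult:
    """Variance components, REML criterion and mixed-model solutions."""

    sigma_g2: float
    sigma_e2: float            # nan when the residual covariance was fixed
    loglik: float
    converged: bool
    boundary: bool             # sigma_g2 estimate hit the zero boundary
    beta: np.ndarray | None = None
    beta_cov: np.ndarray | None = None
    blup: np.ndarray | None = None
    pev: np.ndarray | None = None
    n_obs: int = 0
    message: str = ""

    @property
    def vbar_blup(self) -> float:
        """Mean variance of a difference of two BLUPs (from the PEV)."""
        if self.pev is None:
            raise ValueError("PEV not computed for this fit")
        return mean_variance_difference(self.pev)


def mean_variance_difference(C: np.ndarray) -> float:
    """Average of var(d_i - d_j) over all unordered pairs.

    For a variance matrix C this is mean(C_ii + C_jj - 2 C_ij) over i < j,
    computed in closed form as 2 (n tr(C) - 1'C1) / (n (n-1)).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if n < 2:
        raise ValueError("need at least two entities")
    return float(2.0 * (n * np.trace(C) - C.sum()) / (n * (n - 1)))


def _crit_profiled(lam, d, yr, Xr):
    """-2 REML (up to constants) for the iid family at ratio lam."""
    n, p = Xr.shape
    w = 1.0 + lam * d
    if np.any(w <= 0):
        return np.inf, None, None, None
    Xw = Xr / w[:, None]
    A = Xr.T @ Xw
    try:
        c = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    beta = cho_solve(c, Xw.T @ yr)
    r = yr - Xr @ beta
    rss = float(np.sum(r * r / w))
    if rss <= 0:
        return np.inf, None, None, None
    s2 = rss / (n - p)
    logdetA = 2.0 * np.sum(np.log(np.diag(c[0])))
    crit = (n - p) * (np.log(s2) + 1.0 + _LOG2PI) + np.sum(np.log(w)) + logdetA
    return crit, s2, beta, c


def _crit_fixed(sg2, d, yr, Xr):
    """-2 REML (up to constants) for the fixed-residual family."""
    w = 1.0 + sg2 * d
    if np.any(w <= 0):
        return np.inf
    Xw = Xr / w[:, None]
    A = Xr.T @ Xw
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    try:
        beta = np.linalg.solve(A, Xw.T @ yr)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ beta
    rss = float(np.sum(r * r / w))
    return rss + np.sum(np.log(w)) + logdetA


def _search(f, grid):
    """Grid scan + bounded Brent refinement of a scalar criterion on
    log-parameter scale; returns (best_x, best_f, ok)."""
    vals = np.array([f(g) for g in grid])
    if not np.isfinite(vals).any():
        return grid[0], np.inf, False
    i = int(np.nanargmin(np.where(np.isfinite(vals), vals, np.inf)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return grid[i], vals[i], True
    try:
        res = minimize_scalar(lambda t: f(np.exp(t)),
                              bounds=(np.log(lo), np.log(hi)),
                              method="bounded",
                              options={"xatol": 1e-9})
        x = float(np.exp(res.x))
        fx = float(res.fun)
        if np.isfinite(fx) and fx <= vals[i]:
            return x, fx, True
    except Exception:
        pass
    return grid[i], vals[i], True


def reml_fit(y, X, K=None, Z=None, R=None, effects: bool = True,
             boundary_tol: float = 1e-8) -> REMLResult:
    """REML fit of a one-random-term Gaussian mixed model.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design, full column rank.
    K : (m, m) covariance structure of the random term (identity if None).
    Z : (n, m) incidence of the random term (identity if None).
    R : (n, n) fixed residual covariance; if None the residual is
        iid sigma_e2 * I with sigma_e2 estimated by profiling.
    effects : also solve the mixed-model equations at the estimates and
        return BLUEs with covariance, BLUPs and their PEV.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.size != n:
        raise ValueError("response and design dimensions do not conform")
    m = n if Z is None else Z.shape[1]
    if np.ptp(y) == 0.0:
        return REMLResult(0.0, 0.0 if R is None else np.nan, -np.inf,
                          converged=False, boundary=True, n_obs=n,
                          message="constant response")

    if R is None:
        # iid residual: eigendecompose M = Z K Z'
        if Z is None:
            M = np.eye(n) if K is None else np.asarray(K, dtype=float)
        else:
            ZK = Z if K is None else Z @ K
            M = ZK @ Z.T
        d, U = np.linalg.eigh(M)
        d = np.clip(d, 0.0, None)
        yr, Xr = U.T @ y, U.T @ X
        f = lambda lam: _crit_profiled(lam, d, yr, Xr)[0]
        crit0 = f(0.0)
        grid = np.concatenate([np.logspace(-8, 8, 33)])
        lam, crit, ok = _search(f, grid)
        boundary = (not np.isfinite(crit)) or \
            crit0 <= crit + boundary_tol * max(1.0, abs(crit0))
        if boundary:
            lam, crit = 0.0, crit0
        c, s2, _, _ = _crit_profiled(lam, d, yr, Xr)
        converged = ok and np.isfinite(crit) and s2 is not None
        if not converged:
            return REMLResult(np.nan, np.nan, -np.inf, False, boundary,
                              n_obs=n, message="REML criterion not finite")
        sg2, se2 = lam * s2, s2
        ll = -0.5 * crit
        Rmat = None
    else:
        Rmat = np.asarray(R, dtype=float)
        if Z is not None:
            raise ValueError("fixed-residual family supports Z = identity only")
        try:
            L = cholesky(Rmat, lower=True)
        except np.linalg.LinAlgError:
            return REMLResult(np.nan, np.nan, -np.inf, False, False, n_obs=n,
                              message="residual covariance not positive definite")
        Kw = solve_triangular(L, (np.eye(n) if K is None
                                  else np.asarray(K, float)), lower=True)
        Kw = solve_triangular(L, Kw.T, lower=True)  # L^-1 K L^-T (symmetric)
        d, U = np.linalg.eigh((Kw + Kw.T) / 2.0)
        d = np.clip(d, 0.0, None)
        yw = solve_triangular(L, y, lower=True)
        Xw = solve_triangular(L, X, lower=True)
        yr, Xr = U.T @ yw, U.T @ Xw
        f = lambda s: _crit_fixed(s, d, yr, Xr)
        crit0 = f(0.0)
        scale = max(float(np.var(y)), float(np.mean(np.diag(Rmat))), 1e-12)
        grid = scale * np.logspace(-8, 6, 29)
        sg2, crit, ok = _search(f, grid)
        boundary = (not np.isfinite(crit)) or \
            crit0 <= crit + boundary_tol * max(1.0, abs(crit0))
        if boundary:
            sg2, crit = 0.0, crit0
        converged = ok and np.isfinite(crit)
        if not converged:
            return REMLResult(np.nan, np.nan, -np.inf, False, boundary,
                              n_obs=n, message="REML criterion not finite")
        se2 = np.nan
        ll = -0.5 * crit

    result = REMLResult(float(sg2), float(se2), float(ll), converged,
                        bool(boundary), n_obs=n)
    if effects:
        try:
            beta, bcov, blup, pev = solve_mme(
                y, X, sigma_g2=result.sigma_g2, sigma_e2=result.sigma_e2,
                K=K, Z=Z, R=Rmat)
        except np.linalg.LinAlgError:
            result.converged = False
            result.message = "singular mixed-model system"
            return result
        result.beta, result.beta_cov = beta, bcov
        result.blup, result.pev = blup, pev
    return result


def solve_mme(y, X, sigma_g2: float, sigma_e2: float = np.nan,
              K=None, Z=None, R=None):
    """Solve the mixed-model equations at fixed variance components.

    Returns (beta, beta_cov, blup, pev) with
    beta = (X'V^-1X)^-1 X'V^-1 y,   blup = G_z' V^-1 (y - X beta),
    pev = G - G_z' P G_z where P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1,
    the genotype block of the inverted Henderson coefficient matrix.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    m = n if Z is None else Z.shape[1]
    Kmat = np.eye(m) if K is None else np.asarray(K, dtype=float)
    Gz = sigma_g2 * (Kmat if Z is None else Kmat @ Z.T)   # (m, n) = G Z'
    ZG = Gz.T                                             # (n, m) = Z G
    V = (Z @ Gz) if Z is not None else Gz.copy()
    if R is None:
        V = V + sigma_e2 * np.eye(n)
    else:
        V = V + np.asarray(R, dtype=float)
    c = cho_factor((V + V.T) / 2.0, lower=True)
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    A = X.T @ Vi_X
    Ac = cho_factor((A + A.T) / 2.0, lower=True)
    beta = cho_solve(Ac, X.T @ Vi_y)
    beta_cov = cho_solve(Ac, np.eye(A.shape[0]))
    resid = y - X @ beta
    blup = Gz @ cho_solve(c, resid)
    # PEV = G - Gz' V^-1 Z G + (Gz' V^-1 X) A^-1 (X' V^-1 Z G)
    T = cho_solve(c, ZG)            # V^-1 Z G, (n, m)
    B = X.T @ T                     # (p, m)
    pev = sigma_g2 * Kmat - Gz @ T + B.T @ cho_solve(Ac, B)
    pev = (pev + pev.T) / 2.0
    return beta, beta_cov, blup, pev
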