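"""Scikit-learn style estimators for the two analysis stages.

``StageOneModel`` turns plot-level trial records into adjusted genotype
means (genotype and replicate fixed, incomplete block random), exposing the
means, their variance matrix and the plot-level variance components.

``BLUPModel`` fits the stage-2 mixed model eta = phi + g + e to adjusted
means.  With ``kernel="linear"`` it is RR-BLUP/GBLUP: Var(g) = Z Z' sigma_u2
with Z the marker matrix passed as ``X``; with ``kernel="identity"`` the
genotypes are independent, Var(g) = I sigma_g2; ``kernel="precomputed"``
accepts any covariance structure.  The residual is either iid (variance
estimated by REML) or a fixed matrix carried forward from stage 1.  Both
estimators follow the sklearn contract (``get_params``/``set_params``,
``clone``, fitted attributes with trailing underscores) so they compose
with sklearn model selection; ``BLUPModel.predict`` performs held-out
genomic prediction from training-set covariances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .reml import REMLResult, reml_fit, mean_variance_difference
from .simulate import TrialData

__all__ = ["StageOneModel", "BLUPModel"]


class StageOneModel(BaseEstimator):
    """Adjusted genotype means from alpha-design plot data.

    Model: yield ~ genotype (fixed) + replicate (fixed) + block-within-
    replicate (random, sigma_b2) + plot error (iid sigma_e2), estimated by
    REML.  Adjusted means are the genotype BLUEs (at the first-replicate
    baseline; the common offset is immaterial downstream).

    Attributes
    ----------
    means_ : (n,) adjusted genotype means, in genotype-level order.
    vcov_ : (n, n) variance matrix of the means.
    sigma_b2_, sigma_e2_ : block and plot-error variance components.
    vbar_ : mean variance of a difference of two adjusted means.
    converged_, boundary_ : REML status flags.
    """

    def __init__(self, boundary_tol: float = 1e-8):
        self.boundary_tol = boundary_tol

    def fit(self, X, y=None):
        df = X.to_frame() if isinstance(X, TrialData) else pd.DataFrame(X)
        needed = {"genotype", "replicate", "block", "yield"}
        if not needed.issubset(df.columns):
            raise ValueError(f"plot table must have columns {sorted(needed)}")
        geno = pd.Categorical(df["genotype"])
        rep = pd.Categorical(df["replicate"])
        blk = pd.Categorical(
            list(zip(df["replicate"], df["block"])))
        n_obs, n_g, n_r = len(df), len(geno.categories), len(rep.categories)
        Xg = np.zeros((n_obs, n_g))
        Xg[np.arange(n_obs), geno.codes] = 1.0
        Xr = np.zeros((n_obs, n_r - 1))
        pos = rep.codes - 1
        keep = pos >= 0
        Xr[np.where(keep)[0], pos[keep]] = 1.0
        Xmat = np.hstack([Xg, Xr]) if n_r > 1 else Xg
        Zb = np.zeros((n_obs, len(blk.categories)))
        Zb[np.arange(n_obs), blk.codes] = 1.0

        res = reml_fit(df["yield"].to_numpy(dtype=float), Xmat, Z=Zb,
                       effects=True, boundary_tol=self.boundary_tol)
        self.genotype_levels_ = np.asarray(geno.categories)
        self.n_genotypes_ = n_g
        self.converged_ = res.converged
        self.boundary_ = res.boundary
        self.sigma_b2_ = res.sigma_g2
        self.sigma_e2_ = res.sigma_e2
        self.loglik_ = res.loglik
        if res.converged and res.beta is not None:
            self.means_ = res.beta[:n_g]
            self.vcov_ = res.beta_cov[:n_g, :n_g]
            self.vbar_ = mean_variance_difference(self.vcov_)
        else:
            self.means_ = np.full(n_g, np.nan)
            self.vcov_ = np.full((n_g, n_g), np.nan)
            self.vbar_ = np.nan
        return self

    def to_frame(self) -> pd.DataFrame:
        """Adjusted means as a (genotype, mean, se) table."""
        return pd.DataFrame({
            "genotype": self.genotype_levels_,
            "mean": self.means_,
            "se": np.sqrt(np.diag(self.vcov_)),
        })


class BLUPModel(BaseEstimator, RegressorMixin):
    """Stage-2 mixed model with an intercept and one random genotype term.

    Parameters
    ----------
    kernel : "linear" (Var(g) = X X' sigma_u2, X the marker matrix),
        "identity" (independent genotypes) or "precomputed" (X is the
        covariance structure K itself).
    residual : "iid" for R = I sigma_e2 estimated by REML, or "fixed" for a
        known residual covariance passed to ``fit`` as ``R`` (typically the
        stage-1 variance matrix of the adjusted means).

    Attributes
    ----------
    sigma_g2_ : variance of the random term (sigma_u2 for marker kernels).
    sigma_e2_ : residual variance (nan when ``residual="fixed"``).
    intercept_ : the fixed general mean phi.
    blup_, pev_ : genotype BLUPs and their prediction-error variance matrix.
    vbar_blup_ : mean variance of a BLUP difference.
    converged_, boundary_ : fit status flags.
    """

    def __init__(self, kernel: str = "linear", residual: str = "iid",
                 boundary_tol: float = 1e-8):
        self.kernel = kernel
        self.residual = residual
        self.boundary_tol = boundary_tol

    def _kernel_matrix(self, X, n):
        if self.kernel == "identity":
            return np.eye(n)
        X = np.asarray(X, dtype=float)
        if self.kernel == "linear":
            return X @ X.T
        if self.kernel == "precomputed":
            if X.shape != (n, n):
                raise ValueError("precomputed kernel must be n x n")
            return X
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def fit(self, X, y, R=None):
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        K = self._kernel_matrix(X, n)
        ones = np.ones((n, 1))
        if self.residual == "iid":
            res = reml_fit(y, ones, K=K, boundary_tol=self.boundary_tol)
        elif self.residual == "fixed":
            if R is None:
                raise ValueError('residual="fixed" requires R in fit')
            res = reml_fit(y, ones, K=K, R=R,
                           boundary_tol=self.boundary_tol)
        else:
            raise ValueError(f"unknown residual mode {self.residual!r}")
        self._store(res, X, y, K, R)
        return self

    def _store(self, res: REMLResult, X, y, K, R):
        n = y.size
        self.n_obs_ = n
        self.result_ = res
        self.converged_ = res.converged
        self.boundary_ = res.boundary
        self.sigma_g2_ = res.sigma_g2
        self.sigma_e2_ = res.sigma_e2
        self.loglik_ = res.loglik
        if res.converged and res.beta is not None:
            self.intercept_ = float(res.beta[0])
            self.blup_ = res.blup
            self.pev_ = res.pev
            self.vbar_blup_ = (mean_variance_difference(res.pev)
                               if n > 1 else np.nan)
            # V^-1 (y - phi) for held-out prediction
            V = self.sigma_g2_ * K
            V = V + (np.asarray(R, float) if R is not None
                     else self.sigma_e2_ * np.eye(n))
            self._alpha = np.linalg.solve(V, y - self.intercept_)
        else:
            self.intercept_ = np.nan
            self.blup_ = np.full(n, np.nan)
            self.pev_ = np.full((n, n), np.nan)
            self.vbar_blup_ = np.nan
            self._alpha = np.full(n, np.nan)
        if self.kernel == "linear":
            self.X_fit_ = np.asarray(X, dtype=float)
        return self

    # `sigma_u2_` is the marker-effect variance under the linear kernel;
    # it is the same fitted scalar as `sigma_g2_`.
    @property
    def sigma_u2_(self) -> float:
        return self.sigma_g2_

    def predict_genetic_effects(self, X) -> np.ndarray:
        """BLUPs of g for held-out genotypes.

        ``X`` is the held-out marker matrix for ``kernel="linear"`` or the
        cross-covariance structure K[new, train] for ``kernel="precomputed"``;
        returns G_new,train V_train^-1 (y_train - phi).
        """
        if self.kernel == "identity":
            raise ValueError("independent genotypes carry no information "
                             "about held-out genotypes")
        X = np.asarray(X, dtype=float)
        Kc = X @ self.X_fit_.T if self.kernel == "linear" else X
        return self.sigma_g2_ * (Kc @ self._alpha)

    def predict(self, X) -> np.ndarray:
        return self.intercept_ + self.predict_genetic_effects(X)
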