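"""Heritability measures and predictive-accuracy estimators.

Five heritability measures (methods 1-5) and seven accuracy estimators are
implemented.  Methods 1-4 estimate accuracy indirectly as predictive
ability divided by the square root of a heritability; methods 5-7 estimate
accuracy directly from the fitted covariance structures:

* m1: sigma_g2 / (sigma_g2 + sigma_e2 / r), the plant breeders' ad hoc
  measure with plot error variance sigma_e2 and r replicates;
* m2: sigma_g2 / (sigma_g2 + vbar/2) with vbar the mean variance of a
  difference of two adjusted means (BLUE);
* m3: 1 - vbar_BLUP / (2 sigma_g2), the BLUP-based ad hoc measure;
* m4: trace(Pu G) / trace(V Pu), expected genetic over expected phenotypic
  sample variance;
* m5: trace(Pu C G) / sqrt(trace(Pu G) trace(C' Pu C V)) with
  C = G V^-1 Q, which approximates E(r_g,ghat) and doubles as a direct
  accuracy estimate;
* m6: s_ghat,p / sqrt(s_ghat^2 trace(Pu G));
* m7: the animal breeders' square root of mean reliability,
  rho_i^2 = (G_ii - PEV_ii) / G_ii.

All functions are deterministic in their inputs.  Degenerate inputs raise
``ValueError`` (or return nan for undefined correlations); the evaluation
layer converts these into the study's counted flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "GenomicModel", "true_accuracy", "predictive_ability",
    "heritability_m1", "heritability_m2", "heritability_m3",
    "heritability_m4", "accuracy_m5", "accuracy_m6", "accuracy_m7",
    "reliabilities", "indirect_accuracy", "pearson",
]


def pearson(a, b) -> float:
    """Sample Pearson correlation; nan when either input is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        return np.nan
    da, db = a - a.mean(), b - b.mean()
    va, vb = da @ da, db @ db
    if va <= 0 or vb <= 0:
        return np.nan
    return float((da @ db) / np.sqrt(va * vb))


def true_accuracy(g, ghat) -> float:
    """Correlation between true and predicted breeding values (benchmark)."""
    return pearson(g, ghat)


def predictive_ability(ghat, p) -> float:
    """Correlation between predicted breeding values and phenotypes."""
    return pearson(ghat, p)


@dataclass
class GenomicModel:
    """Covariance structures G (genotypes) and R (residuals) on the
    adjusted-means scale, with the derived operators used by methods 4-7.

    Pu is the centering quadratic form whose trace against a covariance
    matrix gives the expected sample variance; Q sweeps out the GLS
    intercept; C = G V^-1 Q maps phenotypes to genotype BLUPs (at the
    fitted intercept).
    """

    G: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.G.shape != self.R.shape or self.G.ndim != 2:
            raise ValueError("G and R must be square matrices of equal shape")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @cached_property
    def V(self) -> np.ndarray:
        return self.G + self.R

    @cached_property
    def Pu(self) -> np.ndarray:
        n = self.n
        return (np.eye(n) - np.ones((n, n)) / n) / (n - 1)

    @cached_property
    def _Vinv(self) -> np.ndarray:
        return np.linalg.inv(self.V)

    @cached_property
    def Q(self) -> np.ndarray:
        ones = np.ones((self.n, 1))
        Vi1 = self._Vinv @ ones
        return np.eye(self.n) - ones @ (Vi1.T / (ones.T @ Vi1).item())

    @cached_property
    def C(self) -> np.ndarray:
        return self.G @ self._Vinv @ self.Q


def heritability_m1(sigma_g2: float, sigma_e2: float, r: int) -> float:
    """sigma_g2 / (sigma_g2 + sigma_e2 / r)."""
    if sigma_g2 < 0 or sigma_e2 < 0 or r < 1:
        raise ValueError("variances must be >= 0 and r >= 1")
    if sigma_g2 == 0 and sigma_e2 == 0:
        raise ValueError("both variance components are zero")
    return sigma_g2 / (sigma_g2 + sigma_e2 / r)


def heritability_m2(sigma_g2: float, vbar: float) -> float:
    """sigma_g2 / (sigma_g2 + vbar / 2), vbar from BLUE differences."""
    if sigma_g2 < 0 or vbar < 0:
        raise ValueError("inputs must be >= 0")
    if sigma_g2 == 0 and vbar == 0:
        raise ValueError("degenerate inputs")
    return sigma_g2 / (sigma_g2 + vbar / 2.0)


def heritability_m3(sigma_g2: float, vbar_blup: float) -> float:
    """1 - vbar_BLUP / (2 sigma_g2); may be negative (caller flags)."""
    if vbar_blup < 0:
        raise ValueError("vbar_blup must be >= 0")
    if sigma_g2 <= 0:
        raise ValueError("zero genetic variance: heritability undefined")
    return 1.0 - vbar_blup / (2.0 * sigma_g2)


def heritability_m4(model: GenomicModel) -> float:
    """trace(Pu G) / trace(V Pu)."""
    num = float(np.trace(model.Pu @ model.G))
    den = num + float(np.trace(model.R @ model.Pu))
    if den <= 0:
        raise ValueError("expected phenotypic variance is not positive")
    return num / den


def accuracy_m5(model: GenomicModel) -> float:
    """trace(Pu C G) / sqrt(trace(Pu G) trace(C' Pu C V))."""
    Pu, C, G, V = model.Pu, model.C, model.G, model.V
    tPuG = float(np.trace(Pu @ G))
    if tPuG <= 0:
        raise ValueError("expected genetic sample variance is not positive")
    num = float(np.trace(Pu @ C @ G))
    den = np.sqrt(tPuG * float(np.trace(C.T @ Pu @ C @ V)))
    if den <= 0:
        raise ValueError("degenerate denominator")
    return num / den


def accuracy_m6(ghat, p, model: GenomicModel) -> float:
    """s_ghat,p / sqrt(s_ghat^2 * E(s_g^2)) with E(s_g^2) = trace(Pu G)."""
    ghat = np.asarray(ghat, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    e_sg2 = float(np.trace(model.Pu @ model.G))
    s_ghat2 = float(np.var(ghat, ddof=1))
    if s_ghat2 <= 0 or e_sg2 <= 0:
        raise ValueError("zero variance input")
    s_gp = float(np.cov(ghat, p, ddof=1)[0, 1])
    return s_gp / np.sqrt(s_ghat2 * e_sg2)


def reliabilities(model: GenomicModel, pev: np.ndarray) -> np.ndarray:
    """Per-genotype reliability (G_ii - PEV_ii) / G_ii, clipped to [0, 1]."""
    dG = np.diag(model.G)
    if np.any(dG <= 0):
        raise ValueError("diag(G) must be positive")
    rho2 = (dG - np.diag(pev)) / dG
    return np.clip(rho2, 0.0, 1.0)


def accuracy_m7(model: GenomicModel, pev: np.ndarray) -> float:
    """sqrt(mean reliability): the mixed-model-equation accuracy."""
    return float(np.sqrt(reliabilities(model, pev).mean()))


def indirect_accuracy(r_gp: float, H2: float) -> float:
    """Predictive ability divided by the square root of heritability."""
    if not np.isfinite(H2) or H2 <= 0:
        raise ValueError("heritability must be positive")
    if not np.isfinite(r_gp):
        raise ValueError("predictive ability is undefined")
    return r_gp / np.sqrt(H2)
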