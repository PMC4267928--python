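"""Two-stage analysis: plot data -> adjusted means -> genomic model.

Thin functional wrappers over the estimator classes in
:mod:`gpaccuracy.models`, returning the study's domain containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import BLUPModel, StageOneModel
from .simulate import TrialData

__all__ = ["AdjustedMeans", "stage1_adjusted_means", "stage2_fit"]


@dataclass
class AdjustedMeans:
    """Stage-1 output: genotype BLUEs with their variance information."""

    genotype_ids: np.ndarray
    p: np.ndarray
    vcov: np.ndarray
    sigma_b2: float
    sigma_e2_plot: float
    vbar: float
    converged: bool

    @property
    def n(self) -> int:
        return self.p.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "genotype": self.genotype_ids,
            "mean": self.p,
            "se": np.sqrt(np.diag(self.vcov)),
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)


def stage1_adjusted_means(trial: TrialData | pd.DataFrame) -> AdjustedMeans:
    """Adjusted genotype means from plot data (genotype and replicate
    fixed, incomplete block random, REML variance components)."""
    m = StageOneModel().fit(trial)
    return AdjustedMeans(
        genotype_ids=m.genotype_levels_, p=m.means_, vcov=m.vcov_,
        sigma_b2=m.sigma_b2_, sigma_e2_plot=m.sigma_e2_, vbar=m.vbar_,
        converged=m.converged_)


def stage2_fit(means: AdjustedMeans, structure: str = "genomic",
               Z: np.ndarray | None = None,
               weighting: str | None = None) -> BLUPModel:
    """Fit the stage-2 model eta = phi + g + e to adjusted means.

    structure "genomic" uses Var(g) = Z Z' sigma_u2 (Z required); structure
    "independent" uses Var(g) = I sigma_g2.  ``weighting`` selects the
    residual: "simple" is iid R = I sigma_e2, "carried" fixes R at the
    stage-1 variance matrix of the means.  The default is "simple" for the
    genomic structure and "carried" for the independent one, where the iid
    residual would make sigma_g2 unidentifiable (V would be a multiple of
    the identity however the total variance is split).
    """
    if structure == "genomic":
        if Z is None:
            raise ValueError("genomic structure requires the marker matrix Z")
        mode = weighting or "simple"
        if mode == "simple":
            return BLUPModel(kernel="linear", residual="iid").fit(
                np.asarray(Z, dtype=float), means.p)
        return BLUPModel(kernel="linear", residual="fixed").fit(
            np.asarray(Z, dtype=float), means.p, R=means.vcov)
    if structure == "independent":
        mode = weighting or "carried"
        if mode == "simple":
            raise ValueError(
                "independent structure with an iid residual is "
                "unidentifiable on adjusted means; use weighting='carried'")
        return BLUPModel(kernel="identity", residual="fixed").fit(
            None, means.p, R=means.vcov)
    raise ValueError(f"unknown structure {structure!r}")
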