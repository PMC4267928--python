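"""Three-fold, five-replicate cross-validation for predictive ability.

Each of the five replicates partitions the genotypes into three folds of
as-equal-as-possible size; each fold is held out in turn, the genomic
model is refit by REML on the remaining two thirds, and the held-out
genotypes receive BLUP predictions from their covariance with the training
set.  Predictive ability is the Pearson correlation between held-out
predictions and adjusted means, computed per replicate over all genotypes
and averaged over the computable replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import BLUPModel
from .simulate import as_rng
from .twostage import AdjustedMeans

__all__ = ["FoldPlan", "CVPredictions", "make_cv_folds", "cv_predict",
           "cv_predictive_ability"]


@dataclass
class FoldPlan:
    """One CV replicate: genotype -> fold assignment in {0, ..., k-1}."""

    replicate_index: int
    folds: np.ndarray

    @property
    def n_folds(self) -> int:
        return int(self.folds.max()) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": self.replicate_index,
            "genotype": np.arange(self.folds.size),
            "fold": self.folds,
        })


@dataclass
class CVPredictions:
    """Held-out genetic-effect predictions, one row per CV replicate."""

    predictions: np.ndarray          # (reps, n)
    fold_converged: np.ndarray       # (reps, k) bool
    fold_boundary: np.ndarray        # (reps, k) bool: training sigma_u2 = 0

    @property
    def n_replicates(self) -> int:
        return self.predictions.shape[0]


def make_cv_folds(n: int, k: int = 3, reps: int = 5,
                  seed=None) -> list[FoldPlan]:
    """Independent random k-fold partitions; fold sizes differ by <= 1."""
    if n < k:
        raise ValueError("need at least one genotype per fold")
    rng = as_rng(seed)
    base, extra = divmod(n, k)
    sizes = np.array([base + 1] * extra + [base] * (k - extra))
    fold_of_pos = np.repeat(np.arange(k), sizes)
    plans = []
    for r in range(reps):
        folds = np.empty(n, dtype=int)
        folds[rng.permutation(n)] = fold_of_pos
        plans.append(FoldPlan(replicate_index=r + 1, folds=folds))
    return plans


def cv_predict(p: AdjustedMeans | np.ndarray, K: np.ndarray,
               plans: list[FoldPlan]) -> CVPredictions:
    """Held-out GBLUP predictions for every replicate of the plan.

    ``K`` is the (unscaled) genomic covariance structure Z Z'.  For each
    fold the model is refit on the training genotypes only, so a held-out
    genotype's own phenotype never enters its prediction.
    """
    y = p.p if isinstance(p, AdjustedMeans) else np.asarray(p, dtype=float)
    n = y.size
    k = plans[0].n_folds
    preds = np.full((len(plans), n), np.nan)
    conv = np.zeros((len(plans), k), dtype=bool)
    bound = np.zeros((len(plans), k), dtype=bool)
    model = BLUPModel(kernel="precomputed", residual="iid")
    for i, plan in enumerate(plans):
        for f in range(k):
            val = plan.folds == f
            tr = ~val
            fit = model.fit(K[np.ix_(tr, tr)], y[tr])
            conv[i, f] = fit.converged_
            bound[i, f] = fit.boundary_
            if fit.converged_:
                preds[i, val] = fit.predict_genetic_effects(
                    K[np.ix_(val, tr)])
    return CVPredictions(predictions=preds, fold_converged=conv,
                         fold_boundary=bound)


def _replicate_correlations(cvp: CVPredictions, y: np.ndarray):
    from .accuracy import pearson
    rs = []
    for i in range(cvp.n_replicates):
        if not cvp.fold_converged[i].all():
            rs.append(np.nan)
            continue
        rs.append(pearson(cvp.predictions[i], y))
    return np.array(rs)


def cv_predictive_ability(cvp: CVPredictions,
                          p: AdjustedMeans | np.ndarray):
    """Mean per-replicate correlation of held-out predictions with the
    adjusted means.

    Returns ``(mean_r, n_incomputable, per_replicate_r)``; replicates whose
    training fits failed or whose predictions are constant are excluded and
    counted.  ``mean_r`` is nan when no replicate is computable.
    """
    y = p.p if isinstance(p, AdjustedMeans) else np.asarray(p, dtype=float)
    rs = _replicate_correlations(cvp, y)
    ok = np.isfinite(rs)
    mean_r = float(rs[ok].mean()) if ok.any() else np.nan
    return mean_r, int((~ok).sum()), rs
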