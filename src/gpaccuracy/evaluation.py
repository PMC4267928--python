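"""Study orchestration: paired clean/contaminated runs and their summaries.

For every simulated dataset the full analysis chain is run twice — once on
the clean data and once on the twin contaminated with a single outlying
plot — and each of the seven methods' heritability and accuracy estimates
is recorded with its status flags.  Deviations from the per-dataset
simulated truth are summarized as mean deviations (MD) with standard
errors, flag counts (undershoot, overshoot, non-convergence, zero
heritability, zero genetic variance) and pairwise method comparisons.

Scenarios that share a base-data group (same genotype count and marker
variance) regenerate bit-identical clean datasets from the same master
seed, so contaminated runs differing only in the outlier multiplier are
directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import (GenomicModel, accuracy_m5, accuracy_m6, accuracy_m7,
                       heritability_m1, heritability_m2, heritability_m3,
                       heritability_m4, indirect_accuracy, pearson,
                       true_accuracy)
from .config import ScenarioConfig
from .cv import cv_predict, make_cv_folds
from .models import BLUPModel
from .simulate import (AlphaDesign, MarkerMatrix, TrialData,
                       generate_alpha_design, inject_outlier,
                       simulate_breeding_values, simulate_marker_matrix,
                       simulate_trial)
from .twostage import stage1_adjusted_means

logger = logging.getLogger(__name__)

__all__ = [
    "MethodEstimates", "DatasetResult", "analyze_dataset", "run_scenario",
    "mean_deviation", "count_flags", "compare_methods", "summarize",
    "results_to_frame", "write_report", "scenario_markers",
    "zero_heritability_count",
]

HERITABILITY_METHODS = (1, 2, 3, 4, 5)
ACCURACY_METHODS = (1, 2, 3, 4, 5, 6, 7)
CV_METHODS = (1, 2, 3, 4, 6)

SCHEMA_HEADER = "# gpaccuracy results schema v1"


@dataclass
class MethodEstimates:
    """All per-dataset estimates and flags for one analysis condition."""

    H2: dict[int, float]
    acc: dict[int, float]
    r_gp: float
    flags: dict[int, frozenset[str]]
    variance_components: dict[str, float] = field(default_factory=dict)
    n_cv_nonconverged_reps: int = 0
    n_cv_zero_variance_reps: int = 0
    n_cv_boundary_folds: int = 0
    ghat: np.ndarray | None = None   # full-data genomic BLUPs


@dataclass
class DatasetResult:
    """Paired clean/contaminated estimates for one simulated dataset."""

    scenario_id: int
    dataset_index: int
    true_accuracy: float
    true_heritability: float
    clean: MethodEstimates
    contaminated: MethodEstimates
    outlier_plot: int = -1
    outlier_shift: float = 0.0


def _seed(config: ScenarioConfig, *key: int) -> np.random.SeedSequence:
    vm = int(round(config.marker_variance * 1e9))
    return np.random.SeedSequence(
        entropy=config.seed,
        spawn_key=(config.n_genotypes, config.n_markers, vm) + key)


def scenario_markers(config: ScenarioConfig) -> MarkerMatrix:
    """The scenario group's fixed marker panel (shared by all datasets)."""
    return simulate_marker_matrix(
        config.n_genotypes, config.n_markers,
        seed=np.random.default_rng(_seed(config, 0)))


def simulate_scenario_dataset(config: ScenarioConfig, markers: MarkerMatrix,
                              j: int) -> tuple[TrialData, TrialData | None]:
    """Clean dataset j of the scenario's group, plus its contaminated twin
    (None when the scenario is uncontaminated)."""
    rng = lambda s: np.random.default_rng(_seed(config, 1, j, s))
    truth = simulate_breeding_values(markers, config.marker_variance,
                                     seed=rng(0))
    design = generate_alpha_design(config.n_genotypes, config.n_replicates,
                                   config.block_size, seed=rng(1))
    trial = simulate_trial(design, truth,
                           block_variance=config.block_variance,
                           error_variance=config.error_variance,
                           seed=rng(2))
    if config.outlier_multiplier == 0:
        return trial, None
    contaminated = inject_outlier(trial, config.outlier_multiplier,
                                  config.error_sd, seed=rng(3))
    return trial, contaminated


def true_heritability(design: AlphaDesign, K: np.ndarray,
                      marker_variance: float, block_variance: float,
                      error_variance: float) -> float:
    """Method-4 heritability at the true simulating covariances.

    G = Z Z' sigma_u2; R is the exact variance matrix of the genotype
    BLUEs implied by the realized design and the true block and error
    variances.
    """
    n, r = design.n_genotypes, design.n_replicates
    n_obs = design.n_plots
    X = np.zeros((n_obs, n + r - 1))
    X[np.arange(n_obs), design.genotype] = 1.0
    for k in range(1, r):
        X[design.replicate == k, n + k - 1] = 1.0
    Zb = np.zeros((n_obs, r * design.blocks_per_replicate))
    Zb[np.arange(n_obs),
       design.replicate * design.blocks_per_replicate + design.block] = 1.0
    V = block_variance * (Zb @ Zb.T) + error_variance * np.eye(n_obs)
    XtVi = np.linalg.solve(V, X).T
    R_true = np.linalg.inv(XtVi @ X)[:n, :n]
    model = GenomicModel(G=marker_variance * K, R=R_true)
    return heritability_m4(model)


def analyze_dataset(trial: TrialData, K: np.ndarray, cv_seed,
                    n_replicates: int = 2, cv_folds: int = 3,
                    cv_reps: int = 5) -> MethodEstimates:
    """Run the full seven-method analysis chain on one dataset.

    ``K`` is the unscaled genomic structure Z Z'; ``cv_seed`` fixes the CV
    partitions so clean and contaminated twins share them.
    """
    n = trial.n_genotypes
    H2 = {m: np.nan for m in HERITABILITY_METHODS}
    acc = {m: np.nan for m in ACCURACY_METHODS}
    flags: dict[int, set[str]] = {m: set() for m in ACCURACY_METHODS}
    vc: dict[str, float] = {}

    s1 = stage1_adjusted_means(trial)
    vc["sigma_b2_plot"] = s1.sigma_b2
    vc["sigma_e2_plot"] = s1.sigma_e2_plot
    vc["vbar_blue"] = s1.vbar
    if not s1.converged:
        for m in ACCURACY_METHODS:
            flags[m] |= {"nonconverged", "not_computable"}
        return MethodEstimates(H2, acc, np.nan,
                               {m: frozenset(f) for m, f in flags.items()},
                               vc)

    # independent-genotype stage-2 fit: sigma_g2 for methods 1-3
    ind = BLUPModel(kernel="identity", residual="fixed").fit(
        None, s1.p, R=s1.vcov)
    vc["sigma_g2_independent"] = ind.sigma_g2_
    if not ind.converged_:
        for m in (1, 2, 3):
            flags[m].add("nonconverged")
    elif ind.boundary_ or ind.sigma_g2_ <= 0:
        for m in (1, 2, 3):
            flags[m].add("zero_heritability")
        H2[1] = H2[2] = 0.0
    else:
        H2[1] = heritability_m1(ind.sigma_g2_, s1.sigma_e2_plot, n_replicates)
        H2[2] = heritability_m2(ind.sigma_g2_, s1.vbar)
        H2[3] = heritability_m3(ind.sigma_g2_, ind.vbar_blup_)
        if not 0.0 <= H2[3] <= 1.0:
            flags[3].add("out_of_range")
        vc["vbar_blup_independent"] = ind.vbar_blup_

    # genomic stage-2 fit: methods 4-7
    gen = BLUPModel(kernel="precomputed", residual="iid").fit(K, s1.p)
    vc["sigma_u2_genomic"] = gen.sigma_g2_
    vc["sigma_e2_genomic"] = gen.sigma_e2_
    ghat = gen.blup_ if gen.converged_ else None
    model = None
    if not gen.converged_:
        for m in (4, 5, 6, 7):
            flags[m].add("nonconverged")
    elif gen.boundary_ or gen.sigma_g2_ <= 0:
        for m in (4, 5, 6, 7):
            flags[m].add("zero_genetic_variance")
        H2[4] = 0.0
    else:
        model = GenomicModel(G=gen.sigma_g2_ * K,
                             R=gen.sigma_e2_ * np.eye(n))
        H2[4] = heritability_m4(model)
        acc[5] = accuracy_m5(model)
        H2[5] = acc[5] ** 2          # method 5 accuracy is on the H scale
        tiny = 1e-9 * max(1.0, float(np.diag(model.G).max()))
        if np.any(np.diag(gen.pev_) > np.diag(model.G) + tiny):
            flags[7].add("clipped")
        acc[7] = accuracy_m7(model, gen.pev_)

    # cross-validated predictive ability: methods 1-4 and 6
    plans = make_cv_folds(n, cv_folds, cv_reps, seed=cv_seed)
    cvp = cv_predict(s1.p, K, plans)
    rep_r = np.full(cv_reps, np.nan)
    n_nonconv = n_zerovar = 0
    for i in range(cv_reps):
        if not cvp.fold_converged[i].all():
            n_nonconv += 1
            continue
        r_i = pearson(cvp.predictions[i], s1.p)
        if np.isnan(r_i):
            n_zerovar += 1
        rep_r[i] = r_i
    ok = np.isfinite(rep_r)
    r_gp = float(rep_r[ok].mean()) if ok.any() else np.nan
    n_boundary_folds = int(cvp.fold_boundary.sum())
    for m in CV_METHODS:
        if n_nonconv:
            flags[m].add("nonconverged")
        if n_zerovar or n_boundary_folds:
            flags[m].add("zero_genetic_variance")
    for m in (1, 2, 3, 4):
        try:
            acc[m] = indirect_accuracy(r_gp, H2[m])
        except ValueError:
            flags[m].add("not_computable")
    if model is not None and ok.any():
        m6_vals = []
        for i in np.flatnonzero(ok):
            try:
                m6_vals.append(accuracy_m6(cvp.predictions[i], s1.p, model))
            except ValueError:
                pass
        if m6_vals:
            acc[6] = float(np.mean(m6_vals))
        else:
            flags[6].add("not_computable")
    else:
        flags[6].add("not_computable")
    for m in (5, 7):
        if np.isnan(acc[m]):
            flags[m].add("not_computable")

    for m in ACCURACY_METHODS:
        if np.isfinite(acc[m]):
            if acc[m] < 0:
                flags[m].add("undershoot")
            elif acc[m] > 1:
                flags[m].add("overshoot")
    return MethodEstimates(H2, acc, r_gp,
                           {m: frozenset(f) for m, f in flags.items()}, vc,
                           n_cv_nonconverged_reps=n_nonconv,
                           n_cv_zero_variance_reps=n_zerovar,
                           n_cv_boundary_folds=n_boundary_folds,
                           ghat=ghat)


def run_scenario(config: ScenarioConfig, n_datasets: int | None = None,
                 markers: MarkerMatrix | None = None,
                 progress: bool = False) -> list[DatasetResult]:
    """Simulate and analyze all datasets of one scenario, paired."""
    n_ds = config.n_datasets if n_datasets is None else n_datasets
    if markers is None:
        markers = scenario_markers(config)
    K = markers.relationship()
    results = []
    for j in range(n_ds):
        trial, contaminated = simulate_scenario_dataset(config, markers, j)
        cv_seed = _seed(config, 1, j, 4)
        clean_est = analyze_dataset(trial, K, cv_seed,
                                    n_replicates=config.n_replicates)
        # benchmark: correlation of the clean full-data BLUPs with truth
        r_true = (true_accuracy(trial.truth.g, clean_est.ghat)
                  if clean_est.ghat is not None else np.nan)
        h_true = true_heritability(trial.design, K, config.marker_variance,
                                   config.block_variance,
                                   config.error_variance)
        if contaminated is None:
            cont_est = clean_est
            plot, shift = -1, 0.0
        else:
            cont_est = analyze_dataset(contaminated, K, cv_seed,
                                       n_replicates=config.n_replicates)
            plot, shift = contaminated.outlier_record
        results.append(DatasetResult(
            scenario_id=config.scenario_id, dataset_index=j,
            true_accuracy=r_true, true_heritability=h_true,
            clean=clean_est, contaminated=cont_est,
            outlier_plot=plot, outlier_shift=shift))
        if progress and (j + 1) % 25 == 0:
            logger.info("scenario %d: %d/%d datasets analyzed",
                        config.scenario_id, j + 1, n_ds)
    return results


def zero_heritability_count(config: ScenarioConfig,
                            n_datasets: int | None = None,
                            contaminated: bool = True) -> dict[str, int]:
    """Count datasets whose independent-genotype stage-2 REML genetic
    variance sits exactly on the zero boundary.

    When the boundary is hit the heritability used by the indirect methods
    1-3 is zero and their predictive accuracy cannot be computed, the
    failure mode the study tallies for the reduced-variance scenarios.
    Only the stage-1 / independent stage-2 chain is run, so the count is
    affordable at full replication.
    """
    n_ds = config.n_datasets if n_datasets is None else n_datasets
    markers = scenario_markers(config)
    counts = {"n_datasets": n_ds, "zero_heritability": 0, "nonconverged": 0}
    for j in range(n_ds):
        trial, cont = simulate_scenario_dataset(config, markers, j)
        data = cont if (contaminated and cont is not None) else trial
        s1 = stage1_adjusted_means(data)
        if not s1.converged:
            counts["nonconverged"] += 1
            continue
        ind = BLUPModel(kernel="identity", residual="fixed").fit(
            None, s1.p, R=s1.vcov)
        if not ind.converged_:
            counts["nonconverged"] += 1
        elif ind.boundary_ or ind.sigma_g2_ <= 0:
            counts["zero_heritability"] += 1
    return counts


def mean_deviation(estimates, truths):
    """Mean deviation (estimate - truth), its SE and the pair count used.

    Pairs with a non-finite member are excluded; the caller reports the
    exclusion count via ``n_used``.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.size != tru.size:
        raise ValueError("estimates and truths must have equal length")
    dev = est - tru
    dev = dev[np.isfinite(dev)]
    if dev.size == 0:
        raise ValueError("no computable deviations")
    se = float(dev.std(ddof=1) / np.sqrt(dev.size)) if dev.size > 1 else np.nan
    return float(dev.mean()), se, int(dev.size)


def _estimates(result: DatasetResult, condition: str) -> MethodEstimates:
    if condition not in ("clean", "contaminated"):
        raise ValueError("condition must be 'clean' or 'contaminated'")
    return getattr(result, condition)


FLAG_NAMES = ("undershoot", "overshoot", "nonconverged", "zero_heritability",
              "zero_genetic_variance", "not_computable")


def count_flags(results: list[DatasetResult], method: int,
                condition: str = "contaminated") -> dict[str, int]:
    """Flag counts for one method and condition; for the contaminated
    condition the clean-subtracted differences are included as well."""
    counts = {name: 0 for name in FLAG_NAMES}
    for res in results:
        f = _estimates(res, condition).flags[method]
        for name in FLAG_NAMES:
            counts[name] += name in f
    if condition == "contaminated":
        clean = count_flags(results, method, "clean")
        for name in FLAG_NAMES:
            counts[f"delta_{name}"] = counts[name] - clean[name]
    return counts


def _deviation_vector(results, method, condition, metric):
    devs = []
    for res in results:
        est = _estimates(res, condition)
        if metric == "accuracy":
            devs.append(est.acc.get(method, np.nan) - res.true_accuracy)
        else:
            devs.append(est.H2.get(method, np.nan) - res.true_heritability)
    return np.asarray(devs, dtype=float)


def summarize(results: list[DatasetResult]) -> pd.DataFrame:
    """Per method x condition x metric deviation summary with flag counts."""
    rows = []
    if not results:
        return pd.DataFrame(columns=[
            "scenario", "metric", "method", "condition", "md", "se",
            "n_used", "n_excluded", "mean_dev", "sd_dev", "q25", "median",
            "q75", *FLAG_NAMES])
    scenario = results[0].scenario_id
    for metric, methods in (("heritability", HERITABILITY_METHODS),
                            ("accuracy", ACCURACY_METHODS)):
        for method in methods:
            for condition in ("clean", "contaminated"):
                dev = _deviation_vector(results, method, condition, metric)
                ok = np.isfinite(dev)
                counts = {name: 0 for name in FLAG_NAMES}
                for res in results:
                    f = _estimates(res, condition).flags[method]
                    for name in FLAG_NAMES:
                        counts[name] += name in f
                row = dict(scenario=scenario, metric=metric, method=method,
                           condition=condition, n_used=int(ok.sum()),
                           n_excluded=int((~ok).sum()), **counts)
                if ok.any():
                    d = dev[ok]
                    sd = d.std(ddof=1) if d.size > 1 else np.nan
                    row.update(
                        md=d.mean(),
                        se=sd / np.sqrt(d.size) if d.size > 1 else np.nan,
                        mean_dev=d.mean(), sd_dev=sd,
                        q25=np.percentile(d, 25), median=np.median(d),
                        q75=np.percentile(d, 75))
                else:
                    row.update(md=np.nan, se=np.nan, mean_dev=np.nan,
                               sd_dev=np.nan, q25=np.nan, median=np.nan,
                               q75=np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def compare_methods(results: list[DatasetResult], metric: str = "accuracy",
                    condition: str = "contaminated") -> pd.DataFrame:
    """Pairwise Pearson correlations and paired t-tests of the deviations.

    Pairing is by dataset index; datasets where either method is not
    computable are dropped pairwise.  An unadjusted p-value and a
    Bonferroni-adjusted one (over the method pairs) are reported.
    """
    methods = (ACCURACY_METHODS if metric == "accuracy"
               else HERITABILITY_METHODS)
    devs = {m: _deviation_vector(results, m, condition, metric)
            for m in methods}
    rows = []
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i:]]
    n_tests = sum(1 for a, b in pairs if a != b)
    for a, b in pairs:
        ok = np.isfinite(devs[a]) & np.isfinite(devs[b])
        if ok.sum() < 3:
            raise ValueError(
                f"fewer than 3 common computable datasets for pair ({a},{b})")
        da, db = devs[a][ok], devs[b][ok]
        if a == b:
            r, t, p = 1.0, 0.0, 1.0
        else:
            r = pearson(da, db)
            t, p = stats.ttest_rel(da, db)
        rows.append(dict(scenario=results[0].scenario_id, metric=metric,
                         condition=condition, method_a=a, method_b=b,
                         n=int(ok.sum()), pearson_r=r, t_stat=float(t),
                         p_value=float(p),
                         p_bonferroni=min(1.0, float(p) * max(n_tests, 1))))
    return pd.DataFrame(rows)


def results_to_frame(results: list[DatasetResult]) -> pd.DataFrame:
    """Long per-dataset table: one row per dataset x condition x method."""
    rows = []
    for res in results:
        for condition in ("clean", "contaminated"):
            est = _estimates(res, condition)
            for m in ACCURACY_METHODS:
                rows.append(dict(
                    scenario=res.scenario_id, dataset=res.dataset_index,
                    condition=condition, method=m,
                    heritability=est.H2.get(m, np.nan),
                    accuracy=est.acc[m], predictive_ability=est.r_gp,
                    true_accuracy=res.true_accuracy,
                    true_heritability=res.true_heritability,
                    flags="|".join(sorted(est.flags[m])),
                    outlier_plot=res.outlier_plot,
                    outlier_shift=res.outlier_shift))
    cols = ["scenario", "dataset", "condition", "method", "heritability",
            "accuracy", "predictive_ability", "true_accuracy",
            "true_heritability", "flags", "outlier_plot", "outlier_shift"]
    return pd.DataFrame(rows, columns=cols)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_report(results: list[DatasetResult], outdir,
                 plots: bool = False) -> dict[str, Path]:
    """Write the per-dataset, summary and flag-count tables to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    per_dataset = results_to_frame(results)
    paths["per_dataset"] = outdir / "per_dataset.tsv"
    _write_tsv(per_dataset, paths["per_dataset"])
    paths["summary"] = outdir / "summary.tsv"
    _write_tsv(summarize(results), paths["summary"])
    flag_rows = []
    for condition in ("clean", "contaminated"):
        for m in ACCURACY_METHODS:
            if results:
                flag_rows.append(dict(scenario=results[0].scenario_id,
                                      condition=condition, method=m,
                                      **count_flags(results, m, condition)))
    flag_cols = (["scenario", "condition", "method"] + list(FLAG_NAMES)
                 + [f"delta_{n}" for n in FLAG_NAMES])
    paths["flag_counts"] = outdir / "flag_counts.tsv"
    _write_tsv(pd.DataFrame(flag_rows, columns=flag_cols),
               paths["flag_counts"])
    if plots and results:
        paths["md_plot"] = _md_barplot(results, outdir / "md_accuracy.png")
    return paths


def _md_barplot(results, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    summary = summarize(results)
    acc = summary[summary.metric == "accuracy"]
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.38
    for off, (cond, color) in enumerate(
            [("clean", "forestgreen"), ("contaminated", "white")]):
        sub = acc[acc.condition == cond]
        ax.bar(sub.method + (off - 0.5) * width, sub.md, width,
               yerr=sub.se, label=cond, color=color,
               edgecolor="black")
    ax.set_xlabel("method")
    ax.set_ylabel("mean deviation of estimated accuracy")
    ax.axhline(0, color="black", lw=0.8)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
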