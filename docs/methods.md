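# Methods

## The problem

When breeders evaluate genomic prediction, the quantity they care about is
the *predictive accuracy* `r(g, ĝ)` — the correlation between true and
predicted breeding values. In real data `g` is unknown, so accuracy must be
estimated, either indirectly (cross-validated predictive ability divided by
the square root of an estimated heritability) or directly from the fitted
covariance structures. Field phenotypes also contain outliers that data
cleaning does not reliably remove. This package implements a simulation
study that quantifies how a single outlying plot observation perturbs seven
accuracy estimators and five heritability measures under the
RR-BLUP/GBLUP model, benchmarked against the simulated truth.

## Data-generating model

Plot yields follow a resolvable incomplete-block (alpha) design,

    y_ijk = mu + gamma_k + b_jk + g_i + e_ijk,

with fixed replicate effects `gamma_k`, block-within-replicate effects
`b_jk ~ N(0, sigma_b^2)`, plot errors `e_ijk ~ N(0, sigma_e^2)` and
breeding values `g = Z u`, `u ~ N(0, I sigma_u^2)`, where `Z` is the
`n x q` marker matrix coded `{-1, 0, 1}` (doubled-haploid mode, the
default, produces only +/-1). Hence `Var(g) = G = Z Z' sigma_u^2`.

Ten preset scenarios cross two panel sizes (177 genotypes x 275 markers
with plot error variance 48.6728; 698 x 11,646 with 53.8715), two
marker-effect variances per size (0.2019 and 0.2019/10; 0.005892 and
0.005892/10) and outlier multipliers k in {5, 8, 10} (small panel) or
{5, 10} (large). An outlier adds exactly `k * sigma_e` (sigma_e = 6.977 or
7.340) to one uniformly chosen plot; the contaminated dataset shares every
other draw with its clean twin, so paired deviations isolate the outlier
effect. Scenarios differing only in k reuse bit-identical base datasets
(and the same contaminated plot), driven by a seed hierarchy keyed on
(master seed, panel size, marker count, marker variance, dataset index,
stream).

Parameter choices where the study conditions leave a gap:

* **Block variance.** The trial estimates behind the original block
  variances are not published; the presets use `sigma_b^2 = sigma_e^2 / 4`,
  a typical block-to-plot variance ratio for alpha designs of this size.
  It is a configurable stand-in, and the full-scale boundary-count result
  should be read with that uncertainty in mind.
* **Marker panel.** One fixed panel per scenario group (mimicking a real,
  fixed genotyping panel), allele frequencies uniform on [0.05, 0.5]
  (panels of this kind are MAF-filtered), markers independent. Real
  biparental DH panels have strong linkage disequilibrium and kinship;
  independence is deliberate (structure among markers is out of scope) and
  its main visible consequence is discussed under Limitations.
* **Replicate effects and the general mean** default to zero: every
  estimator below is invariant to location shifts.
* **Design layout.** ceil(n / 18) incomplete blocks per replicate with
  sizes as equal as possible (177 -> 7 blocks of 18 + 3 of 17; 698 -> 35 of
  18 + 4 of 17), re-randomized independently per replicate and dataset.
  Equalizing block sizes (rather than one short remainder block) keeps the
  design balance property that block sizes differ by at most one.

## Two-stage analysis

**Stage 1** fits genotype (fixed) + replicate (fixed) + block (random) to
the plot data by REML and returns the genotype BLUEs `p` ("adjusted
means"), their variance matrix, and the plot-level components
`(sigma_b^2, sigma_e^2)`.

**Stage 2** fits `p = phi + g + e` with `g` random. Two covariance
structures are used:

* *genomic*: `Var(g) = Z Z' sigma_u^2`, residual `I sigma_e^2`, both
  estimated by REML. This is the GBLUP fit that produces `ĝ`, the
  prediction-error variance (PEV) matrix, and the plug-in `G` and `R` for
  methods 4-7.
* *independent*: `Var(g) = I sigma_g^2`. With an iid residual this model
  is unidentifiable on adjusted means (V would be `(sigma_g^2 +
  sigma_e^2) I` however the total is split), so the residual covariance is
  fixed at the stage-1 variance matrix of the means — the standard
  weighted two-stage approach. Identification then rests entirely on the
  non-uniformity of that matrix, which is weak in a near-balanced alpha
  design; this is precisely why reduced-variance scenarios produce many
  zero-variance boundary estimates, the failure mode the study counts.

## REML engine

Both stages are instances of one family: a single random term plus a
residual. For `V = sigma_g^2 Z K Z' + sigma_e^2 I` the restricted
likelihood is profiled over the ratio `lambda = sigma_g^2 / sigma_e^2`
after one symmetric eigendecomposition of `Z K Z'`; `sigma_e^2` has a
closed-form update. For `V = sigma_g^2 K + R` with `R` known, the data are
whitened by the Cholesky factor of `R` and the criterion is maximized over
`sigma_g^2` directly. The scalar search is a 29-33 point log-spaced grid
scan followed by bounded Brent refinement (xatol 1e-9 on the log scale);
the boundary `sigma_g^2 = 0` is chosen whenever its criterion value is
within 1e-8 (relative) of the best interior value. Boundary and
non-convergence (non-finite criterion, singular system, constant response)
are flagged outcomes, never exceptions, because the study counts them.
This profiled grid-plus-Brent search is deliberately conservative; it
essentially cannot fail to converge on well-posed inputs, so
non-convergence counts are expected to be far lower than those of
Newton-type solvers, and are reported rather than compared.

BLUEs, BLUPs, their covariance and the PEV matrix are computed at the
REML estimates from the V-inverse form of Henderson's mixed-model
equations (verified against a literal coefficient-matrix inverse in the
tests). No uncertainty in the variance components is propagated — the
estimates are plugged in.

## The seven methods

With `vbar` = mean variance of a difference of two adjusted means, and
`vbar_BLUP` the analogue from the PEV matrix:

| method | heritability | accuracy |
|---|---|---|
| 1 | `sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)` | `r_gp / H_m1` |
| 2 | `sigma_g^2 / (sigma_g^2 + vbar / 2)` | `r_gp / H_m2` |
| 3 | `1 - vbar_BLUP / (2 sigma_g^2)` | `r_gp / H_m3` |
| 4 | `tr(Pu G) / tr(V Pu)` | `r_gp / H_m4` |
| 5 | `H_m5^2` | `tr(Pu C G) / sqrt(tr(Pu G) tr(C' Pu C V))` |
| 6 | — | `s_ghat,p / sqrt(s_ghat^2 tr(Pu G))` |
| 7 | — | `sqrt(mean_i (G_ii - PEV_ii) / G_ii)` |

where `Pu = (I - J/n) / (n-1)` (so `tr(Pu Sigma)` is the expected sample
variance under covariance Sigma), `Q` sweeps out the GLS intercept and
`C = G V^-1 Q`. Methods 1-3 take `sigma_g^2` from the independent stage-2
fit; method 1's `sigma_e^2` is the stage-1 plot error variance and `r` the
replicate count. Methods 4-7 plug in the genomic-fit `G` and `R`. Method
5's statistic is on the correlation (H, not H^2) scale, so its
heritability entry is the square. Method 7 clips negative numerical
reliabilities to zero and flags the clip.

`r_gp` is the cross-validated predictive ability: five independent 3-fold
partitions, the genomic model refit by REML within every training set,
held-out genotypes predicted through their genomic covariance with the
training set, one correlation per replicate over all genotypes, and the
arithmetic mean over the computable replicates (up to 15 per dataset).
Heritability for the indirect ratio is estimated once from the full
dataset, not per fold.

Per dataset and condition each method carries flags: `undershoot`
(accuracy < 0), `overshoot` (> 1), `nonconverged` (any required fit or CV
training fit failed), `zero_heritability` (independent-fit boundary, so
methods 1-3 have no usable denominator), `zero_genetic_variance`
(genomic-fit or CV-training boundary) and `not_computable`. Datasets are
excluded from summaries per method, not listwise, with counts reported.

## Benchmarks and evaluation statistics

* *True accuracy* of dataset j: Pearson correlation between the simulated
  `g` and the clean full-data GBLUP `ĝ`.
* *True heritability* of dataset j: method 4 evaluated at the true
  covariances — `G = Z Z' sigma_u^2` and `R` the exact variance matrix of
  the genotype BLUEs implied by the realized design and the true
  `(sigma_b^2, sigma_e^2)`.
* For every method x scenario x condition: the mean deviation MD of the
  estimates from the per-dataset benchmark, its standard error,
  descriptive statistics, and the flag counts with contaminated-minus-
  clean differences.
* Method pairs are compared by Pearson correlation of their deviations and
  a paired t-test by dataset index (unadjusted p plus a Bonferroni
  column; no simulation-based multiplicity adjustment).

## Problem sizes used

Closed-form identities are verified at n <= 8 against brute-force oracles.
The Monte-Carlo consistency check of method 5 uses n = 60 with 2000
simulated phenotype vectors; stage-2 parameter recovery uses 500 datasets
at n = 177. The qualitative study reproduction runs scenarios 1-6 at 100
datasets each; the full-scale boundary count runs scenario 6 at 1000
datasets through the stage-1 / independent-stage-2 chain only. These sizes
were chosen so the whole suite runs on a single CPU in well under half an
hour while keeping Monte-Carlo error far below the effect sizes examined.

## Limitations

* The marker panel has no linkage disequilibrium or kinship structure, so
  held-out genotypes are nearly unrelated to their training sets and
  cross-validated predictive ability is much lower than in real biparental
  DH panels. The CV-based indirect methods therefore show a large negative
  deviation from the benchmark even on clean data. The *outlier-induced
  changes* — the study's object — are unaffected by this level shift, but
  absolute MD values for methods 1-4 and 6 should not be compared with
  values obtained on structured panels.
* Block variances are stand-ins (see above), so counted rates of boundary
  events match the original study's printed counts only in magnitude.
* Non-convergence is solver-specific; a robust scalar profile search makes
  it rare by design.
* Methods 5 and 7 are computed for phenotyped genotypes only; extension to
  unphenotyped genotypes is out of scope.
* `E(r) ≈ H_m5` is a ratio-of-expectations approximation; its O(1/n)
  Jensen bias is visible below n ≈ 40 (the tests check the exact moment
  identities separately from the approximate consistency).
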