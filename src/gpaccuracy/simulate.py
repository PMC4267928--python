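"""Synthetic trial generator: markers, breeding values, alpha-design yields.

Stands in for the proprietary maize trials the study conditions are modelled
on. Markers are biallelic SNPs coded {-1, 0, 1} (doubled-haploid mode, the
default, restricts codes to +/-1); true breeding values follow the ridge
regression / GBLUP model g = Z u with u ~ N(0, I sigma_u2); plot yields
follow a resolvable incomplete-block (alpha) design

    y_ijk = mu + gamma_k + b_jk + g_i + e_ijk

with fixed replicate effects gamma_k, random block effects
b_jk ~ N(0, sigma_b2) and plot errors e_ijk ~ N(0, sigma_e2). An outlier is
a single randomly chosen plot whose yield is shifted by exactly
k * sigma_e; the contaminated copy shares every other number with its clean
twin so paired comparisons isolate the outlier's effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix", "BreedingValues", "AlphaDesign", "TrialData",
    "simulate_marker_matrix", "simulate_breeding_values",
    "generate_alpha_design", "simulate_trial", "inject_outlier",
]


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from an int seed, SeedSequence or Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MarkerMatrix:
    """Marker panel: n genotypes x q biallelic SNPs coded {-1, 0, 1}."""

    genotype_ids: np.ndarray
    Z: np.ndarray
    allele_frequencies: np.ndarray

    @property
    def n_genotypes(self) -> int:
        return self.Z.shape[0]

    @property
    def n_markers(self) -> int:
        return self.Z.shape[1]

    def relationship(self, marker_variance: float = 1.0) -> np.ndarray:
        """Genomic covariance G = Z Z' * sigma_u2."""
        Z = self.Z.astype(float)
        return (Z @ Z.T) * float(marker_variance)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Z,
                          columns=[f"m{k + 1}" for k in range(self.n_markers)])
        df.insert(0, "genotype", self.genotype_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        ids = df["genotype"].to_numpy()
        Z = df.drop(columns="genotype").to_numpy(dtype=np.int8)
        freq = np.asarray((Z == 1).mean(axis=0) + 0.5 * (Z == 0).mean(axis=0))
        return cls(genotype_ids=ids, Z=Z, allele_frequencies=freq)


@dataclass
class BreedingValues:
    """Marker effects u and the true breeding values g = Z u (exactly)."""

    u: np.ndarray
    g: np.ndarray


@dataclass
class AlphaDesign:
    """Resolvable incomplete-block layout.

    Arrays are plot-indexed and share length n_genotypes * n_replicates;
    every genotype occurs exactly once per replicate, blocks are nested
    within replicates and their sizes differ by at most one.
    """

    genotype: np.ndarray   # genotype index per plot
    replicate: np.ndarray  # replicate index per plot (0-based)
    block: np.ndarray      # block index within replicate (0-based)
    n_genotypes: int
    n_replicates: int
    blocks_per_replicate: int

    @property
    def n_plots(self) -> int:
        return self.genotype.size


@dataclass
class TrialData:
    """Plot records plus every stored model component.

    The identity y = mu + gamma[replicate] + block_effect + g[genotype]
    + error (+ outlier shift on one plot, if any) holds exactly for the
    stored arrays, so simulated datasets are fully auditable.
    """

    design: AlphaDesign
    yields: np.ndarray
    mu: float
    replicate_effects: np.ndarray          # gamma_k, fixed
    block_effects: np.ndarray              # (n_replicates, blocks_per_replicate)
    plot_errors: np.ndarray
    truth: BreedingValues
    outlier_record: tuple[int, float] | None = None

    @property
    def n_genotypes(self) -> int:
        return self.design.n_genotypes

    def reconstructed_yields(self) -> np.ndarray:
        d = self.design
        y = (self.mu + self.replicate_effects[d.replicate]
             + self.block_effects[d.replicate, d.block]
             + self.truth.g[d.genotype] + self.plot_errors)
        if self.outlier_record is not None:
            idx, shift = self.outlier_record
            y = y.copy()
            y[idx] += shift
        return y

    def to_frame(self) -> pd.DataFrame:
        d = self.design
        return pd.DataFrame({
            "genotype": d.genotype,
            "replicate": d.replicate + 1,
            "block": d.block + 1,
            "plot": np.arange(d.n_plots) + 1,
            "yield": self.yields,
        })


def simulate_marker_matrix(n: int, q: int, maf_low: float = 0.05,
                           maf_high: float = 0.5, dh_mode: bool = True,
                           seed=None) -> MarkerMatrix:
    """Draw an n x q marker panel with per-marker allele frequencies
    uniform on [maf_low, maf_high].

    In doubled-haploid mode every genotype is homozygous, so codes are
    +/-1 with P(+1) equal to the marker's allele frequency; otherwise the
    two alleles are drawn independently and heterozygotes are coded 0.
    Constant (monomorphic) columns are redrawn so every marker segregates.
    """
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if n < 1 or q < 1:
        raise ValueError("n and q must be >= 1")
    rng = as_rng(seed)
    freq = rng.uniform(maf_low, maf_high, size=q)

    def draw(cols_freq, size):
        if dh_mode:
            return np.where(rng.random((size, cols_freq.size)) < cols_freq,
                            1, -1).astype(np.int8)
        a1 = rng.random((size, cols_freq.size)) < cols_freq
        a2 = rng.random((size, cols_freq.size)) < cols_freq
        return (a1.astype(np.int8) + a2.astype(np.int8) - 1)

    Z = draw(freq, n)
    if n > 1:
        for _ in range(1000):
            const = np.all(Z == Z[0], axis=0)
            if not const.any():
                break
            freq[const] = rng.uniform(maf_low, maf_high, size=const.sum())
            Z[:, const] = draw(freq[const], n)
    ids = np.array([f"G{i + 1:04d}" for i in range(n)])
    return MarkerMatrix(genotype_ids=ids, Z=Z, allele_frequencies=freq)


def simulate_breeding_values(markers: MarkerMatrix, marker_variance: float,
                             seed=None) -> BreedingValues:
    """Draw u ~ iid N(0, sigma_u2) and return g = Z u."""
    if marker_variance < 0:
        raise ValueError("marker variance must be >= 0")
    rng = as_rng(seed)
    u = rng.normal(0.0, np.sqrt(marker_variance), size=markers.n_markers)
    return BreedingValues(u=u, g=markers.Z @ u)


def generate_alpha_design(n: int, r: int = 2, block_size: int = 18,
                          seed=None) -> AlphaDesign:
    """Randomized resolvable incomplete-block layout.

    ceil(n / block_size) blocks per replicate with sizes as equal as
    possible (differing by at most one plot); the genotype-to-block
    allocation is re-randomized independently in every replicate.
    """
    if block_size > n:
        raise ValueError("block_size cannot exceed the number of genotypes")
    if block_size < 2 or r < 1:
        raise ValueError("require block_size >= 2 and r >= 1")
    rng = as_rng(seed)
    n_blocks = -(-n // block_size)
    base, extra = divmod(n, n_blocks)
    sizes = np.array([base + 1] * extra + [base] * (n_blocks - extra))
    block_of_pos = np.repeat(np.arange(n_blocks), sizes)
    genotype, replicate, block = [], [], []
    for k in range(r):
        perm = rng.permutation(n)
        genotype.append(perm)
        replicate.append(np.full(n, k))
        block.append(block_of_pos)
    return AlphaDesign(
        genotype=np.concatenate(genotype),
        replicate=np.concatenate(replicate),
        block=np.concatenate(block),
        n_genotypes=n, n_replicates=r, blocks_per_replicate=n_blocks)


def simulate_trial(design: AlphaDesign, truth: BreedingValues,
                   mu: float = 0.0, replicate_effects=None,
                   block_variance: float = 0.0, error_variance: float = 0.0,
                   seed=None) -> TrialData:
    """Simulate plot yields under the alpha-design model."""
    if block_variance < 0 or error_variance < 0:
        raise ValueError("variances must be >= 0")
    rng = as_rng(seed)
    gamma = (np.zeros(design.n_replicates) if replicate_effects is None
             else np.asarray(replicate_effects, dtype=float))
    if gamma.size != design.n_replicates:
        raise ValueError("one replicate effect per replicate is required")
    b = rng.normal(0.0, np.sqrt(block_variance),
                   size=(design.n_replicates, design.blocks_per_replicate))
    e = rng.normal(0.0, np.sqrt(error_variance), size=design.n_plots)
    y = (mu + gamma[design.replicate] + b[design.replicate, design.block]
         + truth.g[design.genotype] + e)
    return TrialData(design=design, yields=y, mu=mu, replicate_effects=gamma,
                     block_effects=b, plot_errors=e, truth=truth)


def inject_outlier(trial: TrialData, k: float, error_sd: float,
                   seed=None) -> TrialData:
    """Return a contaminated twin: one random plot's yield += k * error_sd.

    Every other number (design, effects, errors, remaining yields) is
    shared bit-for-bit with the clean input.
    """
    if k <= 0:
        raise ValueError("outlier multiplier must be > 0")
    if trial.outlier_record is not None:
        raise ValueError("trial is already contaminated")
    rng = as_rng(seed)
    idx = int(rng.integers(trial.design.n_plots))
    shift = float(k) * float(error_sd)
    y = trial.yields.copy()
    y[idx] += shift
    return replace(trial, yields=y, outlier_record=(idx, shift))
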