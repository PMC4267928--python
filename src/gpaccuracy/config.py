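"""Scenario configurations for the outlier-robustness simulation study.

Ten preset scenarios cross two trial sizes (177 genotypes x 275 markers;
698 genotypes x 11,646 markers), two marker-effect variances per size (the
larger one and the same divided by ten), and outlier magnitudes of 5, 8 or
10 residual-error standard deviations added to a single plot observation.
Scenarios that differ only in the outlier multiplier share the same base
datasets (``group_id``), so outlier effects can be isolated by pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

__all__ = ["ScenarioConfig", "make_scenario_configs", "load_config", "save_config"]

#: error variances used to simulate plot errors; their square roots are the
#: SDs whose multiples define the injected outliers.
SMALL_ERROR_VARIANCE = 48.6728
LARGE_ERROR_VARIANCE = 53.8715
SMALL_ERROR_SD = 6.977
LARGE_ERROR_SD = 7.340

SMALL_MARKER_VARIANCE = 0.2019
LARGE_MARKER_VARIANCE = 0.005892


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (sizes, variances, outlier magnitude).

    ``error_sd`` is the SD used to scale injected outliers (k * error_sd);
    ``error_variance`` is the variance used to draw the plot errors. They
    agree to floating tolerance but are carried separately because the
    study states both to different printed precisions.
    """

    scenario_id: int
    n_genotypes: int
    n_markers: int
    marker_variance: float
    error_variance: float
    error_sd: float
    block_variance: float
    n_replicates: int = 2
    block_size: int = 18
    outlier_multiplier: float = 0.0
    n_datasets: int = 1000
    seed: int = 20140

    def __post_init__(self) -> None:
        if self.marker_variance < 0:
            raise ValueError("marker_variance must be >= 0")
        if self.error_variance <= 0:
            raise ValueError("error_variance must be > 0")
        if self.block_variance < 0:
            raise ValueError("block_variance must be >= 0")
        if not math.isclose(self.error_sd, math.sqrt(self.error_variance),
                            rel_tol=5e-4):
            raise ValueError(
                f"error_sd {self.error_sd} is not the square root of "
                f"error_variance {self.error_variance}")
        if self.outlier_multiplier not in (0, 5, 8, 10):
            raise ValueError("outlier_multiplier must be one of 0, 5, 8, 10")

    @property
    def outlier_shift(self) -> float:
        """Absolute yield shift applied to the contaminated plot."""
        return self.outlier_multiplier * self.error_sd

    @property
    def group_id(self) -> str:
        """Scenarios with equal group_id share identical base datasets."""
        return f"n{self.n_genotypes}_su{self.marker_variance:.6g}"

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def _preset(sid: int, n: int, q: int, su2: float, se2: float, sd: float,
            k: float, **kw) -> ScenarioConfig:
    # block variance default: a quarter of the plot error variance (stand-in
    # for the unavailable trial estimates; see docs/methods.md)
    return ScenarioConfig(
        scenario_id=sid, n_genotypes=n, n_markers=q, marker_variance=su2,
        error_variance=se2, error_sd=sd, block_variance=se2 / 4.0,
        outlier_multiplier=k, **kw)


def make_scenario_configs(n_datasets: int = 1000,
                          seed: int = 20140) -> list[ScenarioConfig]:
    """Return the ten preset scenarios of the study.

    Scenarios 1-6 use the small trial (177 genotypes, 275 markers, error
    variance 48.6728); 7-10 the large trial (698 genotypes, 11,646 markers,
    error variance 53.8715). Marker-effect variances are 0.2019 (1-3),
    0.2019/10 (4-6), 0.005892 (7-8) and 0.005892/10 (9-10); outlier
    multipliers are 5/8/10 (small) and 5/10 (large).
    """
    kw = dict(n_datasets=n_datasets, seed=seed)
    s, l = SMALL_ERROR_VARIANCE, LARGE_ERROR_VARIANCE
    ssd, lsd = SMALL_ERROR_SD, LARGE_ERROR_SD
    return [
        _preset(1, 177, 275, SMALL_MARKER_VARIANCE, s, ssd, 5, **kw),
        _preset(2, 177, 275, SMALL_MARKER_VARIANCE, s, ssd, 8, **kw),
        _preset(3, 177, 275, SMALL_MARKER_VARIANCE, s, ssd, 10, **kw),
        _preset(4, 177, 275, SMALL_MARKER_VARIANCE / 10, s, ssd, 5, **kw),
        _preset(5, 177, 275, SMALL_MARKER_VARIANCE / 10, s, ssd, 8, **kw),
        _preset(6, 177, 275, SMALL_MARKER_VARIANCE / 10, s, ssd, 10, **kw),
        _preset(7, 698, 11646, LARGE_MARKER_VARIANCE, l, lsd, 5, **kw),
        _preset(8, 698, 11646, LARGE_MARKER_VARIANCE, l, lsd, 10, **kw),
        _preset(9, 698, 11646, LARGE_MARKER_VARIANCE / 10, l, lsd, 5, **kw),
        _preset(10, 698, 11646, LARGE_MARKER_VARIANCE / 10, l, lsd, 10, **kw),
    ]


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config)))


def load_config(path: str | Path, **overrides) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text())
    data.update(overrides)
    return ScenarioConfig(**data)
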