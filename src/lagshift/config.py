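"""Configuration objects for simulation and break detection."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .binning import MAGNITUDE_BINS
from .months import ym_to_index


@dataclass(frozen=True)
class BinEffect:
    """Ground-truth multiplicative effect of one magnitude bin on an assemblage.

    ``richness`` and ``abundance`` multiply the expected species count and
    the expected total number of individuals; ``evenness_shift`` (>= 0) tilts
    relative abundances toward dominance; ``turnover`` is the fraction of
    species identities replaced from the study pool.
    """

    richness: float = 1.0
    abundance: float = 1.0
    evenness_shift: float = 0.0
    turnover: float = 0.0


def default_effect_table() -> dict:
    """Per-magnitude-bin effects used by the synthetic landscape generator.

    The grand means implied by these defaults echo the scale of effects
    reported for abrupt land change on local assemblages (a few percent fewer
    species and individuals overall, ~15% fewer species beyond a 50% loss in
    EVI, and strongly reduced compositional similarity in the severest bin).
    """
    return {
        "loss>50%": BinEffect(0.84, 0.89, 0.30, 0.35),
        "loss 25-50%": BinEffect(0.92, 0.95, 0.15, 0.20),
        "loss <=25%": BinEffect(0.97, 0.98, 0.05, 0.10),
        "gain <=25%": BinEffect(0.985, 0.99, 0.02, 0.05),
        "gain 25-50%": BinEffect(0.95, 0.97, 0.04, 0.08),
        "gain>50%": BinEffect(0.89, 0.95, 0.05, 0.12),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic landscape generator.

    Defaults describe a moderately sized multi-study field campaign: 40
    studies of 30 sites each, 18-year monthly EVI series (1998-2015) with a
    two-harmonic seasonal cycle of amplitude 0.15 EVI units and observation
    noise of 0.03, and half of the sites subject to a single abrupt change.
    """

    n_studies: int = 40
    sites_per_study: int = 30
    prop_changed_sites: float = 0.5

    series_start: str = "1998-01"
    series_end: str = "2015-12"
    obs_per_month: int = 3

    baseline_evi_range: tuple = (0.30, 0.60)
    base_trend_range: tuple = (-3e-4, 3e-4)
    seasonal_amplitude: float = 0.15
    noise_sd: float = 0.03
    cloud_fraction: float = 0.15
    outlier_rate: float = 0.02
    missing_block_rate: float = 0.30
    missing_block_length_months: int = 6

    break_time_range: tuple = ("2000-01", "2013-12")
    magnitude_range: tuple = (-0.6, 0.6)
    trend_diff_range: tuple = (-0.004, 0.004)

    effect_table: dict = field(default_factory=default_effect_table)

    species_pool_size: int = 120
    lognormal_sd: float = 1.0
    occupancy: float = 0.30
    mean_abundance: float = 8.0
    occurrence_study_fraction: float = 0.2

    mle_missing_rate: float = 0.18
    sample_start_range: tuple = ("2010-01", "2015-12")

    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> "SimulationConfig":
        def _fail(name, msg):
            raise ValueError(f"invalid SimulationConfig.{name}: {msg}")

        for name in ("n_studies", "sites_per_study", "obs_per_month",
                     "species_pool_size", "missing_block_length_months"):
            if int(getattr(self, name)) < 1:
                _fail(name, "must be a positive count")
        for name in ("prop_changed_sites", "cloud_fraction", "outlier_rate",
                     "missing_block_rate", "occupancy",
                     "occurrence_study_fraction", "mle_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                _fail(name, f"fraction {v} outside [0, 1]")
        for name in ("baseline_evi_range", "base_trend_range",
                     "magnitude_range", "trend_diff_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                _fail(name, f"range ({lo}, {hi}) not ordered")
        if ym_to_index(self.series_start) >= ym_to_index(self.series_end):
            _fail("series_start", "must precede series_end")
        b0, b1 = (ym_to_index(x) for x in self.break_time_range)
        if b0 > b1:
            _fail("break_time_range", "range not ordered")
        if not (ym_to_index(self.series_start) <= b0
                and b1 <= ym_to_index(self.series_end)):
            _fail("break_time_range", "must lie inside the series span")
        for b, eff in self.effect_table.items():
            if b not in MAGNITUDE_BINS:
                _fail("effect_table", f"unknown magnitude bin {b!r}")
            if eff.richness <= 0 or eff.abundance <= 0:
                _fail("effect_table", f"non-positive multiplier in bin {b!r}")
            if not 0.0 <= eff.turnover <= 1.0:
                _fail("effect_table", f"turnover outside [0,1] in bin {b!r}")
        if self.noise_sd < 0 or self.seasonal_amplitude < 0:
            _fail("noise_sd", "noise/amplitude must be non-negative")
        if self.lognormal_sd < 0:
            _fail("lognormal_sd", "must be non-negative")
        if self.mean_abundance <= 0:
            _fail("mean_abundance", "must be positive")
        return self

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_table"] = {k: asdict(v) if isinstance(v, BinEffect) else v
                             for k, v in self.effect_table.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "effect_table" in d:
            d["effect_table"] = {
                k: v if isinstance(v, BinEffect) else BinEffect(**v)
                for k, v in d["effect_table"].items()
            }
        for name in ("baseline_evi_range", "base_trend_range", "magnitude_range",
                     "trend_diff_range", "break_time_range", "sample_start_range"):
            if name in d and d[name] is not None:
                d[name] = tuple(d[name])
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class BreakDetectionConfig:
    """Settings of the single-break detector.

    ``h_fraction`` (MOSUM bandwidth and minimum-segment fraction) defaults to
    12 months divided by the series length, i.e. one year of data relative to
    the record; ``k`` is the harmonic order of the seasonal term.
    """

    k: int = 2
    alpha: float = 0.05
    h_fraction: Optional[float] = None  # None -> 12 / series length
    min_segment_months: int = 12
    period_months: int = 12
    require_bic: bool = True
    max_missing_fraction: float = 0.5
    magnitude_from: str = "trend"  # or "full" (trend + seasonal)

    def validate(self) -> "BreakDetectionConfig":
        if self.k < 0:
            raise ValueError("invalid BreakDetectionConfig.k: must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("invalid BreakDetectionConfig.alpha: not in (0,1)")
        if self.h_fraction is not None and not 0 < self.h_fraction < 0.5:
            raise ValueError(
                "invalid BreakDetectionConfig.h_fraction: not in (0, 0.5)")
        if self.min_segment_months < 2 * self.k + 2:
            raise ValueError(
                "invalid BreakDetectionConfig.min_segment_months: smaller "
                "than the per-segment parameter count")
        if self.magnitude_from not in ("trend", "full"):
            raise ValueError(
                "invalid BreakDetectionConfig.magnitude_from: "
                "must be 'trend' or 'full'")
        return self
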