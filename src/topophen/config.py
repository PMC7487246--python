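"""Configuration objects for the synthetic landscape and pipeline runs.

``SyntheticConfig`` collects every knob of the synthetic-landscape
generator.  The defaults encode the study conditions: paired north/south
grassland slopes with a ~3.06 °C soil-temperature contrast, flowering
advancing ~3.4 days per +1 °C of mean March–May temperature, weekly
surveys over the March–June season, three 1 m² plots per aspect, and a
fraction of each site's species present on only one aspect (turnover).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: March–June season expressed as day-of-year (1-based).
DEFAULT_SEASON = (60, 181)
#: March–May flowering-season window used for mean-temperature summaries.
FLOWERING_WINDOW = (60, 151)

DEFAULT_YEAR_OFFSETS = {
    "2015": 0.0,
    "2016": 0.5,
    "2017": -1.0,
    "2018": 0.3,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic paired-aspect landscape.

    Attributes
    ----------
    seed
        Master seed; every random stream derives from it.
    n_sites
        Number of sites, each with a paired north and south aspect.
    plots_per_aspect
        Quadrats per aspect sharing one soil-temperature sensor.
    season_window
        ``(start_doy, end_doy)`` of the survey season (inclusive).
    survey_interval_days
        Days between successive surveys (aligned grid from season start).
    n_species_pool
        Size of the landscape species pool.
    turnover_fraction
        Fraction of a site's species present on only one aspect.
    aspect_temp_offset_C
        Expected south-minus-north soil-temperature contrast in °C.
    sensitivity_days_per_C
        Days of flowering advance per +1 °C of mean March–May temperature.
    curve_sd_days
        Spread (sd, days) of each species' unimodal flowering curve.
    abundance_mean
        Expected total inflorescences per species per plot per season.
    var_species_peak, var_site, var_genotype, var_plot_noise
        Variance components (days²) of realized peak flowering dates.
    fixed_genotype_mode
        Emulates common-genotype subplots: forces the genotype variance
        contribution to zero so only plastic responses remain.
    years
        Mapping of year label -> year-level temperature offset (°C).
    """

    seed: int = 0
    n_sites: int = 4
    plots_per_aspect: int = 3
    season_window: tuple[int, int] = DEFAULT_SEASON
    survey_interval_days: int = 7
    n_species_pool: int = 32
    turnover_fraction: float = 0.3
    aspect_temp_offset_C: float = 3.06
    sensitivity_days_per_C: float = 3.4
    curve_sd_days: float = 7.0
    abundance_mean: float = 50.0
    var_species_peak: float = 225.0
    var_site: float = 25.0
    var_genotype: float = 4.0
    var_plot_noise: float = 4.0
    fixed_genotype_mode: bool = False
    years: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_YEAR_OFFSETS)
    )

    # --- temperature model calibration ---
    base_temp_C: float = 10.0          # north-aspect soil temp at season start
    seasonal_range_C: float = 8.0      # warming across the season
    diurnal_amp_C: float = 2.0         # damped diurnal cycle at 10 cm depth
    temp_noise_sd_C: float = 0.5       # per-hourly-reading Gaussian noise
    site_temp_sd_C: float = 0.5        # between-site temperature sd

    # --- survey model calibration ---
    peak_mean_doy: float = 115.0       # landscape mean peak (late April)
    peak_layout: str = "even"          # staggered succession; or "random"
    site_richness_range: tuple[int, int] = (6, 18)
    poisson_noise: bool = True

    # --- moisture model calibration ---
    moisture_doys: tuple[int, ...] = (100, 130, 160)
    moisture_south_mean_vwc: float = 10.0
    aspect_moisture_log_ratio: float = 0.157   # log(VWC_N / VWC_S)
    moisture_drydown_log: float = 0.4          # log-scale decline over season
    moisture_noise_sd_log: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.turnover_fraction <= 1.0:
            raise ValueError("turnover_fraction must be in [0, 1]")
        if self.survey_interval_days < 1:
            raise ValueError("survey_interval_days must be >= 1")
        lo, hi = self.season_window
        if hi <= lo:
            raise ValueError("season_window must be a non-empty (start, end)")
        for name in ("var_species_peak", "var_site", "var_genotype",
                     "var_plot_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites < 1 or self.plots_per_aspect < 1:
            raise ValueError("need at least one site and one plot per aspect")
        if self.n_species_pool < 1:
            raise ValueError("n_species_pool must be >= 1")
        if self.fixed_genotype_mode:
            self.var_genotype = 0.0
        self.years = dict(self.years)
        if not self.years:
            raise ValueError("at least one year is required")

    @property
    def survey_doys(self) -> list[int]:
        lo, hi = self.season_window
        return list(range(lo, hi + 1, self.survey_interval_days))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["season_window"] = list(self.season_window)
        d["site_richness_range"] = list(self.site_richness_range)
        d["moisture_doys"] = list(self.moisture_doys)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        for key in ("season_window", "site_richness_range", "moisture_doys"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Convention switches default to the choices documented in each stage:
    step-threshold dates, plot-level durations averaged per aspect, and
    pooled-count combined-aspect duration.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    outdir: str | Path = "topophen_run"
    input_dir: str | Path | None = None       # read CSVs instead of simulating
    threshold_mode: str = "step"              # or "interp"
    regression_threshold_mode: str = "interp" # date resolution for regressions
    aspect_duration_mode: str = "plot_mean"   # or "pooled"
    combined_mode: str = "pooled"             # or "union"
    single_date_rule: bool = True
    include_fixed_genotype: bool = True       # run the common-genotype companion
    overwrite: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("step", "interp"):
            raise ValueError("threshold_mode must be 'step' or 'interp'")
        if self.regression_threshold_mode not in ("step", "interp"):
            raise ValueError(
                "regression_threshold_mode must be 'step' or 'interp'")
        if self.aspect_duration_mode not in ("plot_mean", "pooled"):
            raise ValueError("aspect_duration_mode must be 'plot_mean' or 'pooled'")
        if self.combined_mode not in ("pooled", "union"):
            raise ValueError("combined_mode must be 'pooled' or 'union'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["outdir"] = str(self.outdir)
        d["input_dir"] = None if self.input_dir is None else str(self.input_dir)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], Mapping):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        """Hash of the scientific configuration (paths/verbosity excluded)."""
        d = self.to_dict()
        for key in ("outdir", "input_dir", "verbosity", "overwrite"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
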