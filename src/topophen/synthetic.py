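"""Synthetic paired-aspect landscape generator.

Emulates the statistical structure of a paired north/south-slope
grassland phenology study so the whole pipeline can run with no field
data: hourly soil-temperature series per site × aspect sensor, weekly
inflorescence counts per plot × species with Poisson noise, and spot
soil-moisture measurements.

Mechanism for the surveys: every species in the pool has a peak
flowering day-of-year; the realized peak of a species in a plot is

    pool_peak + site_effect + genotype_effect + plot_noise
        - sensitivity * (plot mean March-May temperature - landscape mean)

so warmer (south) aspects flower earlier by ``sensitivity × ΔT`` days in
expectation.  Expected counts follow a discretized Gaussian-shaped curve
normalized over the survey dates so that the expected season total per
species × plot equals ``abundance_mean`` exactly; observed counts are
Poisson draws around those expectations.  Species assignment to aspects
implements the turnover fraction (species present on only one aspect of
a site).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FLOWERING_WINDOW, SyntheticConfig

ASPECTS = ("N", "S")

SURVEYS_COLUMNS = ["site_id", "aspect", "plot_id", "species_id", "year",
                   "doy", "count"]
TEMPERATURE_COLUMNS = ["site_id", "aspect", "year", "doy", "hour",
                       "soil_temp_C"]
MOISTURE_COLUMNS = ["site_id", "aspect", "plot_id", "year", "doy", "vwc_pct"]

# sub-stream tags appended to the master seed so each table has its own
# reproducible random stream
_TEMP_STREAM, _SURVEY_STREAM, _MOISTURE_STREAM = 1, 2, 3


def _site_ids(config: SyntheticConfig) -> list[str]:
    return [f"site{i + 1}" for i in range(config.n_sites)]


def _plot_ids(config: SyntheticConfig) -> list[str]:
    return [f"p{i + 1}" for i in range(config.plots_per_aspect)]


def simulate_temperature(config: SyntheticConfig) -> pd.DataFrame:
    """Hourly soil temperature per site × aspect sensor over the season.

    Model: linear seasonal warming + damped diurnal sinusoid + site and
    year offsets + the south-aspect offset + iid Gaussian noise.  With
    noise sd 0 every paired (S − N) reading equals the configured aspect
    offset exactly.  Deterministic given ``config.seed``.
    """
    lo, hi = config.season_window
    rng = np.random.default_rng([config.seed, _TEMP_STREAM])
    site_eff = rng.normal(0.0, config.site_temp_sd_C, config.n_sites)

    doys = np.arange(lo, hi + 1)
    hours = np.arange(24)
    seasonal = config.base_temp_C + config.seasonal_range_C * (doys - lo) / (hi - lo)
    diurnal = config.diurnal_amp_C * np.sin(2 * np.pi * (hours - 9) / 24.0)
    grid = seasonal[:, None] + diurnal[None, :]          # (n_doy, 24)
    n = grid.size

    frames = []
    for si, site in enumerate(_site_ids(config)):
        for year, yoff in config.years.items():
            for aspect in ASPECTS:
                shift = config.aspect_temp_offset_C if aspect == "S" else 0.0
                noise = rng.normal(0.0, config.temp_noise_sd_C, grid.shape)
                temp = grid + site_eff[si] + yoff + shift + noise
                frames.append(pd.DataFrame({
                    "site_id": site,
                    "aspect": aspect,
                    "year": year,
                    "doy": np.repeat(doys, 24),
                    "hour": np.tile(hours, len(doys)),
                    "soil_temp_C": temp.reshape(n),
                }))
    return pd.concat(frames, ignore_index=True)


def plot_season_temperature(temperature: pd.DataFrame,
                            window: tuple[int, int] = FLOWERING_WINDOW,
                            ) -> pd.DataFrame:
    """Mean of daily-mean soil temperature in ``window`` per sensor-year.

    Returns a frame with columns site_id, aspect, year, mean_temp_C.  One
    sensor serves all plots on its aspect, so this is also the plot-level
    flowering-season temperature.
    """
    daily = (temperature
             .groupby(["site_id", "aspect", "year", "doy"], sort=True)
             ["soil_temp_C"].mean().reset_index())
    lo, hi = window
    sel = daily[(daily["doy"] >= lo) & (daily["doy"] <= hi)]
    out = (sel.groupby(["site_id", "aspect", "year"], sort=True)
           ["soil_temp_C"].mean().reset_index()
           .rename(columns={"soil_temp_C": "mean_temp_C"}))
    return out


def _pool_peaks(config: SyntheticConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Peak flowering day of each pool species.

    ``even``: a staggered flowering succession — peaks equally spaced
    across the pool's span (uniform with sd ``sqrt(var_species_peak)``)
    plus a small jitter, the classic picture of sequential flowering in
    a spring community.  ``random``: iid Gaussian peaks.
    """
    sd = math.sqrt(config.var_species_peak)
    n = config.n_species_pool
    if config.peak_layout == "random":
        return config.peak_mean_doy + rng.normal(0.0, sd, n)
    if config.peak_layout != "even":
        raise ValueError(f"unknown peak_layout {config.peak_layout!r}")
    half = math.sqrt(3.0) * sd           # uniform(-half, half) has sd == sd
    if n == 1:
        offsets = np.zeros(1)
    else:
        offsets = np.linspace(-half, half, n)
    jitter = rng.normal(0.0, 0.15 * sd if sd > 0 else 0.0, n)
    return config.peak_mean_doy + offsets + jitter


def _site_species_assignment(config: SyntheticConfig, rng: np.random.Generator,
                             pool_peaks: np.ndarray):
    """Per site: which pool species occur, and on which aspect(s).

    Returns ``{site_id: {species_index: set of aspects}}``.  A fraction
    ``turnover_fraction`` of each site's species is present on a single
    aspect.  Single-aspect species are assigned alternately along the
    flowering succession (sorted by pool peak), emulating guild
    replacement: an aspect specialist is typically replaced on the
    opposite slope by a different species flowering in a similar window,
    so both aspects keep a comparable community phenology structure.
    """
    lo_r, hi_r = config.site_richness_range
    hi_r = min(hi_r, config.n_species_pool)
    lo_r = min(lo_r, hi_r)
    pool_order = sorted(range(config.n_species_pool),
                        key=lambda sp: pool_peaks[sp])
    assignment: dict[str, dict[int, set]] = {}
    for site in _site_ids(config):
        richness = int(rng.integers(lo_r, hi_r + 1))
        # whole replacement pairs: round the specialist count to even
        n_unique = 2 * int(round(config.turnover_fraction * richness / 2.0))
        n_pairs = min(n_unique // 2, config.n_species_pool // 2)
        per_species: dict[int, set] = {}
        # guild-replacement pairs: pool neighbours in the succession split
        # N/S, so each specialist is replaced on the other slope by a
        # species flowering in a near-identical window
        starts = rng.permutation(max(config.n_species_pool - 1, 0))
        used: set[int] = set()
        assigned = 0
        first = int(rng.integers(0, 2))
        for i in starts.tolist():
            if assigned >= n_pairs:
                break
            if i in used or i + 1 in used:
                continue
            # orientation alternates between a site's pairs so neither
            # aspect systematically hosts the earlier guild member
            flip = (first + assigned) % 2
            per_species[pool_order[i]] = {ASPECTS[flip]}
            per_species[pool_order[i + 1]] = {ASPECTS[1 - flip]}
            used.update((i, i + 1))
            assigned += 1
        n_shared = max(0, richness - 2 * assigned)
        free = [pool_order[j] for j in range(config.n_species_pool)
                if j not in used]
        shared = rng.choice(np.array(free), size=min(n_shared, len(free)),
                            replace=False)
        for sp in shared.tolist():
            per_species[sp] = {"N", "S"}
        assignment[site] = per_species
    return assignment


def simulate_surveys(config: SyntheticConfig,
                     temperature: pd.DataFrame) -> pd.DataFrame:
    """Weekly inflorescence counts per site × aspect × plot × species × year.

    Raises ``ValueError`` if the temperature series does not cover the
    season for every site × aspect × year, or if any species' flowering
    curve falls entirely outside the season window (reported, never
    silently truncated).
    """
    lo, hi = config.season_window
    temps = plot_season_temperature(temperature)
    expected_keys = {(s, a, y) for s in _site_ids(config) for a in ASPECTS
                     for y in config.years}
    have = set(map(tuple, temps[["site_id", "aspect", "year"]]
                   .astype(str).itertuples(index=False)))
    missing = expected_keys - have
    if missing:
        raise ValueError(
            f"temperature series missing for {sorted(missing)[:5]} "
            f"({len(missing)} sensor-years total)")
    tmap = {(r.site_id, r.aspect, r.year): r.mean_temp_C
            for r in temps.itertuples()}
    landscape_mean = float(np.mean(list(tmap.values())))

    rng = np.random.default_rng([config.seed, _SURVEY_STREAM])
    pool_peaks = _pool_peaks(config, rng)
    assignment = _site_species_assignment(config, rng, pool_peaks)

    doys = np.asarray(config.survey_doys)
    sd = config.curve_sd_days
    sens = config.sensitivity_days_per_C
    plots = _plot_ids(config)

    rows = []
    offenders = []
    for site, per_species in assignment.items():
        species = sorted(per_species)
        # one community-wide timing offset per site (soil, exposure, elevation)
        site_shift = rng.normal(0.0, math.sqrt(config.var_site))
        for aspect in ASPECTS:
            present = [sp for sp in species if aspect in per_species[sp]]
            for plot in plots:
                geno = dict(zip(present, rng.normal(
                    0.0, math.sqrt(config.var_genotype), len(present))))
                for year in config.years:
                    t_plot = tmap[(site, aspect, year)]
                    shift = -sens * (t_plot - landscape_mean)
                    pnoise = rng.normal(0.0, math.sqrt(config.var_plot_noise),
                                        len(present))
                    for sp, eps in zip(present, pnoise):
                        peak = (pool_peaks[sp] + site_shift + geno[sp]
                                + eps + shift)
                        w = np.exp(-0.5 * ((doys - peak) / sd) ** 2)
                        wsum = w.sum()
                        if wsum < 1e-8:
                            offenders.append((site, aspect, plot,
                                              f"sp{sp + 1:02d}", year,
                                              round(float(peak), 1)))
                            continue
                        expected = config.abundance_mean * w / wsum
                        if config.poisson_noise:
                            counts = rng.poisson(expected).astype(float)
                        else:
                            counts = expected
                        for d, c in zip(doys.tolist(), counts.tolist()):
                            rows.append((site, aspect, plot,
                                         f"sp{sp + 1:02d}", year, d, c))
    if offenders:
        raise ValueError(
            "flowering curve mass entirely outside the season window for "
            f"{len(offenders)} species-plot-years, e.g. {offenders[:3]} "
            "(site, aspect, plot, species, year, realized peak doy); widen "
            "season_window or reduce variance components")
    return pd.DataFrame(rows, columns=SURVEYS_COLUMNS)


def simulate_moisture(config: SyntheticConfig) -> pd.DataFrame:
    """Spot volumetric-water-content measurements per plot on a few dates.

    Log-scale model: south-aspect VWC declines over the season (soil
    drydown); the north aspect is wetter by ``aspect_moisture_log_ratio``
    on the log scale (≈1.7 %VWC at a ~10% baseline).
    """
    lo, hi = config.season_window
    rng = np.random.default_rng([config.seed, _MOISTURE_STREAM])
    site_eff = rng.normal(0.0, 0.05, config.n_sites)
    rows = []
    for si, site in enumerate(_site_ids(config)):
        for year in config.years:
            for doy in config.moisture_doys:
                base = (math.log(config.moisture_south_mean_vwc)
                        - config.moisture_drydown_log * (doy - lo) / (hi - lo)
                        + site_eff[si])
                for aspect in ASPECTS:
                    shift = (config.aspect_moisture_log_ratio
                             if aspect == "N" else 0.0)
                    noise = rng.normal(0.0, config.moisture_noise_sd_log,
                                       config.plots_per_aspect)
                    for plot, eps in zip(_plot_ids(config), noise):
                        rows.append((site, aspect, plot, year, doy,
                                     math.exp(base + shift + eps)))
    return pd.DataFrame(rows, columns=MOISTURE_COLUMNS)


def truth_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generating parameters as a two-column (parameter, value) table."""
    rows = [(k, json.dumps(v) if isinstance(v, (dict, list)) else str(v))
            for k, v in config.to_dict().items()]
    return pd.DataFrame(rows, columns=["parameter", "value"])


def simulate_landscape(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Generate all tables: surveys, temperature, moisture, truth."""
    temperature = simulate_temperature(config)
    surveys = simulate_surveys(config, temperature)
    moisture = simulate_moisture(config)
    return {
        "surveys": surveys,
        "temperature": temperature,
        "moisture": moisture,
        "truth": truth_table(config),
    }


def write_dataset(tables: dict[str, pd.DataFrame], path: str | Path,
                  overwrite: bool = False) -> dict[str, Path]:
    """Write the dataset as tidy CSVs under ``path``.

    Refuses to overwrite existing files unless ``overwrite=True``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = {}
    targets = {name: path / f"{name}.csv" for name in tables}
    if not overwrite:
        existing = [str(p) for p in targets.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing}; pass overwrite=True")
    for name, df in tables.items():
        df.to_csv(targets[name], index=False)
        written[name] = targets[name]
    return written


def read_dataset(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read back a dataset written by :func:`write_dataset`.

    Year labels are restored as strings so tables round-trip losslessly.
    """
    path = Path(path)
    out = {}
    for name in ("surveys", "temperature", "moisture", "truth"):
        f = path / f"{name}.csv"
        if not f.exists():
            continue
        if name == "truth":
            out[name] = pd.read_csv(f, dtype=str)
        else:
            df = pd.read_csv(f)
            if "year" in df.columns:
                df["year"] = df["year"].astype(str)
            out[name] = df
    return out
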