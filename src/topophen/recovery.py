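"""Parameter-recovery computations on synthetic landscapes.

These are the pipeline's own regression and microclimate summaries,
packaged so that a recovery study (generate a landscape with known
parameters, re-estimate them from the simulated observations) is a
two-line affair.  Midflowering regressions use interpolated threshold
dates: the weekly survey grid otherwise quantizes dates to ±3.5 days,
which dominates the uncertainty of a slope of a few days per °C.
"""

from __future__ import annotations

import pandas as pd

from . import phenology, synthetic
from .config import SyntheticConfig
from .inference import LinearFit, fit_linear


def balanced_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict to sites observed in every year (balanced design)."""
    years = table["year"].nunique()
    per_site = table.groupby("site_id")["year"].nunique()
    keep = per_site[per_site == years].index
    return table[table["site_id"].isin(keep)]


def sensitivity_regression(surveys: pd.DataFrame, temps: pd.DataFrame,
                           mode: str = "interp",
                           single_date_rule: bool = True,
                           balanced_only: bool = False) -> LinearFit:
    """Midflowering date ~ mean March–May temperature + site + year.

    Plot-level community mid dates regressed on the plot's (= aspect
    sensor's) flowering-season mean soil temperature, with site and year
    as categorical fixed effects.  The coefficient of ``mean_temp_C`` is
    the phenological sensitivity in days per °C (negative: warmer plots
    flower earlier).
    """
    plots = phenology.plot_level_summaries(surveys, mode=mode,
                                           single_date_rule=single_date_rule)
    plots = plots[plots["flowering"]]
    if balanced_only:
        plots = balanced_sites(plots)
    data = plots.merge(temps, on=["site_id", "aspect", "year"])
    return fit_linear(data, "mid_doy", ["mean_temp_C", "year", "site_id"])


def recover_sensitivity_slope(seed: int, n_sites: int = 5
                              ) -> tuple[float, int]:
    """Regenerate a default landscape and re-estimate the sensitivity.

    Returns ``(slope, n)``: the fitted days-per-°C coefficient and the
    number of plot-year observations behind it.
    """
    cfg = SyntheticConfig(seed=seed, n_sites=n_sites)
    temperature = synthetic.simulate_temperature(cfg)
    surveys = synthetic.simulate_surveys(cfg, temperature)
    temps = synthetic.plot_season_temperature(temperature)
    fit = sensitivity_regression(surveys, temps)
    return float(fit.coef["mean_temp_C"]), fit.n


def recover_aspect_contrast(seed: int, n_sites: int = 5
                            ) -> tuple[float, int]:
    """Mean south-minus-north contrast of paired daily-mean soil
    temperatures over the season, across all site-years.

    Returns ``(contrast_C, n_pairs)``.
    """
    cfg = SyntheticConfig(seed=seed, n_sites=n_sites)
    temperature = synthetic.simulate_temperature(cfg)
    daily = (temperature
             .groupby(["site_id", "aspect", "year", "doy"])["soil_temp_C"]
             .mean().reset_index())
    wide = daily.pivot_table(index=["site_id", "year", "doy"],
                             columns="aspect", values="soil_temp_C").dropna()
    diffs = wide["S"] - wide["N"]
    return float(diffs.mean()), int(len(diffs))
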