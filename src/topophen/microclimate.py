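"""Abiotic contrasts between aspects: degree-days, means, gaps, moisture.

Growing degree-days (GDD) accumulate max(0, daily mean − base) with a
5 °C base temperature.  Paired south/north GDD totals are compared with
an exact binomial sign test.  Short logger gaps can be filled from the
same sensor's other years, adjusted by an air-temperature reference.
Soil-moisture spot measurements are compared on the log scale with a
fixed-effects linear model.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import FLOWERING_WINDOW
from .inference import LinearFit, compare_nested, exact_binomial, fit_linear

GDD_BASE_C = 5.0
MAX_GAP_DAYS = 7


@dataclass
class GddSeries:
    """Cumulative growing degree-days over a window for one sensor-year.

    ``cumulative_gdd[i]`` is the accumulation from zero at the start of
    the window through the end of day ``doys[i]``.
    """

    doys: np.ndarray
    cumulative_gdd: np.ndarray
    base_C: float
    entity: Mapping[str, str] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.cumulative_gdd[-1])


def _daily_means(series: pd.DataFrame) -> pd.Series:
    """Daily mean temperature indexed by doy from an hourly/daily table."""
    return series.groupby("doy")["soil_temp_C"].mean().sort_index()


def _check_gaps(doys: np.ndarray, window: tuple[int, int]) -> None:
    lo, hi = window
    present = np.zeros(hi - lo + 1, dtype=bool)
    inside = (doys >= lo) & (doys <= hi)
    present[doys[inside] - lo] = True
    missing = np.flatnonzero(~present)
    if missing.size == 0:
        return
    # longest run of consecutive missing days
    runs = np.split(missing, np.where(np.diff(missing) != 1)[0] + 1)
    longest = max(len(r) for r in runs)
    if longest > MAX_GAP_DAYS:
        raise ValueError(
            f"temperature gap of {longest} days (> {MAX_GAP_DAYS}) in "
            f"window {window}; fill it first with gap_fill_temperature")


def growing_degree_days(series: pd.DataFrame, base_C: float = GDD_BASE_C,
                        window: tuple[int, int] = (60, 181),
                        entity: Mapping[str, str] | None = None) -> GddSeries:
    """Cumulative GDD for one sensor-year table (columns doy, soil_temp_C).

    Daily contribution is max(0, daily mean − base).  Gaps of up to
    seven days are linearly interpolated on the daily means; longer gaps
    raise an error directing to :func:`gap_fill_temperature`.
    """
    lo, hi = window
    daily = _daily_means(series)
    daily = daily[(daily.index >= lo) & (daily.index <= hi)]
    if daily.empty:
        raise ValueError(f"no temperature data inside window {window}")
    _check_gaps(daily.index.to_numpy(), window)
    full = daily.reindex(range(lo, hi + 1)).interpolate(
        limit_direction="both")
    contrib = np.clip(full.to_numpy() - base_C, 0.0, None)
    return GddSeries(doys=np.arange(lo, hi + 1),
                     cumulative_gdd=np.cumsum(contrib), base_C=base_C,
                     entity=dict(entity or {}))


def gdd_table(temperature: pd.DataFrame, base_C: float = GDD_BASE_C,
              window: tuple[int, int] = (60, 181)) -> pd.DataFrame:
    """Total GDD per site × aspect × year."""
    rows = []
    for (site, aspect, year), grp in temperature.groupby(
            ["site_id", "aspect", "year"], sort=True):
        g = growing_degree_days(grp, base_C=base_C, window=window)
        rows.append({"site_id": site, "aspect": aspect, "year": str(year),
                     "gdd_total": g.total})
    return pd.DataFrame(rows)


def gdd_sign_test(gdd_totals: pd.DataFrame) -> tuple[int, int, float]:
    """Did south aspects accumulate more GDD than paired north aspects?

    Returns ``(k, n, p)``: k site-years with GDD_S > GDD_N out of n
    non-tied pairs, with the exact two-sided binomial p-value at 0.5.
    """
    wide = gdd_totals.pivot_table(index=["site_id", "year"], columns="aspect",
                                  values="gdd_total")
    wide = wide.dropna(subset=["N", "S"])
    diffs = wide["S"] - wide["N"]
    non_tied = diffs[diffs != 0]
    k = int((non_tied > 0).sum())
    n = len(non_tied)
    if n == 0:
        raise ValueError("all pairs tied; sign test undefined")
    return k, n, exact_binomial(k, n)


def mean_seasonal_temperature(series: pd.DataFrame,
                              window: tuple[int, int] = FLOWERING_WINDOW,
                              ) -> float:
    """Arithmetic mean of daily-mean temperatures inside the window."""
    daily = _daily_means(series)
    lo, hi = window
    sel = daily[(daily.index >= lo) & (daily.index <= hi)]
    if sel.empty:
        raise ValueError(f"no temperature data inside window {window}")
    return float(sel.mean())


def _doy_month(doy: int) -> int:
    # non-leap calendar mapping
    return (datetime.date(2001, 1, 1)
            + datetime.timedelta(days=int(doy) - 1)).month


def gap_fill_temperature(target: pd.Series,
                         donors: Sequence[pd.Series],
                         air_target: pd.Series | None = None,
                         air_donors: Sequence[pd.Series] | None = None,
                         ) -> tuple[pd.Series, pd.Series]:
    """Fill missing daily means from the same sensor's other years.

    Each missing day is filled with the donor-years' mean for that day
    plus the difference in air-temperature means (target year minus donor
    years) over the month containing the gap.  Returns the filled series
    and a boolean mask of the filled positions.

    Parameters are daily-mean series indexed by day-of-year; missing
    target days are NaN (or absent donors for a day leave it unfillable).
    """
    if not donors:
        raise ValueError("no donor years supplied; gap is unfillable")
    filled = target.astype(float).copy()
    mask = pd.Series(False, index=filled.index)
    donor_df = pd.concat(list(donors), axis=1)
    for doy in filled.index[filled.isna()]:
        donor_vals = donor_df.loc[doy].dropna() if doy in donor_df.index \
            else pd.Series(dtype=float)
        if donor_vals.empty:
            raise ValueError(f"doy {doy} missing from every donor year; "
                             "unfillable")
        adj = 0.0
        if air_target is not None and air_donors:
            month = _doy_month(doy)
            sel_t = air_target[[_doy_month(d) == month for d in air_target.index]]
            donor_air = pd.concat(list(air_donors))
            sel_d = donor_air[[_doy_month(d) == month for d in donor_air.index]]
            if len(sel_t) and len(sel_d):
                adj = float(sel_t.mean() - sel_d.mean())
        filled.loc[doy] = float(donor_vals.mean()) + adj
        mask.loc[doy] = True
    return filled, mask


@dataclass
class MoistureComparison:
    """Aspect contrast in log volumetric water content."""

    log_ratio_N_over_S: float   # fitted log(VWC_N) − log(VWC_S)
    ratio: float                # exp of the above
    approx_vwc_diff: float      # back-transformed difference at the S mean
    f_stat: float
    p_value: float
    n: int
    fit: LinearFit = field(repr=False, default=None)


def moisture_compare(moisture: pd.DataFrame) -> MoistureComparison:
    """Fixed-effects comparison of aspect soil moisture on the log scale.

    Fits log(VWC) ~ aspect + site + measurement date (categorical; a date
    label encodes its year, so year is not entered separately) and tests
    aspect by comparison with the model with aspect removed.
    """
    if (moisture["vwc_pct"] <= 0).any():
        raise ValueError("non-positive VWC; cannot log-transform")
    df = moisture.copy()
    df["log_vwc"] = np.log(df["vwc_pct"].astype(float))
    df["date"] = df["year"].astype(str) + "-" + df["doy"].astype(str)
    if df["aspect"].nunique() < 2:
        raise ValueError("need both aspects")
    if df["date"].nunique() < 2:
        raise ValueError("need at least two measurement dates")
    full = fit_linear(df, "log_vwc", ["aspect", "site_id", "date"])
    null = fit_linear(df, "log_vwc", ["site_id", "date"])
    f_stat, _, _, p = compare_nested(null, full)
    coef_s = float(full.coef.get("aspect[S]", 0.0))
    log_ratio = -coef_s                      # N relative to S
    s_mean = float(df.loc[df["aspect"] == "S", "vwc_pct"].mean())
    return MoistureComparison(
        log_ratio_N_over_S=log_ratio,
        ratio=float(np.exp(log_ratio)),
        approx_vwc_diff=float(s_mean * (np.exp(log_ratio) - 1.0)),
        f_stat=f_stat, p_value=p, n=len(df), fit=full)
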