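"""Flowering-time extension across paired aspects, and its decomposition.

The headline statistic: at a site, combining both aspects' flowering
gives a season of length ``Combined``; the extension due to topographic
complementarity is measured against the longer single aspect,

    Extension(%) = (Combined − Longer) / Longer × 100.

This is conservative: it credits only days beyond the longer slope.
Supporting statistics: a sign test for complementarity (aspects that
start earlier also end earlier), absolute species turnover between
aspects, the extension recomputed with turnover removed (shared species
only), species-level union durations with between-aspect gap removal,
and the turnover-vs-extension regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import phenology
from .inference import compare_nested, exact_binomial, fit_linear


@dataclass
class ExtensionResult:
    site_id: str
    year: str
    level: str                       # community / species:<id> / community_shared_only
    duration_south: float
    duration_north: float
    duration_combined: float
    longer: float
    extension_days: float
    extension_pct: float             # NaN when longer == 0
    gap_days: float = 0.0            # species level only
    flagged: str = ""                # non-empty for degenerate cases


@dataclass
class TurnoverSummary:
    site_id: str
    year: str
    n_unique_north: int
    n_unique_south: int
    n_shared: int

    @property
    def turnover(self) -> int:
        return self.n_unique_north + self.n_unique_south

    @property
    def richness_north(self) -> int:
        return self.n_unique_north + self.n_shared

    @property
    def richness_south(self) -> int:
        return self.n_unique_south + self.n_shared


@dataclass
class SignTestResult:
    n_consistent: int
    n_total: int                     # ties excluded
    n_ties: int
    p_value: float                   # NaN when all pairs tied


def extension_metrics(duration_south: float, duration_north: float,
                      duration_combined: float, site_id: str = "",
                      year: str = "", level: str = "community",
                      gap_days: float = 0.0, flagged: str = "",
                      ) -> ExtensionResult:
    """Fill the extension fields from the three durations.

    ``extension_pct`` is missing (NaN) when the longer aspect has zero
    duration.  A pooled combined duration shorter than the longer aspect
    is reported as-is with a flag, never clamped.
    """
    if min(duration_south, duration_north, duration_combined) < 0:
        raise ValueError("durations must be non-negative")
    longer = max(duration_south, duration_north)
    days = duration_combined - longer
    pct = 100.0 * days / longer if longer > 0 else math.nan
    if days < 0 and not flagged:
        flagged = "combined_shorter_than_longer"
    return ExtensionResult(site_id=site_id, year=year, level=level,
                           duration_south=duration_south,
                           duration_north=duration_north,
                           duration_combined=duration_combined,
                           longer=longer, extension_days=days,
                           extension_pct=pct, gap_days=gap_days,
                           flagged=flagged)


def species_combined_duration(interval_n: tuple[float, float],
                              interval_s: tuple[float, float],
                              ) -> tuple[float, float]:
    """Union duration of two flowering intervals with the gap removed.

    Returns ``(duration, gap_days)`` where duration is the total measure
    of the union (span minus any gap between disjoint intervals) and
    ``gap_days = max(0, later start − earlier end)``.
    """
    (s_n, e_n), (s_s, e_s) = interval_n, interval_s
    if s_n > e_n or s_s > e_s:
        raise ValueError("intervals must satisfy start <= end")
    span = max(e_n, e_s) - min(s_n, s_s)
    gap = max(0.0, max(s_n, s_s) - min(e_n, e_s))
    return float(span - gap), float(gap)


def _aspect_stats(plot_summaries: pd.DataFrame, aspect: str
                  ) -> tuple[float, float, float] | None:
    """(mean duration, mean start, mean end) over flowering plots."""
    sel = plot_summaries[(plot_summaries["aspect"] == aspect)
                         & plot_summaries["flowering"]]
    if sel.empty:
        return None
    return (float(sel["duration_days"].mean()),
            float(sel["start_doy"].mean()),
            float(sel["end_doy"].mean()))


def _pooled_stats(records: pd.DataFrame, single_date_rule: bool, mode: str
                  ) -> tuple[float, float, float] | None:
    curve = phenology.cumulative_proportion(records)
    if not curve.flowering:
        return None
    s = phenology.pheno_summary(curve, single_date_rule=single_date_rule,
                                mode=mode)
    return s.duration_days, s.start_doy, s.end_doy


def community_extension(records: pd.DataFrame, site_id: str, year: str,
                        aspect_duration_mode: str = "plot_mean",
                        combined_mode: str = "pooled",
                        threshold_mode: str = "step",
                        single_date_rule: bool = True,
                        level: str = "community") -> ExtensionResult:
    """Community extension for one site × year from its survey records.

    Per-aspect duration: mean of plot-level durations (default) or the
    aspect-pooled curve.  Combined duration: counts pooled across both
    aspects' plots and re-thresholded (default), or the union of the two
    aspect intervals with any gap removed.  If one aspect never flowers,
    the combined duration is the flowering aspect's duration and the
    extension is zero, flagged.
    """
    sel = records[(records["site_id"] == site_id)
                  & (records["year"].astype(str) == str(year))]
    if sel.empty:
        raise ValueError(f"no records for site {site_id!r} year {year!r}")

    stats = {}
    for aspect in ("N", "S"):
        asp = sel[sel["aspect"] == aspect]
        if asp.empty or asp["count"].sum() == 0:
            stats[aspect] = None
        elif aspect_duration_mode == "plot_mean":
            plots = phenology.plot_level_summaries(
                asp, single_date_rule=single_date_rule, mode=threshold_mode)
            stats[aspect] = _aspect_stats(plots, aspect)
        else:
            stats[aspect] = _pooled_stats(asp, single_date_rule,
                                          threshold_mode)

    if stats["N"] is None and stats["S"] is None:
        raise ValueError(f"no flowering at site {site_id!r} year {year!r}")
    if stats["N"] is None or stats["S"] is None:
        present = "S" if stats["N"] is None else "N"
        dur = stats[present][0]
        return extension_metrics(
            duration_south=dur if present == "S" else 0.0,
            duration_north=dur if present == "N" else 0.0,
            duration_combined=dur, site_id=site_id, year=str(year),
            level=level, flagged=f"single_aspect:{present}")

    dur_n, start_n, end_n = stats["N"]
    dur_s, start_s, end_s = stats["S"]
    union_dur, gap = species_combined_duration((start_n, end_n),
                                               (start_s, end_s))
    pooled = _pooled_stats(sel, single_date_rule, threshold_mode)
    pooled_dur = pooled[0] if pooled else math.nan
    combined = pooled_dur if combined_mode == "pooled" else union_dur
    res = extension_metrics(duration_south=dur_s, duration_north=dur_n,
                            duration_combined=combined, site_id=site_id,
                            year=str(year), level=level, gap_days=gap)
    return res


def community_extension_table(surveys: pd.DataFrame,
                              shared_only: bool = False,
                              **conventions) -> pd.DataFrame:
    """Community extension for every site × year in a survey table.

    With ``shared_only`` the records are first restricted to species
    flowering on both aspects of the site that year (turnover removed);
    site-years with no shared species are reported flagged with missing
    durations.
    """
    level = "community_shared_only" if shared_only else "community"
    rows = []
    for (site, year), grp in surveys.groupby(["site_id", "year"], sort=True):
        if shared_only:
            pres = presence_by_aspect(grp)
            shared = pres.get("N", set()) & pres.get("S", set())
            if not shared:
                rows.append({"site_id": site, "year": str(year),
                             "level": level, "duration_south": np.nan,
                             "duration_north": np.nan,
                             "duration_combined": np.nan, "longer": np.nan,
                             "extension_days": np.nan,
                             "extension_pct": np.nan, "gap_days": np.nan,
                             "flagged": "no_shared_species"})
                continue
            grp = grp[grp["species_id"].isin(shared)]
        res = community_extension(grp, site, str(year), level=level,
                                  **conventions)
        rows.append(vars(res))
    return pd.DataFrame(rows)


def presence_by_aspect(records: pd.DataFrame) -> dict[str, set]:
    """Species with at least one positive count per aspect."""
    pos = records[records["count"] > 0]
    return {aspect: set(grp["species_id"])
            for aspect, grp in pos.groupby("aspect")}


def turnover(site_id: str, year: str,
             species_presence_by_aspect: Mapping[str, set],
             ) -> TurnoverSummary:
    """Absolute turnover: species present on only one aspect of the site."""
    north = set(species_presence_by_aspect.get("N", set()))
    south = set(species_presence_by_aspect.get("S", set()))
    shared = north & south
    return TurnoverSummary(site_id=site_id, year=str(year),
                           n_unique_north=len(north - south),
                           n_unique_south=len(south - north),
                           n_shared=len(shared))


def turnover_table(surveys: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (site, year), grp in surveys.groupby(["site_id", "year"], sort=True):
        t = turnover(site, str(year), presence_by_aspect(grp))
        rows.append({"site_id": t.site_id, "year": t.year,
                     "n_unique_north": t.n_unique_north,
                     "n_unique_south": t.n_unique_south,
                     "n_shared": t.n_shared, "turnover": t.turnover,
                     "richness_north": t.richness_north,
                     "richness_south": t.richness_south})
    return pd.DataFrame(rows)


def species_extension_table(surveys: pd.DataFrame,
                            threshold_mode: str = "step",
                            single_date_rule: bool = True) -> pd.DataFrame:
    """Species-level aspect differences and extension, shared species only.

    For each species flowering on both aspects of a site in a year:
    per-aspect dates from plots pooled within aspect; combined duration
    as the union of the two intervals with between-aspect gaps removed;
    extension against the longer aspect; N − S date differences.
    """
    summaries = phenology.species_aspect_summaries(
        surveys, single_date_rule=single_date_rule, mode=threshold_mode)
    summaries = summaries[summaries["flowering"]]
    rows = []
    for (site, sp, year), grp in summaries.groupby(
            ["site_id", "species_id", "year"], sort=True):
        by_aspect = {r.aspect: r for r in grp.itertuples()}
        if "N" not in by_aspect or "S" not in by_aspect:
            continue
        n, s = by_aspect["N"], by_aspect["S"]
        combined, gap = species_combined_duration(
            (n.start_doy, n.end_doy), (s.start_doy, s.end_doy))
        res = extension_metrics(
            duration_south=s.duration_days, duration_north=n.duration_days,
            duration_combined=max(combined, max(s.duration_days,
                                                n.duration_days)),
            site_id=site, year=str(year), level=f"species:{sp}",
            gap_days=gap)
        rows.append({**vars(res), "species_id": sp,
                     "start_diff_NS": n.start_doy - s.start_doy,
                     "mid_diff_NS": n.mid_doy - s.mid_doy,
                     "end_diff_NS": n.end_doy - s.end_doy})
    return pd.DataFrame(rows)


def complementarity_sign_test(aspect_dates: pd.DataFrame) -> SignTestResult:
    """Do aspects that start flowering earlier also end earlier?

    ``aspect_dates`` has one row per site × year × aspect with
    ``start_doy`` and ``end_doy``.  Site-years tied on start or end are
    excluded from the test and counted separately.  The p-value is the
    exact two-sided binomial test at 0.5; with every pair tied no test is
    possible and the p-value is NaN.
    """
    wide = aspect_dates.pivot_table(index=["site_id", "year"],
                                    columns="aspect",
                                    values=["start_doy", "end_doy"])
    wide = wide.dropna()
    k = n = ties = 0
    for _, row in wide.iterrows():
        ds = row[("start_doy", "N")] - row[("start_doy", "S")]
        de = row[("end_doy", "N")] - row[("end_doy", "S")]
        if ds == 0 or de == 0:
            ties += 1
            continue
        n += 1
        if (ds > 0) == (de > 0):
            k += 1
    p = exact_binomial(k, n) if n > 0 else math.nan
    return SignTestResult(n_consistent=k, n_total=n, n_ties=ties, p_value=p)


def turnover_extension_regression(data: pd.DataFrame
                                  ) -> tuple[float, float, float, float]:
    """OLS of extension days on absolute turnover across site-years.

    Returns ``(slope, intercept, r_squared, p)``; the p-value is the
    extra-sum-of-squares F test against the intercept-only model.
    Constant turnover makes the design rank deficient and raises.
    """
    df = data.dropna(subset=["turnover", "extension_days"])
    if len(df) < 3:
        raise ValueError("need at least 3 site-year points")
    fit = fit_linear(df, "extension_days", ["turnover"])
    null = fit_linear(df, "extension_days", [])
    if fit.rss == 0:                     # collinear points: F undefined
        p = 0.0
    else:
        _, _, _, p = compare_nested(null, fit)
    return (float(fit.coef["turnover"]), float(fit.coef["Intercept"]),
            fit.r_squared, p)
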