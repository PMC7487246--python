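"""Cumulative flowering curves and threshold phenology dates.

The cumulative flowering proportion at a survey date is
(flowers counted through that date) / (total flowers over the season).
Start, mid and end of flowering are the dates at which the cumulative
proportion first reaches 5%, 50% and 95%; duration is end − start.  A
species seen flowering on a single survey date can optionally be given a
nominal 1-day duration (it certainly flowered between surveys, but the
data cannot resolve it).

Two threshold conventions are provided: ``step`` (the first observed
survey date whose cumulative proportion reaches the quantile — the
default, matching weekly field surveys) and ``interp`` (linear
interpolation of the cumulative curve between surveys, finer resolution
but the same ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

THRESHOLDS = (0.05, 0.50, 0.95)


@dataclass
class FloweringCurve:
    """Ordered survey dates, counts and cumulative proportions for one entity."""

    doys: np.ndarray
    counts: np.ndarray
    cum_prop: np.ndarray
    total: float
    entity: Mapping[str, str] = field(default_factory=dict)

    @property
    def flowering(self) -> bool:
        """False for a "no flowering" curve (season total of zero)."""
        return self.total > 0


@dataclass
class PhenoSummary:
    start_doy: float
    mid_doy: float
    end_doy: float
    duration_days: float
    total_count: float
    entity: Mapping[str, str] = field(default_factory=dict)


def cumulative_proportion(doys: Sequence[int] | pd.DataFrame,
                          counts: Sequence[float] | None = None,
                          entity: Mapping[str, str] | None = None,
                          ) -> FloweringCurve:
    """Build a cumulative flowering-proportion curve for one entity.

    Accepts either parallel ``doys``/``counts`` sequences or a DataFrame
    with ``doy`` and ``count`` columns.  Counts on the same date (e.g.
    multiple plots or species pooled into one aggregation level) are
    summed.  A zero season total yields a flagged "no flowering" curve
    (``curve.flowering`` is False) rather than an exception, so callers
    can exclude it downstream.
    """
    if isinstance(doys, pd.DataFrame):
        df = doys
        doy_arr = df["doy"].to_numpy()
        count_arr = df["count"].to_numpy(dtype=float)
    else:
        doy_arr = np.asarray(doys)
        count_arr = np.asarray(counts, dtype=float)
    if len(doy_arr) == 0:
        raise ValueError("need at least one survey record")
    if np.any(count_arr < 0):
        raise ValueError("counts must be non-negative")

    order = np.argsort(doy_arr, kind="stable")
    doy_arr, count_arr = doy_arr[order], count_arr[order]
    uniq, inv = np.unique(doy_arr, return_inverse=True)
    pooled = np.zeros(len(uniq))
    np.add.at(pooled, inv, count_arr)

    total = float(pooled.sum())
    cum = np.cumsum(pooled)
    cum_prop = cum / total if total > 0 else np.zeros_like(cum)
    return FloweringCurve(doys=uniq.astype(int), counts=pooled,
                          cum_prop=cum_prop, total=total,
                          entity=dict(entity or {}))


def threshold_date(curve: FloweringCurve, q: float,
                   mode: str = "step") -> float:
    """Day-of-year at which the cumulative proportion first reaches ``q``.

    ``step`` returns the first observed survey date with cum_prop >= q
    ("had been reached" at a weekly survey); ``interp`` interpolates the
    cumulative curve linearly between surveys.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    if not curve.flowering:
        raise ValueError("no-flowering curve has no threshold dates")
    cp = curve.cum_prop
    idx = int(np.searchsorted(cp, q - 1e-12))
    if idx >= len(cp):           # numerical guard; cp ends at 1.0
        idx = len(cp) - 1
    if mode == "step":
        return float(curve.doys[idx])
    if mode == "interp":
        if idx == 0:
            return float(curve.doys[0])
        c0, c1 = cp[idx - 1], cp[idx]
        d0, d1 = curve.doys[idx - 1], curve.doys[idx]
        if c1 == c0:
            return float(d1)
        return float(d0 + (q - c0) / (c1 - c0) * (d1 - d0))
    raise ValueError(f"unknown threshold mode {mode!r}")


def pheno_summary(curve: FloweringCurve, single_date_rule: bool = True,
                  mode: str = "step") -> PhenoSummary:
    """Start (5%), mid (50%) and end (95%) dates and flowering duration.

    With ``single_date_rule`` a curve whose start and end coincide (all
    flowering seen on one survey date) is assigned a 1-day duration.
    """
    start = threshold_date(curve, 0.05, mode)
    mid = threshold_date(curve, 0.50, mode)
    end = threshold_date(curve, 0.95, mode)
    duration = end - start
    if single_date_rule and duration == 0:
        duration = 1.0
    return PhenoSummary(start_doy=start, mid_doy=mid, end_doy=end,
                        duration_days=float(duration), total_count=curve.total,
                        entity=dict(curve.entity))


def pheno_table(surveys: pd.DataFrame, group_cols: Iterable[str],
                single_date_rule: bool = True, mode: str = "step",
                ) -> pd.DataFrame:
    """Phenology summaries for every group of ``group_cols`` in a survey table.

    Counts are pooled by summation over any survey columns not in
    ``group_cols`` (plots, species, aspects), then thresholded.  Groups
    with zero season total are returned flagged (``flowering = False``)
    with missing dates, ready for downstream exclusion.
    """
    group_cols = list(group_cols)
    rows = []
    for key, grp in surveys.groupby(group_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        entity = dict(zip(group_cols, map(str, key)))
        curve = cumulative_proportion(grp, entity=entity)
        if not curve.flowering:
            rows.append({**entity, "flowering": False, "start_doy": np.nan,
                         "mid_doy": np.nan, "end_doy": np.nan,
                         "duration_days": np.nan, "total_count": 0.0})
            continue
        s = pheno_summary(curve, single_date_rule=single_date_rule, mode=mode)
        rows.append({**entity, "flowering": True, "start_doy": s.start_doy,
                     "mid_doy": s.mid_doy, "end_doy": s.end_doy,
                     "duration_days": s.duration_days,
                     "total_count": s.total_count})
    return pd.DataFrame(rows)


def plot_level_summaries(surveys: pd.DataFrame, **kw) -> pd.DataFrame:
    """Community phenology per plot (species pooled within plot)."""
    return pheno_table(surveys, ["site_id", "aspect", "plot_id", "year"], **kw)


def aspect_level_summaries(surveys: pd.DataFrame, **kw) -> pd.DataFrame:
    """Community phenology per aspect (plots and species pooled)."""
    return pheno_table(surveys, ["site_id", "aspect", "year"], **kw)


def species_aspect_summaries(surveys: pd.DataFrame, **kw) -> pd.DataFrame:
    """Per-species phenology per aspect (plots pooled within aspect)."""
    return pheno_table(surveys, ["site_id", "aspect", "species_id", "year"], **kw)
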