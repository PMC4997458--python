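"""Classical trend statistics and population-exposure tabulation.

OLS trends of annual summary series with 95% confidence intervals, empirical
quantile series over study-area cells, yearly concentration histograms,
grade-area time series, grouped boxplot quantiles, and the percent of
population living above concentration thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import (
    GradeScheme,
    RasterGrid,
    ZoneLabels,
    area_percent_by_grade,
    classify_grades,
)

__all__ = [
    "AnnualSeries",
    "TrendFit",
    "ols_trend",
    "quantile_series",
    "time_histogram",
    "grade_area_series",
    "exposure_percent",
    "boxplot_stats",
]


@dataclass(frozen=True)
class AnnualSeries:
    """A yearly summary series (μg/m³ or percent)."""

    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an annual series: slope per year with a 95% CI."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("CI must bracket the slope")


def ols_trend(series: AnnualSeries) -> TrendFit:
    """Ordinary least squares of value on year.

    95% CI for the slope is slope ± t_{0.975, n-2} * SE(slope). A perfectly
    linear series gets a zero-width interval.
    """
    years = np.asarray(series.years, dtype=float)
    values = np.asarray(series.values, dtype=float)
    if years.size < 3:
        raise ValueError("need at least 3 points for a trend")
    res = stats.linregress(years, values)
    tcrit = stats.t.ppf(0.975, years.size - 2)
    half = tcrit * res.stderr
    if not np.isfinite(half):
        half = 0.0
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_low=float(res.slope - half),
        ci_high=float(res.slope + half),
        r_squared=float(res.rvalue**2),
    )


def _study_values(grid: RasterGrid, zones: ZoneLabels | None) -> np.ndarray:
    if grid.n_missing:
        raise ValueError("grid must be fully observed")
    if zones is None:
        return grid.values.ravel()
    if zones.shape != grid.shape:
        raise ValueError("zone raster shape must match grid")
    vals = grid.values[zones.labels > 0]
    if vals.size == 0:
        raise ValueError("empty study area")
    return vals


def quantile_series(
    grids: Sequence[RasterGrid], q: float, zones: ZoneLabels | None = None
) -> AnnualSeries:
    """Per-year empirical quantile over study-area cells.

    Uses the linear-interpolation ("type 7") quantile definition.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    years = tuple(int(g.year) for g in grids)
    values = tuple(float(np.quantile(_study_values(g, zones), q)) for g in grids)
    return AnnualSeries(years=years, values=values)


def time_histogram(
    grids: Sequence[RasterGrid],
    bin_edges: Sequence[float],
    zones: ZoneLabels | None = None,
) -> pd.DataFrame:
    """Year x bin matrix of normalized concentration frequencies.

    Row t holds the relative frequencies of year t's cell values; values
    below the first or at/above the last edge are counted in the open end
    bins, so every row sums to 1.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing with >= 2 entries")
    n_bins = edges.size - 1
    rows = []
    for g in grids:
        vals = _study_values(g, zones)
        idx = np.clip(np.digitize(vals, edges) - 1, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        rows.append(counts / vals.size)
    index = pd.Index([int(g.year) for g in grids], name="year")
    cols = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_bins)]
    return pd.DataFrame(rows, index=index, columns=cols)


def grade_area_series(
    grids: Sequence[RasterGrid],
    scheme: GradeScheme,
    zones: ZoneLabels | None = None,
) -> dict[int, AnnualSeries]:
    """Per-grade annual series of area percent (cell-count share).

    Feed each series to :func:`ols_trend` for the per-grade trends.
    """
    years = [int(g.year) for g in grids]
    per_year = []
    for g in grids:
        grades = classify_grades(g, scheme)
        per_year.append(
            area_percent_by_grade(grades, zones=zones, grades=scheme.labels)
        )
    table = pd.DataFrame(per_year, index=years)
    return {
        int(grade): AnnualSeries(years=tuple(years), values=tuple(table[grade]))
        for grade in table.columns
    }


def exposure_percent(
    conc: RasterGrid, pop: RasterGrid, thresholds: Iterable[float]
) -> pd.Series:
    """Percent of population in cells with concentration strictly above each threshold.

    Masked population cells (outside the study area) count as zero people.
    """
    if conc.n_missing:
        raise ValueError("concentration grid must be fully observed")
    if conc.shape != pop.shape:
        raise ValueError("grids must be aligned")
    weights = np.where(pop.missing_mask, 0.0, pop.values)
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total population")
    thresholds = [float(t) for t in thresholds]
    pct = [
        100.0 * weights[conc.values > t].sum() / total
        for t in thresholds
    ]
    return pd.Series(pct, index=pd.Index(thresholds, name="threshold"), name="percent")


def boxplot_stats(
    grids: Sequence[RasterGrid],
    group_mask: np.ndarray,
    quantiles: Sequence[float] = (0.1, 0.5, 0.9),
) -> pd.DataFrame:
    """Per-year quantile summaries (default 10%, median, 90%) of one cell group.

    ``group_mask`` is a boolean cell mask selecting the group (e.g. an urban
    agglomeration's cells).
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    if not group_mask.any():
        raise ValueError("empty group")
    rows = []
    for g in grids:
        if g.n_missing:
            raise ValueError("grid must be fully observed")
        if g.shape != group_mask.shape:
            raise ValueError("mask shape must match grids")
        vals = g.values[group_mask]
        rows.append([float(np.quantile(vals, q)) for q in quantiles])
    index = pd.Index([int(g.year) for g in grids], name="year")
    return pd.DataFrame(rows, index=index, columns=[f"q{int(100 * q)}" for q in quantiles])
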